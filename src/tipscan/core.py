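"""Shared domain types, reference windowing and standard-format I/O.

Coordinates are 0-based half-open everywhere inside the toolkit.  BED is
written as-is; GFF3/GTF gene annotation (1-based inclusive) is converted on
ingest.  Window identifiers are the fixed string ``chrom:start-end`` so that
presence/absence matrices are joinable across runs.
"""

from __future__ import annotations

import csv
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

SUPERFAMILIES = ("Gypsy", "Copia", "LINE", "other")

DEFAULT_WINDOW_SIZE = 10_000


@dataclass(frozen=True)
class TEFamily:
    """A TE family: one consensus sequence, with optional LTR/RT features.

    ``ltr_length`` is the length of each terminal repeat for LTR
    retrotransposons (None for LINEs and other non-LTR elements);
    ``rt_domain`` is a half-open interval on the consensus pointing at the
    reverse-transcriptase domain (or, for non-coding LARD-type families, any
    configured low-copy internal probe).
    """

    family_id: str
    superfamily: str
    consensus: str
    ltr_length: int | None = None
    rt_domain: tuple[int, int] | None = None

    def __post_init__(self):
        if not self.consensus:
            raise ValueError(f"{self.family_id}: empty consensus")
        if set(self.consensus) - set("ACGTN"):
            raise ValueError(f"{self.family_id}: consensus not over ACGTN")
        if self.superfamily not in SUPERFAMILIES:
            raise ValueError(f"{self.family_id}: unknown superfamily {self.superfamily!r}")
        if self.ltr_length is not None and self.ltr_length > len(self.consensus) / 2:
            raise ValueError(f"{self.family_id}: ltr_length exceeds half the consensus")
        if self.rt_domain is not None:
            s, e = self.rt_domain
            if not (0 <= s < e <= len(self.consensus)):
                raise ValueError(f"{self.family_id}: rt_domain outside consensus")

    @property
    def ltr5(self) -> str:
        if self.ltr_length is None:
            raise ValueError(f"{self.family_id} has no LTR")
        return self.consensus[: self.ltr_length]

    @property
    def internal(self) -> str:
        if self.ltr_length is None:
            return self.consensus
        return self.consensus[self.ltr_length : len(self.consensus) - self.ltr_length]


@dataclass(frozen=True)
class GenomeWindow:
    chrom: str
    start: int
    end: int

    @property
    def window_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError("invalid window bounds")
        if self.end - self.start > DEFAULT_WINDOW_SIZE:
            raise ValueError("window larger than 10 kb")


@dataclass(frozen=True)
class AccessionMeta:
    accession_id: str
    group: str = "other"  # Indica | Japonica | Aus/Boro | other
    zone: int | None = None
    coverage: float | None = None


@dataclass(frozen=True)
class GeneRecord:
    chrom: str
    start: int  # 0-based half-open
    end: int
    gene_id: str
    strand: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start >= end")


# ---------------------------------------------------------------------------
# windowing


class WindowSet:
    """The 10-kb tiling of a genome, with O(1) position-to-window lookup."""

    def __init__(self, windows: Sequence[GenomeWindow], size: int):
        self.size = size
        self.windows = list(windows)
        self._by_chrom: dict[str, list[GenomeWindow]] = {}
        for w in self.windows:
            self._by_chrom.setdefault(w.chrom, []).append(w)
        for ws in self._by_chrom.values():
            ws.sort(key=lambda w: w.start)

    def __iter__(self):
        return iter(self.windows)

    def __len__(self):
        return len(self.windows)

    def window_of(self, chrom: str, pos: int) -> GenomeWindow:
        ws = self._by_chrom.get(chrom)
        if ws is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if pos < 0 or pos >= ws[-1].end:
            raise ValueError(f"position {pos} outside {chrom}")
        w = ws[pos // self.size] if self.size else None
        if w is None or not (w.start <= pos < w.end):  # pragma: no cover
            i = bisect_right([x.start for x in ws], pos) - 1
            w = ws[i]
        return w

    def by_id(self) -> dict[str, GenomeWindow]:
        return {w.window_id: w for w in self.windows}


def make_windows(genome: Mapping[str, str] | Mapping[str, object],
                 size: int = DEFAULT_WINDOW_SIZE) -> WindowSet:
    """Tile every chromosome into consecutive ``size``-bp windows.

    The final window of a chromosome may be shorter than ``size``; it is kept
    as a short window, not discarded.
    """
    if not genome:
        raise ValueError("no sequences")
    out = []
    for chrom, seq in genome.items():
        L = len(seq)
        if L == 0:
            raise ValueError(f"no sequences in {chrom}")
        for s in range(0, L, size):
            out.append(GenomeWindow(chrom, s, min(s + size, L)))
    return WindowSet(out, size)


def window_of(chrom: str, pos: int, windows: WindowSet) -> GenomeWindow:
    return windows.window_of(chrom, pos)


# ---------------------------------------------------------------------------
# readers / writers


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain FASTA into an in-memory {name: sequence} mapping (uppercased)."""
    recs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in recs:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        recs[rec.id] = str(rec.seq).upper()
    if not recs:
        raise ValueError("no sequences")
    return recs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_te_library(fasta_path: str | Path,
                    features_path: str | Path | None = None) -> list[TEFamily]:
    """Load a TE consensus library from FASTA plus an optional feature sidecar.

    The sidecar is a TSV with columns ``family_id, superfamily, ltr_length,
    rt_start, rt_end`` (empty fields allowed); rows are attached to FASTA
    records by family_id.
    """
    seqs = read_fasta(fasta_path)
    feats: dict[str, dict] = {}
    if features_path is not None:
        with open(features_path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                fid = row["family_id"]
                if fid not in seqs:
                    raise ValueError(f"sidecar family {fid!r} has no FASTA record")
                feats[fid] = row
    out = []
    for fid, seq in seqs.items():
        row = feats.get(fid, {})
        ltr = row.get("ltr_length") or None
        rt_s = row.get("rt_start") or None
        rt_e = row.get("rt_end") or None
        out.append(TEFamily(
            family_id=fid,
            superfamily=row.get("superfamily") or "other",
            consensus=seq,
            ltr_length=int(ltr) if ltr is not None else None,
            rt_domain=(int(rt_s), int(rt_e)) if rt_s is not None and rt_e is not None else None,
        ))
    return out


def write_bed(records: Iterable[tuple], path: str | Path) -> None:
    """Write (chrom, start, end, name, score) tuples as BED5."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score in records:
            if start >= end:
                raise ValueError(f"BED record with start >= end: {chrom}:{start}-{end}")
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\n")


def read_bed(path: str | Path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            rec = (f[0], int(f[1]), int(f[2]))
            if len(f) > 3:
                rec += (f[3],)
            if len(f) > 4:
                try:
                    rec += (int(f[4]),)
                except ValueError:
                    rec += (f[4],)
            out.append(rec)
    return out


def read_accession_meta(path: str | Path) -> list[AccessionMeta]:
    """TSV with columns accession_id, group[, zone][, coverage]."""
    df = pd.read_csv(path, sep="\t")
    if df["accession_id"].duplicated().any():
        raise ValueError("duplicate accession_id in metadata")
    out = []
    for _, r in df.iterrows():
        out.append(AccessionMeta(
            accession_id=str(r["accession_id"]),
            group=str(r.get("group", "other")),
            zone=int(r["zone"]) if "zone" in df.columns and pd.notna(r.get("zone")) else None,
            coverage=float(r["coverage"]) if "coverage" in df.columns and pd.notna(r.get("coverage")) else None,
        ))
    return out


def _parse_gff_attr(attr: str, keys: tuple[str, ...]) -> str | None:
    # handles both GFF3 (ID=x;...) and GTF (gene_id "x"; ...) attribute styles
    for key in keys:
        for part in attr.replace("; ", ";").split(";"):
            part = part.strip()
            if part.startswith(key):
                val = part[len(key):].strip(" =\"")
                val = val.strip('"')
                if val:
                    return val
    return None


def read_genes(path: str | Path, feature_types: tuple[str, ...] = ("gene",)) -> list[GeneRecord]:
    """Read gene records from GFF3/GTF, converting to 0-based half-open.

    Falls back to transcript/mRNA features when no ``gene`` lines exist.
    """
    rows: dict[str, list] = {t: [] for t in feature_types + ("mRNA", "transcript")}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            ftype = f[2]
            if ftype not in rows:
                continue
            gid = _parse_gff_attr(f[8], ("ID", "gene_id", "transcript_id", "Name"))
            rows[ftype].append(GeneRecord(f[0], int(f[3]) - 1, int(f[4]),
                                          gid or f"{f[0]}:{f[3]}", f[6]))
    for t in feature_types + ("mRNA", "transcript"):
        if rows[t]:
            return rows[t]
    return []


def genome_as_dict(genome) -> dict[str, str]:
    """Accept a {chrom: seq} mapping, a pyfaidx.Fasta, or a FASTA path."""
    if isinstance(genome, (str, Path)):
        return read_fasta(genome)
    if isinstance(genome, dict):
        return genome
    return {name: str(genome[name][:]) for name in genome.keys()}


def chrom_lengths(genome: Mapping[str, str]) -> dict[str, int]:
    return {c: len(s) for c, s in genome.items()}
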