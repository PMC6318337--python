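"""Windowed TIP detection from paired-end reads (the pipeline core).

For each accession, read pairs are first matched against the TE consensus
library; pairs where exactly one mate matches a family are junction pairs.
The non-TE mate is then anchored onto the reference genome, and every unique
anchor increments the support count of the 10-kb window it falls in, for
that (accession, family).  Calling is two-pass across the whole panel:

* pass 1 — a (family, window) event is *opened* when some accession supports
  it with at least ``open_threshold`` (default 5) pairs;
* pass 2 — every accession is re-scored against the opened windows with the
  lower ``rescue_threshold`` (default 2), rescuing low-coverage carriers.

The rationale: five independent junction pairs essentially never arise by
chance, so an opened window is trusted; once a window is trusted, two pairs
in another accession are strong evidence for the same event, while the
probability that two chimeric pairs hit the exact same opened window is
negligible.  The output is a binary presence/absence matrix with events
(family, window) in rows and accessions in columns, at 10-kb resolution —
the method deliberately does not refine breakpoints to base pairs.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import (AlignmentParams, ReferenceAligner, TEAligner,
                    batch_te_candidates)
from .core import AccessionMeta, TEFamily, WindowSet, make_windows, write_bed

logger = logging.getLogger(__name__)

OPEN_THRESHOLD = 5
RESCUE_THRESHOLD = 2


@dataclass(frozen=True)
class JunctionPair:
    """A read pair evidencing a TE-genome junction."""

    accession_id: str
    pair_id: str
    te_mate: str
    family_id: str
    anchor_mate: str
    multi_family: bool = False


@dataclass
class SupportTable:
    """(accession, family, window) -> count of uniquely-anchored pairs."""

    counts: dict[tuple[str, str, str], int] = field(default_factory=dict)

    def add(self, accession_id: str, family_id: str, window_id: str, n: int = 1):
        key = (accession_id, family_id, window_id)
        self.counts[key] = self.counts.get(key, 0) + n

    def items(self):
        return self.counts.items()

    def get(self, accession_id: str, family_id: str, window_id: str) -> int:
        return self.counts.get((accession_id, family_id, window_id), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, f, w, c) for (a, f, w), c in sorted(self.counts.items())]
        return pd.DataFrame(rows, columns=["accession_id", "family_id",
                                           "window_id", "support"])


@dataclass(frozen=True)
class TIPCall:
    family_id: str
    window_id: str
    accession_id: str
    support: int
    pass_: int  # 1 if support met the opening threshold, else 2


class TIPMatrix:
    """Binary presence/absence matrix: (family, window) rows x accessions."""

    def __init__(self, df: pd.DataFrame):
        self.df = df  # MultiIndex (family_id, window_id) x accession columns

    @classmethod
    def from_calls(cls, calls: Sequence[TIPCall], panel: Sequence[AccessionMeta],
                   windows: WindowSet | None = None) -> "TIPMatrix":
        acc_ids = sorted(m.accession_id for m in panel)
        known = set(acc_ids)
        for c in calls:
            if c.accession_id not in known:
                raise ValueError(f"call for unknown accession {c.accession_id!r}")
        events = sorted({(c.family_id, c.window_id) for c in calls},
                        key=lambda fw: (fw[0], _window_sort_key(fw[1])))
        mat = pd.DataFrame(
            0, index=pd.MultiIndex.from_tuples(events or [],
                                               names=["family_id", "window_id"]),
            columns=acc_ids, dtype=np.int8)
        for c in calls:
            mat.loc[(c.family_id, c.window_id), c.accession_id] = 1
        return cls(mat)

    @property
    def n_events(self) -> int:
        return len(self.df)

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.index = [f"{f}:{w}" for f, w in out.index]
        out.to_csv(path, sep="\t", index_label="event")

    @classmethod
    def from_tsv(cls, path) -> "TIPMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        idx = pd.MultiIndex.from_tuples(
            [tuple(e.split(":", 1)) for e in df.index],
            names=["family_id", "window_id"])
        df.index = idx
        return cls(df.astype(np.int8))


def _window_sort_key(window_id: str):
    chrom, rest = window_id.split(":")
    start = int(rest.split("-")[0])
    return (chrom, start)


# ---------------------------------------------------------------------------
# stage operations


def classify_pairs(pairs: Iterable[tuple[str, str, str]], te_aligner: TEAligner,
                   accession_id: str = "") -> Iterator[JunctionPair]:
    """Keep pairs where exactly one mate maps to a TE family.

    ``pairs`` yields (pair_id, mate1, mate2).  Pairs with both or neither
    mate matching a consensus carry no junction information and are dropped.
    """
    for pair_id, m1, m2 in pairs:
        f1, multi1 = te_aligner.best_family(m1)
        f2, multi2 = te_aligner.best_family(m2)
        if (f1 is None) == (f2 is None):
            continue
        if f1 is not None:
            yield JunctionPair(accession_id, pair_id, m1, f1, m2, multi1)
        else:
            yield JunctionPair(accession_id, pair_id, m2, f2, m1, multi2)


def collect_support(junctions: Iterable[JunctionPair],
                    ref_aligner: ReferenceAligner,
                    windows: WindowSet,
                    support: SupportTable | None = None) -> SupportTable:
    """Anchor each junction's genomic mate; unique anchors add window support."""
    support = support if support is not None else SupportTable()
    for j in junctions:
        hit = ref_aligner.anchor(j.anchor_mate, j.accession_id, j.family_id)
        if hit.uniqueness != "unique":
            continue
        w = windows.window_of(hit.chrom, hit.pos)
        support.add(j.accession_id, j.family_id, w.window_id)
    return support


def first_pass(support: SupportTable,
               open_threshold: int = OPEN_THRESHOLD) -> set[tuple[str, str]]:
    """(family, window) events opened by >= open_threshold pairs in some accession."""
    opened = set()
    for (acc, fam, win), c in support.items():
        if c >= open_threshold:
            opened.add((fam, win))
    return opened


def second_pass(support: SupportTable, opened: set[tuple[str, str]],
                rescue_threshold: int = RESCUE_THRESHOLD,
                open_threshold: int = OPEN_THRESHOLD) -> list[TIPCall]:
    """Re-scan all accessions at the rescue threshold, restricted to opened windows."""
    calls = []
    for (acc, fam, win), c in sorted(support.items()):
        if (fam, win) in opened and c >= rescue_threshold:
            calls.append(TIPCall(fam, win, acc, c,
                                 1 if c >= open_threshold else 2))
    return calls


def build_matrix(calls: Sequence[TIPCall],
                 panel: Sequence[AccessionMeta]) -> TIPMatrix:
    return TIPMatrix.from_calls(calls, panel)


# ---------------------------------------------------------------------------
# accession-level processing


def _read_fastq_seqs(path) -> list[str]:
    seqs = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                seqs.append(line.strip().upper())
    return seqs


def iter_pair_batches(source, batch_size: int = 50_000) -> Iterator[tuple[list[str], list[str]]]:
    """Yield (mates1, mates2) batches from FASTQ paths or in-memory lists."""
    if isinstance(source, tuple) and len(source) == 2 and not isinstance(source[0], (str, Path)):
        m1, m2 = source
        for i in range(0, len(m1), batch_size):
            yield list(m1[i : i + batch_size]), list(m2[i : i + batch_size])
        return
    fq1, fq2 = source
    m1 = _read_fastq_seqs(fq1)
    m2 = _read_fastq_seqs(fq2)
    if len(m1) != len(m2):
        raise ValueError("FASTQ mate files differ in read count")
    for i in range(0, len(m1), batch_size):
        yield m1[i : i + batch_size], m2[i : i + batch_size]


@dataclass
class AccessionStats:
    accession_id: str
    n_pairs: int = 0
    n_candidates: int = 0
    n_junctions: int = 0
    n_unique_anchors: int = 0
    n_ambiguous_anchors: int = 0


def process_accession(accession_id: str, source, te_aligner: TEAligner,
                      ref_aligner: ReferenceAligner, windows: WindowSet,
                      support: SupportTable,
                      batch_size: int = 50_000) -> AccessionStats:
    """Screen, classify and anchor one accession's read pairs into ``support``.

    The k-mer pre-screen discards pairs sharing no exact k-mer with any
    consensus (either strand) before any alignment work, which is what makes
    whole-panel scans cheap: only reads touching a TE are ever aligned.
    """
    stats = AccessionStats(accession_id)
    pair_no = 0
    for m1, m2 in iter_pair_batches(source, batch_size):
        n = len(m1)
        cand1 = batch_te_candidates(m1, te_aligner)
        cand2 = batch_te_candidates(m2, te_aligner)
        cand = cand1 | cand2
        idx = np.nonzero(cand)[0]
        stats.n_pairs += n
        stats.n_candidates += len(idx)
        pairs = ((f"{accession_id}:{pair_no + i}", m1[i], m2[i]) for i in idx)
        for j in classify_pairs(pairs, te_aligner, accession_id):
            stats.n_junctions += 1
            hit = ref_aligner.anchor(j.anchor_mate, accession_id, j.family_id)
            if hit.uniqueness == "unique":
                stats.n_unique_anchors += 1
                w = windows.window_of(hit.chrom, hit.pos)
                support.add(accession_id, j.family_id, w.window_id)
            elif hit.uniqueness == "ambiguous":
                stats.n_ambiguous_anchors += 1
        pair_no += n
    logger.info("accession %s: %d pairs, %d candidates, %d junctions, %d unique anchors",
                accession_id, stats.n_pairs, stats.n_candidates,
                stats.n_junctions, stats.n_unique_anchors)
    return stats


@dataclass
class DetectionResult:
    matrix: TIPMatrix
    calls: list[TIPCall]
    support: SupportTable
    opened: set[tuple[str, str]]
    stats: list[AccessionStats]
    windows: WindowSet

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.accession_id, c.family_id, c.window_id, c.support, c.pass_)
             for c in self.calls],
            columns=["accession_id", "family_id", "window_id", "support", "pass"])

    def tip_windows_bed(self, path) -> None:
        by_id = self.windows.by_id()
        recs = []
        for fam, win in sorted({(c.family_id, c.window_id) for c in self.calls},
                               key=lambda fw: (_window_sort_key(fw[1]), fw[0])):
            w = by_id[win]
            n_acc = sum(1 for c in self.calls
                        if c.family_id == fam and c.window_id == win)
            recs.append((w.chrom, w.start, w.end, fam, n_acc))
        write_bed(recs, path)


def detect_tips(panel_sources: Mapping[str, object],
                library: Sequence[TEFamily],
                genome: Mapping[str, str],
                panel_meta: Sequence[AccessionMeta] | None = None,
                open_threshold: int = OPEN_THRESHOLD,
                rescue_threshold: int = RESCUE_THRESHOLD,
                params: AlignmentParams | None = None,
                te_min_len: int = 50, te_min_identity: float = 0.90,
                window_size: int = 10_000) -> DetectionResult:
    """Run the complete two-pass detector over a panel.

    ``panel_sources`` maps accession_id to either a (fq1, fq2) path pair or
    an in-memory (mates1, mates2) tuple of sequence lists.  Accessions are
    processed independently; opened windows are merged by set union, so the
    result does not depend on processing order.
    """
    params = params or AlignmentParams()
    windows = make_windows(genome, window_size)
    te_aligner = TEAligner(library, params, te_min_len, te_min_identity)
    ref_aligner = ReferenceAligner(genome, params)
    support = SupportTable()
    stats = []
    for acc_id, source in panel_sources.items():
        try:
            stats.append(process_accession(acc_id, source, te_aligner,
                                           ref_aligner, windows, support))
        except (OSError, ValueError) as exc:
            logger.warning("accession %s failed (%s); dropped from matrix",
                           acc_id, exc)
    opened = first_pass(support, open_threshold)
    calls = second_pass(support, opened, rescue_threshold, open_threshold)
    meta = panel_meta or [AccessionMeta(s.accession_id) for s in stats]
    matrix = build_matrix(calls, meta)
    return DetectionResult(matrix, calls, support, opened, stats, windows)
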