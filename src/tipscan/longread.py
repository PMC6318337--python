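"""Long-read validation of short-read TIP calls.

Junction-bearing long reads are those with a TE-consensus match covering at
most 80 % of the read (a larger fraction means the read lies wholly inside
an element and carries no junction).  Up to 300 bp of sequence flanking the
TE interval on the read is mapped back to the reference under a stringent
gate (>= 250 bp at >= 90 % identity, unique placement); the flank base
adjacent to the TE gives the insertion position.  Insertion loci are
de-duplicated per (family, window) before comparison with short-read calls:
a TIP is validated when a long-read insertion of the same family falls in
its window.  Following the original usage, *specificity* is the fraction of
short-read TIPs validated by long reads and *sensitivity* the fraction of
long-read loci recovered by the short-read calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .align import AlignmentParams, ReferenceAligner, SeedAligner, TEAligner
from .core import TEFamily, WindowSet

MAX_TE_FRACTION = 0.80
FLANK = 300
FLANK_MIN_LEN = 250
FLANK_MIN_IDENTITY = 0.90


@dataclass(frozen=True)
class JunctionRead:
    read_id: str
    sequence: str
    family_id: str
    te_start: int  # TE interval on the read, half-open
    te_end: int


@dataclass(frozen=True)
class LongReadInsertion:
    read_id: str
    family_id: str
    chrom: str
    pos: int
    flank_side: str  # 'left' | 'right' | 'both'


def find_te_reads(reads: Sequence[tuple[str, str]] | Mapping[str, str],
                  library: Sequence[TEFamily],
                  params: AlignmentParams | None = None,
                  min_len: int = 100, min_identity: float = 0.80,
                  max_te_fraction: float = MAX_TE_FRACTION) -> list[JunctionRead]:
    """Reads containing a TE junction: a consensus hit covering <= 80 % of
    the read.  Reads without a qualifying hit, or covered beyond the cap
    (reads lying wholly inside an element), are discarded.
    """
    params = params or AlignmentParams()
    te_aligner = TEAligner(library, params, min_len, min_identity)
    items = reads.items() if isinstance(reads, Mapping) else reads
    out = []
    for read_id, seq in items:
        alns = te_aligner.aligner.align(seq, min_len=min_len,
                                        min_identity=min_identity)
        if not alns:
            continue
        best_fam = alns[0].target_id
        fam_alns = [a for a in alns if a.target_id == best_fam]
        te_start = min(a.query_start for a in fam_alns)
        te_end = max(a.query_end for a in fam_alns)
        if (te_end - te_start) > max_te_fraction * len(seq):
            continue
        out.append(JunctionRead(read_id, seq, best_fam, te_start, te_end))
    return out


def extract_flanks(read: JunctionRead, flank: int = FLANK) -> dict[str, str]:
    """Up to two ``flank``-bp sequences adjacent to the TE interval.

    Flanks shorter than ``flank`` are dropped; a TE interval spanning the
    whole read is an upstream filtering failure and raises.
    """
    if read.te_start <= 0 and read.te_end >= len(read.sequence):
        raise ValueError("TE interval spans the whole read")
    flanks = {}
    if read.te_start >= flank:
        flanks["left"] = read.sequence[read.te_start - flank : read.te_start]
    if len(read.sequence) - read.te_end >= flank:
        flanks["right"] = read.sequence[read.te_end : read.te_end + flank]
    return flanks


def map_insertions(junction_reads: Sequence[JunctionRead],
                   genome: Mapping[str, str],
                   params: AlignmentParams | None = None,
                   flank: int = FLANK,
                   min_len: int = FLANK_MIN_LEN,
                   min_identity: float = FLANK_MIN_IDENTITY,
                   ref_aligner: ReferenceAligner | None = None) -> list[LongReadInsertion]:
    """Map junction-read flanks to the reference; unique placements only.

    The insertion position is the genome coordinate of the flank base
    adjacent to the TE.  When both flanks of a read place uniquely, one
    insertion is reported per read with flank_side='both' (positions agree
    up to the target-site duplication).
    """
    params = params or AlignmentParams()
    if ref_aligner is None:
        ref_aligner = ReferenceAligner(genome, params)
    out = []
    for jr in junction_reads:
        placements = {}
        for side, seq in extract_flanks(jr, flank).items():
            alns = ref_aligner.aligner.align(seq, min_len=min_len,
                                             min_identity=min_identity)
            if not alns:
                continue
            best = alns[0]
            if len(alns) > 1 and best.score - alns[1].score < params.score_margin:
                continue
            # flank base adjacent to the TE, accounting for strand
            if side == "left":
                pos = best.target_end - 1 if best.strand == "+" else best.target_start
            else:
                pos = best.target_start if best.strand == "+" else best.target_end - 1
            placements[side] = (best.target_id, int(pos))
        if not placements:
            continue
        if len(placements) == 2:
            chrom, pos = placements["left"]
            side = "both"
        else:
            (side, (chrom, pos)), = placements.items()
        out.append(LongReadInsertion(jr.read_id, jr.family_id, chrom, pos, side))
    return out


@dataclass
class ValidationSummary:
    tp: int
    fp: int
    fn: int
    sensitivity: float | None  # validated long-read loci / all long-read loci
    specificity: float | None  # validated TIPs / all TIPs
    n_tips: int
    n_longread_loci: int


def dedup_insertion_loci(insertions: Sequence[LongReadInsertion],
                         windows: WindowSet) -> set[tuple[str, str]]:
    """Collapse per-read insertions to (family, window) loci."""
    loci = set()
    for ins in insertions:
        w = windows.window_of(ins.chrom, ins.pos)
        loci.add((ins.family_id, w.window_id))
    return loci


def compare_callsets(tips: Sequence[tuple[str, str]],
                     insertions: Sequence[LongReadInsertion],
                     windows: WindowSet,
                     boundary_margin: int = 500) -> ValidationSummary:
    """Score short-read TIPs of one accession against long-read insertions.

    ``tips`` are (family_id, window_id) events.  Matching is per (family,
    window), with one concession to the 10-kb grid: paired-end support for a
    junction spreads up to about one insert size around it, so a short-read
    call for a junction sitting within ``boundary_margin`` bp of a window
    edge may land in the adjacent window.  A long-read insertion that close
    to an edge therefore snaps to the neighbouring window when that window
    (and not its own) was called.  Each insertion still contributes exactly
    one locus, so TP + FP equals the TIP count and TP + FN the
    de-duplicated long-read locus count, exactly.
    """
    tip_set = set(tips)
    lr_loci = set()
    for ins in insertions:
        w = windows.window_of(ins.chrom, ins.pos)
        key = (ins.family_id, w.window_id)
        if key not in tip_set and boundary_margin > 0:
            for edge_pos in (ins.pos - boundary_margin, ins.pos + boundary_margin):
                try:
                    w2 = windows.window_of(ins.chrom, edge_pos)
                except (ValueError, KeyError):
                    continue
                alt = (ins.family_id, w2.window_id)
                if alt in tip_set:
                    key = alt
                    break
        lr_loci.add(key)
    tp = len(tip_set & lr_loci)
    fp = len(tip_set - lr_loci)
    fn = len(lr_loci - tip_set)
    return ValidationSummary(
        tp=tp, fp=fp, fn=fn,
        sensitivity=tp / len(lr_loci) if lr_loci else None,
        specificity=tp / len(tip_set) if tip_set else None,
        n_tips=len(tip_set),
        n_longread_loci=len(lr_loci),
    )
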