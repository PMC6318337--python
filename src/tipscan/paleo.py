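"""Genomic paleontology: full-element discovery, LTR dating, orthology.

An LTR retrotransposon's two terminal repeats are identical at insertion
time and diverge afterwards at the neutral substitution rate, so the
identity between them is a molecular clock: ``age = (1 - identity) / (2 r)``
with r = 1.3e-8 substitutions/site/year.  Identity is the raw mismatch
fraction of the largest local alignment between the element's two halves
(no multiple-hit correction by default — printed divergences at these time
depths are small enough that the correction is well inside the noise; a
Jukes-Cantor option is available behind a flag).

Full elements are discovered in an assembly by searching with the family's
RT-domain probe (or any configured low-copy internal probe for non-coding
LARD-type families), extending each hit and requiring both LTRs.  Orthology
across assemblies is decided by anchoring 300 bp of upstream flank in the
other genome (single near-full-length hit required) and scanning the 15 kb
downstream of the anchor for a consensus match.  Presence/absence across
three genomes yields seven categories (three group-specific, three
pairwise-common, one common-to-all), optionally validated against panel
carrier frequencies (>= 60 % of the corresponding group for specific
insertions, >= 80 % of each implicated group for common ones).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentParams, SeedAligner, local_align
from .core import TEFamily, WindowSet
from .detect import TIPMatrix

MOLECULAR_CLOCK_RATE = 1.3e-8  # substitutions / site / year

CATEGORIES = (
    "Indica-specific", "Japonica-specific", "Aus-specific",
    "common-all", "common-IndJap", "common-IndAus", "common-JapAus",
)

GROUPS_OF_CATEGORY = {
    "Indica-specific": ("Indica",),
    "Japonica-specific": ("Japonica",),
    "Aus-specific": ("Aus/Boro",),
    "common-all": ("Indica", "Japonica", "Aus/Boro"),
    "common-IndJap": ("Indica", "Japonica"),
    "common-IndAus": ("Indica", "Aus/Boro"),
    "common-JapAus": ("Japonica", "Aus/Boro"),
}


@dataclass(frozen=True)
class FullElement:
    """A genomic LTR-retrotransposon copy with both terminal repeats."""

    genome_id: str
    family_id: str
    chrom: str
    start: int
    end: int
    ltr5: tuple[int, int]  # genome coordinates, half-open
    ltr3: tuple[int, int]
    ltr_identity: float | None = None

    def __post_init__(self):
        if not (self.start <= self.ltr5[0] < self.ltr5[1] <= self.ltr3[0]
                < self.ltr3[1] <= self.end):
            raise ValueError("LTR intervals inconsistent with element bounds")


@dataclass(frozen=True)
class DatedInsertion:
    element: FullElement
    identity: float
    age_years: float
    category: str | None = None
    validated: bool | None = None


# ---------------------------------------------------------------------------
# discovery


def find_paralogs(family: TEFamily, genome: Mapping[str, str],
                  params: AlignmentParams | None = None,
                  probe: tuple[int, int] | None = None,
                  min_len: int = 100, min_identity: float = 0.85) -> list[tuple[str, int, int]]:
    """Candidate element loci: significant RT-domain (probe) placements,
    merged when closer than one consensus length."""
    probe = probe or family.rt_domain
    if probe is None:
        raise ValueError(f"{family.family_id}: no rt_domain and no alternative probe")
    params = params or AlignmentParams()
    query = family.consensus[probe[0] : probe[1]]
    aligner = SeedAligner(dict(genome), params)
    alns = aligner.align(query, min_len=min_len, min_identity=min_identity)
    merged: list[list] = []
    span = len(family.consensus)
    for a in sorted(alns, key=lambda a: (a.target_id, a.target_start)):
        if merged and merged[-1][0] == a.target_id and a.target_start - merged[-1][2] < span:
            merged[-1][2] = max(merged[-1][2], a.target_end)
        else:
            merged.append([a.target_id, a.target_start, a.target_end])
    return [(c, s, e) for c, s, e in merged]


def recover_full_element(locus: tuple[str, int, int], family: TEFamily,
                         genome: Mapping[str, str], genome_id: str = "genome",
                         params: AlignmentParams | None = None,
                         extension: float = 1.5,
                         ltr_min_cov: float = 0.5,
                         ltr_min_identity: float = 0.85) -> FullElement | None:
    """Extend an RT locus and require both LTRs in the extended region.

    Extension is ``extension`` x consensus length on each side.  The element
    is trimmed to the outer bounds of the two best non-overlapping LTR hits;
    None when fewer than two qualifying LTR placements exist (solo LTRs,
    heavily truncated copies).
    """
    if family.ltr_length is None:
        return None
    params = params or AlignmentParams()
    chrom, s, e = locus
    seq = genome[chrom]
    ext = int(extension * len(family.consensus))
    rs = max(0, s - ext)
    re_ = min(len(seq), e + ext)
    region = seq[rs:re_]
    aligner = SeedAligner({"region": region}, params)
    min_len = int(ltr_min_cov * family.ltr_length)
    alns = [a for a in aligner.align(family.ltr5, min_len=min_len,
                                     min_identity=ltr_min_identity)
            if a.strand == "+"]
    if len(alns) < 2:
        return None
    # best pair of non-overlapping placements, outermost extent
    alns = sorted(alns, key=lambda a: a.target_start)
    first, last = alns[0], alns[-1]
    if first.target_end > last.target_start:
        return None
    return FullElement(
        genome_id=genome_id, family_id=family.family_id, chrom=chrom,
        start=rs + first.target_start, end=rs + last.target_end,
        ltr5=(rs + first.target_start, rs + first.target_end),
        ltr3=(rs + last.target_start, rs + last.target_end),
    )


def ltr_identity(element: FullElement, genome: Mapping[str, str],
                 params: AlignmentParams | None = None) -> float:
    """Identity of the largest local alignment between the element's halves.

    Only the LTRs align between the two halves of a trimmed element, so the
    largest HSP is the LTR-LTR alignment.
    """
    seq = genome[element.chrom][element.start : element.end]
    mid = len(seq) // 2
    half1, half2 = seq[:mid], seq[mid:]
    p = params or AlignmentParams(min_len=1, min_identity=0.0)
    alns = local_align(half1, half2, min_score=20, params=p)
    if not alns:
        raise ValueError("no alignment between element halves despite recovered LTRs")
    best = max(alns, key=lambda a: a.aln_length)
    return best.matches / best.aln_length


def date_insertion(identity: float, rate: float = MOLECULAR_CLOCK_RATE,
                   jukes_cantor: bool = False) -> float:
    """Molecular-clock age in years: ``(1 - identity) / (2 rate)``.

    Divergence is the raw mismatch fraction by default; ``jukes_cantor``
    applies the multiple-hit correction d = -3/4 ln(1 - 4p/3) first.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if not (0 <= identity <= 1):
        raise ValueError("identity must be in [0, 1]")
    d = 1.0 - identity
    if jukes_cantor and d > 0:
        d = -0.75 * math.log1p(-4.0 * d / 3.0)
    return d / (2.0 * rate)


# ---------------------------------------------------------------------------
# orthology


def find_ortholog(element: FullElement, source_genome: Mapping[str, str],
                  target_genome: Mapping[str, str], family: TEFamily,
                  params: AlignmentParams | None = None,
                  flank: int = 300, downstream: int = 15_000,
                  flank_min_cov: float = 0.90,
                  te_min_len: int = 100, te_min_identity: float = 0.85,
                  target_aligner: SeedAligner | None = None) -> str:
    """'present' / 'absent' / 'unresolved' at the orthologous locus.

    The 300-bp flank upstream of the element must produce exactly one hit
    covering >= 90 % of its length in the target; the 15 kb downstream of
    that anchor is then scanned for a consensus match.
    """
    params = params or AlignmentParams()
    src = source_genome[element.chrom]
    if element.start < flank:
        return "unresolved"
    probe = src[element.start - flank : element.start]
    if target_aligner is None:
        target_aligner = SeedAligner(dict(target_genome), params)
    min_len = int(flank_min_cov * flank)
    hits = target_aligner.align(probe, min_len=min_len, min_identity=0.85)
    hits = [h for h in hits if h.query_span >= flank_min_cov * flank]
    if len(hits) != 1:
        return "unresolved"
    h = hits[0]
    tseq = target_genome[h.target_id]
    if h.strand == "+":
        region = tseq[h.target_end : h.target_end + downstream]
    else:
        region = tseq[max(0, h.target_start - downstream) : h.target_start]
    if len(region) < te_min_len:
        return "absent"
    raligner = SeedAligner({"region": region}, params)
    te_hits = raligner.align(family.consensus, min_len=te_min_len,
                             min_identity=te_min_identity)
    return "present" if te_hits else "absent"


def classify_insertion(japonica: str, indica: str, aus: str) -> str:
    """Seven-way category from presence flags in the Japonica-type,
    Indica-type and Aus-type assemblies (in that order)."""
    flags = (japonica, indica, aus)
    for f in flags:
        if f not in ("present", "absent"):
            raise ValueError(f"flag must be present/absent, got {f!r}")
    p = tuple(f == "present" for f in flags)
    table = {
        (True, False, False): "Japonica-specific",
        (False, True, False): "Indica-specific",
        (False, False, True): "Aus-specific",
        (True, True, True): "common-all",
        (True, True, False): "common-IndJap",
        (False, True, True): "common-IndAus",
        (True, False, True): "common-JapAus",
    }
    if p == (False, False, False):
        raise ValueError("element absent from all three genomes")
    return table[p]


def validate_category(element: FullElement, category: str, matrix: TIPMatrix,
                      groups: Mapping[str, str], windows: WindowSet,
                      specific_threshold: float = 0.6,
                      common_threshold: float = 0.8) -> tuple[bool, str]:
    """Check a category against panel carrier frequencies.

    Specific categories need carrier frequency >= 60 % in the corresponding
    varietal group; common categories >= 80 % in each implicated group.  The
    element is matched to the matrix row whose window contains its start.
    Returns (validated, reason).
    """
    try:
        w = windows.window_of(element.chrom, element.start)
    except (KeyError, ValueError):
        return False, "no panel evidence"
    key = (element.family_id, w.window_id)
    if key not in matrix.df.index:
        return False, "no panel evidence"
    row = matrix.df.loc[key]
    implicated = GROUPS_OF_CATEGORY[category]
    thr = specific_threshold if len(implicated) == 1 else common_threshold
    for grp in implicated:
        accs = [a for a in matrix.df.columns if groups.get(a) == grp]
        if not accs:
            return False, f"no accessions in group {grp}"
        freq = float(row[accs].sum()) / len(accs)
        if freq < thr:
            return False, f"frequency {freq:.2f} < {thr} in {grp}"
    return True, "ok"


def category_age_distributions(dated: Sequence[DatedInsertion],
                               validated_only: bool = True) -> pd.DataFrame:
    """Median and quartiles of LTR identity and age per category."""
    rows = []
    for d in dated:
        if d.category is None:
            continue
        if validated_only and not d.validated:
            continue
        rows.append((d.category, d.identity, d.age_years))
    df = pd.DataFrame(rows, columns=["category", "identity", "age_years"])
    if df.empty:
        return pd.DataFrame(columns=["category", "n", "identity_median",
                                     "identity_q1", "identity_q3",
                                     "age_median", "age_q1", "age_q3"])
    g = df.groupby("category")
    out = pd.DataFrame({
        "n": g.size(),
        "identity_median": g["identity"].median(),
        "identity_q1": g["identity"].quantile(0.25),
        "identity_q3": g["identity"].quantile(0.75),
        "age_median": g["age_years"].median(),
        "age_q1": g["age_years"].quantile(0.25),
        "age_q3": g["age_years"].quantile(0.75),
    })
    return out.reset_index()
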