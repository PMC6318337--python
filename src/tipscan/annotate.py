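"""Downstream summaries of a presence/absence matrix.

Insertion frequencies within an accession subset, per-family frequency
spectra, a declared (configurable) activity-class heuristic, window-to-gene
distances, and the copy-number phenotype table consumed by external GWAS
tools (one quantitative phenotype per family: the number of insertions an
accession carries).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GeneRecord
from .detect import TIPMatrix


@dataclass
class FrequencySpectrum:
    """Per-event carrier frequencies within a chosen accession subset."""

    frequencies: pd.DataFrame  # family_id, window_id, carriers, frequency
    subset_size: int
    bin_edges: np.ndarray

    def histogram(self, family_id: str | None = None) -> pd.DataFrame:
        df = self.frequencies
        if family_id is not None:
            df = df[df["family_id"] == family_id]
        counts, edges = np.histogram(df["frequency"], bins=self.bin_edges)
        return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                             "count": counts})

    def families(self) -> list[str]:
        return sorted(self.frequencies["family_id"].unique())


def tip_frequencies(matrix: TIPMatrix, subset: Sequence[str] | None = None,
                    bin_edges: Sequence[float] | None = None) -> FrequencySpectrum:
    """Carrier frequency of every event among ``subset`` accessions.

    Events with zero carriers in the subset are dropped, so frequencies lie
    in (0, 1]; carriers * subset size stays an exact integer count.
    """
    cols = list(matrix.df.columns)
    if subset is None:
        subset = cols
    subset = list(subset)
    if not subset:
        raise ValueError("empty accession subset")
    missing = set(subset) - set(cols)
    if missing:
        raise ValueError(f"accessions not in matrix: {sorted(missing)}")
    sub = matrix.df[subset]
    carriers = sub.sum(axis=1).astype(int)
    keep = carriers > 0
    df = pd.DataFrame({
        "family_id": [f for f, w in sub.index[keep]],
        "window_id": [w for f, w in sub.index[keep]],
        "carriers": carriers[keep].to_numpy(),
    })
    df["frequency"] = df["carriers"] / len(subset)
    edges = np.asarray(bin_edges if bin_edges is not None
                       else np.concatenate([[0.0, 0.01, 0.05], np.arange(0.1, 1.05, 0.1)]))
    return FrequencySpectrum(df, len(subset), edges)


def classify_activity(frequencies: Sequence[float],
                      recent_cut: float = 0.05, recent_frac: float = 0.80,
                      old_cut: float = 0.5, old_frac: float = 0.50) -> str:
    """Heuristic transpositional-history class from a family's spectrum.

    Recent: an L-shaped spectrum, >= ``recent_frac`` of events below
    ``recent_cut``; Old: strictly more than ``old_frac`` of events above
    ``old_cut`` (strict, so an even spread stays Continuous); Continuous
    otherwise.  The thresholds are an explicit, configurable heuristic, not
    an inferred biological constant.
    """
    f = np.asarray(list(frequencies), dtype=float)
    if f.size == 0:
        raise ValueError("no events for family")
    if np.mean(f < recent_cut) >= recent_frac:
        return "Recent"
    if np.mean(f > old_cut) > old_frac:
        return "Old"
    return "Continuous"


def distance_to_gene(window_id: str, genes: Sequence[GeneRecord]) -> int | None:
    """Minimum gap (bp) between a TIP window and any gene; 0 when overlapping.

    Distances are window-to-gene at 10-kb resolution, not breakpoint-based.
    Returns None when the window's chromosome has no annotated gene.
    """
    chrom, rest = window_id.split(":")
    ws, we = (int(x) for x in rest.split("-"))
    best: int | None = None
    for g in genes:
        if g.chrom != chrom:
            continue
        if g.end <= ws:
            d = ws - g.end
        elif g.start >= we:
            d = g.start - we
        else:
            d = 0
        if best is None or d < best:
            best = d
    return best


def distances_table(matrix: TIPMatrix, genes: Sequence[GeneRecord],
                    families: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Distance to the nearest gene for every event; optional superfamily tag."""
    rows = []
    for fam, win in matrix.df.index:
        d = distance_to_gene(win, genes)
        rows.append((fam, win, d,
                     families.get(fam, "other") if families else "other"))
    return pd.DataFrame(rows, columns=["family_id", "window_id",
                                       "distance_bp", "superfamily"])


def copy_number_phenotype(matrix: TIPMatrix) -> pd.DataFrame:
    """Insertion count per (accession, family): the GWAS quantitative phenotype.

    Exact row-sum semantics — the table's grand total equals the number of
    1-cells in the matrix.
    """
    if matrix.df.empty:
        fams = sorted({f for f, _ in matrix.df.index})
        return pd.DataFrame(0, index=matrix.df.columns, columns=fams, dtype=int)
    out = matrix.df.groupby(level="family_id").sum().T
    out.index.name = "accession_id"
    return out.astype(int)


@dataclass
class GroupCompareResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    degenerate: bool


def group_compare_distance(dist_a: Sequence[float],
                           dist_b: Sequence[float]) -> GroupCompareResult:
    """Welch two-sample t test between two gene-distance vectors
    (e.g. Gypsy vs Copia superfamilies)."""
    a = np.asarray(list(dist_a), dtype=float)
    b = np.asarray(list(dist_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    degenerate = bool(np.var(a) == 0 and np.var(b) == 0)
    if degenerate and np.mean(a) == np.mean(b):
        return GroupCompareResult(0.0, 1.0, len(a), len(b),
                                  float(a.mean()), float(b.mean()), True)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return GroupCompareResult(float(t), float(p), len(a), len(b),
                              float(a.mean()), float(b.mean()), degenerate)
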