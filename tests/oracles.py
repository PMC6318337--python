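"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's seed-and-extend machinery: placements
are enumerated exhaustively through a sorted array of *all* 32-mers of the
genome and its reverse complement, then re-scored by literal gapless
comparison.  On genomes whose duplications are exact copies (the simulator's
reference class), every >=80-bp placement at >=95 % identity contains an
exact 32-mer, so the enumeration is complete.
"""

from __future__ import annotations

import numpy as np

from tipscan.align import encode, kmer_codes, revcomp

K_ORACLE = 32
MATCH, MISMATCH = 1, -2


def _kadane_best(cmp: np.ndarray) -> tuple[int, int, int]:
    """(start, end, score) of the maximal +1/-2 segment (plain Python)."""
    best, cur, cur_start = 0, 0, 0
    seg = (0, 0)
    for i, ok in enumerate(cmp):
        if cur <= 0:
            cur, cur_start = 0, i
        cur += MATCH if ok else MISMATCH
        if cur > best:
            best, seg = cur, (cur_start, i + 1)
    return seg[0], seg[1], best


def _qualifies(cmp: np.ndarray, min_len: int, min_identity: float) -> bool:
    n = len(cmp)
    if n < min_len:
        return False
    c = np.cumsum(np.concatenate([[0], cmp.astype(np.int64)]))
    for L in range(min_len, n + 1):
        allowed = int(L * (1 - min_identity))
        if np.any(L - (c[L:] - c[:-L]) <= allowed):
            return True
    return False


class BruteForcePlacer:
    """Exhaustive placement enumeration for queries against one genome."""

    def __init__(self, genome: dict[str, str]):
        self.chroms = list(genome)
        self.seqs = {c: encode(s) for c, s in genome.items()}
        self.rc_seqs = {c: encode(revcomp(s)) for c, s in genome.items()}
        codes_all, meta = [], []
        for ci, c in enumerate(self.chroms):
            for strand, arr in ((0, self.seqs[c]), (1, self.rc_seqs[c])):
                codes, valid = kmer_codes(arr, K_ORACLE)
                idx = np.nonzero(valid)[0]
                codes_all.append(codes[idx])
                m = np.empty((len(idx), 3), dtype=np.int64)
                m[:, 0], m[:, 1], m[:, 2] = ci, strand, idx
                meta.append(m)
        codes_cat = np.concatenate(codes_all)
        meta_cat = np.concatenate(meta)
        order = np.argsort(codes_cat, kind="stable")
        self.codes = codes_cat[order]
        self.meta = meta_cat[order]

    def placements(self, query: str, min_len: int = 80,
                   min_identity: float = 0.95) -> list[tuple]:
        """All qualifying placements as (chrom, strand, fwd_pos, score),
        deduplicated by (chrom, strand, diagonal) before scoring.  The
        query's own locus, if in the genome, is included like any other."""
        q = encode(query)
        codes, valid = kmer_codes(q, K_ORACLE)
        lo = np.searchsorted(self.codes, codes, side="left")
        hi = np.searchsorted(self.codes, codes, side="right")
        cands = set()
        for qi in np.nonzero(valid)[0]:
            for j in range(lo[qi], hi[qi]):
                ci, strand, tpos = self.meta[j]
                cands.add((int(ci), int(strand), int(tpos) - int(qi)))
        out = []
        for ci, strand, diag in sorted(cands):
            chrom = self.chroms[ci]
            t = self.seqs[chrom] if strand == 0 else self.rc_seqs[chrom]
            a = max(0, -diag)
            b = min(len(q), len(t) - diag)
            if b - a < min_len:
                continue
            cmp = (q[a:b] == t[diag + a : diag + b]) & (q[a:b] < 4)
            s, e, score = _kadane_best(cmp)
            seg = cmp[s:e]
            ok = (e - s >= min_len and seg.sum() / max(e - s, 1) >= min_identity) \
                or _qualifies(cmp, min_len, min_identity)
            if not ok:
                continue
            # report position on the forward strand of the chromosome
            if strand == 0:
                fwd_pos = diag + a + s
            else:
                fwd_pos = len(t) - (diag + a + e)
            out.append((chrom, "+-"[strand], int(fwd_pos), int(score)))
        return out

    def uniqueness(self, query: str, min_len: int = 80,
                   min_identity: float = 0.95, score_margin: int = 10) -> str:
        """Uniqueness verdict under the same declared rule as the aligner,
        but with exhaustively enumerated placements."""
        pl = self.placements(query, min_len=min_len, min_identity=min_identity)
        if not pl:
            return "none"
        scores = sorted((p[3] for p in pl), reverse=True)
        if len(scores) == 1:
            return "unique"
        if scores[0] - scores[1] >= score_margin:
            return "unique"
        return "ambiguous"


def brute_force_mappability(genome: dict[str, str], windows,
                            tile: int = 100) -> dict[str, float]:
    """Per-window unique-tile fraction by exhaustive placement counting."""
    placer = BruteForcePlacer(genome)
    track = {}
    for w in windows:
        seq = genome[w.chrom][w.start : w.end]
        tiles = [seq[i : i + tile] for i in range(0, len(seq) - tile + 1, tile)]
        if not tiles:
            track[w.window_id] = 0.0
            continue
        n_unique = sum(placer.uniqueness(t) == "unique" for t in tiles)
        track[w.window_id] = n_unique / len(tiles)
    return track


def brute_force_min_gene_distance(window, genes) -> int | None:
    """Naive pairwise minimum gap between a window interval and genes."""
    best = None
    for g in genes:
        if g.chrom != window[0]:
            continue
        ws, we = window[1], window[2]
        d = 0 if (g.start < we and g.end > ws) else \
            (ws - g.end if g.end <= ws else g.start - we)
        if best is None or d < best:
            best = d
    return best
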