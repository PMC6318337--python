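"""Seed-and-extend local alignment used by every stage of the toolkit.

The aligner matches Illumina-length queries (and long-read flanks) against a
set of target sequences: exact k-mer seeding on a sorted-array index, seeds
grouped into diagonal clusters, then either gapless extension (substitution
only, scored match +1 / mismatch -2) or a banded edit-distance extension
(edlib) when seeds spread over several diagonals, i.e. when indels are
present.  Significance is a length-and-identity gate rather than an e-value:
an alignment qualifies when it covers at least ``min_len`` bases of the query
at ``min_identity`` or better.  E-values depend on database size, so a fixed
gate keeps the behaviour identical across genomes of different sizes; the
defaults (80 bp at 95 % identity) are chosen to be the short-read anchoring
regime and are configurable everywhere.

Uniqueness of a placement follows a best-versus-second rule: a hit is unique
when it passes the gate and either no second placement passes, or the best
score beats the runner-up by ``score_margin`` (default 10).  The margin
tolerates micro-homology at repeat edges without declaring the whole read
ambiguous.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

try:
    import edlib
except ImportError:  # pragma: no cover - edlib is a hard dependency
    edlib = None

# ---------------------------------------------------------------------------
# base-level encoding

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i  # lowercase

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3, other -> 4)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return _DECODE[np.minimum(arr, 4)].tobytes().decode("ascii")


def revcomp_u8(arr: np.ndarray) -> np.ndarray:
    rc = arr[::-1]
    return np.where(rc < 4, 3 - rc, rc).astype(np.uint8)


def revcomp(seq: str) -> str:
    return decode(revcomp_u8(encode(seq)))


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit pack every k-mer of ``arr`` into uint64 codes.

    Returns ``(codes, valid)`` where ``valid[i]`` is False when the window
    starting at ``i`` contains a non-ACGT base.  Requires ``k <= 31``.
    """
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | (arr[j : j + n] & np.uint8(3)).astype(np.uint64)
    bad = np.cumsum(np.concatenate([[0], (arr >= 4).astype(np.int64)]))
    valid = (bad[k:] - bad[:-k]) == 0
    return codes, valid


# ---------------------------------------------------------------------------
# alignment records


@dataclass(frozen=True)
class LocalAlignment:
    """One local alignment (the HSP of classic BLAST terminology)."""

    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str  # '+' or '-'
    matches: int
    aln_length: int
    score: int

    @property
    def identity(self) -> float:
        return self.matches / self.aln_length if self.aln_length else 0.0

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


@dataclass(frozen=True)
class AnchorHit:
    """Placement of a read on the reference: unique, ambiguous or none."""

    accession_id: str
    family_id: str
    chrom: str | None
    pos: int | None
    uniqueness: str  # 'unique' | 'ambiguous' | 'none'


@dataclass
class AlignmentParams:
    """Gate and scoring constants shared across the pipeline.

    min_len/min_identity form the significance gate standing in for a fixed
    e-value cut-off; score_margin implements the uniqueness rule.
    """

    k: int = 21
    min_len: int = 80
    min_identity: float = 0.95
    score_margin: int = 10
    max_kmer_occ: int = 256
    diag_band: int = 24
    match: int = 1
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -1


_CIG_RE = re.compile(r"(\d+)([=XIDM])")


def _calibrate_cigar_ops() -> tuple[str, str]:
    """Determine which cigar letters consume query vs target bases.

    Edlib's I/D convention is fixed but easy to misremember; one tiny
    alignment at import time pins it down unambiguously.
    """
    if edlib is None:  # pragma: no cover
        return "=XI", "=XD"
    res = edlib.align("ACGTACGT", "ACGTTTACGT", mode="NW", task="path")
    ops = _CIG_RE.findall(res["cigar"])
    # the 2-base gap op consumes target only
    gap_op = next(op for n, op in ops if op in "ID" and int(n) == 2)
    if gap_op == "D":
        return "=XI", "=XD"  # D consumes target
    return "=XD", "=XI"


_Q_OPS, _T_OPS = _calibrate_cigar_ops()


def _kadane(cmp: np.ndarray, match: int, mismatch: int) -> tuple[int, int, int, int]:
    """Best-scoring contiguous segment of a match/mismatch vector.

    Returns (start, end, score, matches) of the maximal segment under
    +match/-|mismatch| scoring (gapless Smith-Waterman on one diagonal).
    """
    best = 0
    best_seg = (0, 0)
    cur = 0
    cur_start = 0
    vals = np.where(cmp, match, mismatch)
    for i in range(len(vals)):
        if cur <= 0:
            cur = 0
            cur_start = i
        cur += vals[i]
        if cur > best:
            best = cur
            best_seg = (cur_start, i + 1)
    s, e = best_seg
    m = int(np.count_nonzero(cmp[s:e]))
    return s, e, int(best), m


def _qualifying_window(cmp: np.ndarray, min_len: int, min_identity: float) -> tuple[int, int] | None:
    """Any window of length >= min_len with identity >= min_identity, if one exists.

    Fallback used when the best-scoring segment fails the gate but a shorter
    qualifying stretch may still exist on the same diagonal.
    """
    n = len(cmp)
    if n < min_len:
        return None
    c = np.cumsum(np.concatenate([[0], cmp.astype(np.int64)]))
    for L in range(min_len, min(n, int(min_len * 1.25)) + 1):
        allowed = int(L * (1 - min_identity))
        mism = (np.arange(n - L + 1) * 0 + L) - (c[L:] - c[:-L])
        idx = np.nonzero(mism <= allowed)[0]
        if len(idx):
            return int(idx[0]), int(idx[0]) + L
    return None


class KmerIndex:
    """Sorted-array exact k-mer index over a set of target sequences."""

    def __init__(self, names: Sequence[str], seqs: Sequence[np.ndarray], k: int = 21):
        if k < 8 or k > 31:
            raise ValueError("k must be in [8, 31]")
        self.k = k
        self.names = list(names)
        self.seqs = [np.ascontiguousarray(s, dtype=np.uint8) for s in seqs]
        self.lengths = np.array([len(s) for s in self.seqs], dtype=np.int64)
        gaps = np.full(k, 4, dtype=np.uint8)
        parts: list[np.ndarray] = []
        starts = []
        off = 0
        for s in self.seqs:
            starts.append(off)
            parts.append(s)
            parts.append(gaps)
            off += len(s) + k
        self.starts = np.array(starts, dtype=np.int64)
        cat = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        codes, valid = kmer_codes(cat, k)
        idx = np.nonzero(valid)[0]
        order = np.argsort(codes[idx], kind="stable")
        self._codes = codes[idx][order]
        self._gpos = idx[order]

    def occurrences(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self._codes, codes, side="left")
        hi = np.searchsorted(self._codes, codes, side="right")
        return lo, hi

    def contains_any(self, codes: np.ndarray, valid: np.ndarray) -> bool:
        lo, hi = self.occurrences(codes)
        return bool(np.any((hi > lo) & valid))

    def seed_hits(self, codes: np.ndarray, valid: np.ndarray, max_occ: int) -> tuple[np.ndarray, np.ndarray]:
        """(query_pos, global_target_pos) pairs for every indexed occurrence."""
        lo, hi = self.occurrences(codes)
        occ = hi - lo
        use = valid & (occ > 0) & (occ <= max_occ)
        which = np.nonzero(use)[0]
        if len(which) == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qpos = np.repeat(which, occ[which])
        slices = [self._gpos[lo[i] : hi[i]] for i in which]
        gpos = np.concatenate(slices)
        return qpos.astype(np.int64), gpos.astype(np.int64)

    def locate(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        seq_i = np.searchsorted(self.starts, gpos, side="right") - 1
        return seq_i, gpos - self.starts[seq_i]


class SeedAligner:
    """Local alignment of queries against an indexed target set.

    Targets are indexed on both strands internally; hit coordinates are
    always reported on the forward strand of the target, with ``strand``
    recording the query orientation.
    """

    def __init__(self, targets: Mapping[str, str] | Mapping[str, np.ndarray],
                 params: AlignmentParams | None = None):
        self.params = params or AlignmentParams()
        names = []
        seqs = []
        self._fwd_n = len(targets)
        for name, seq in targets.items():
            names.append(name)
            seqs.append(seq if isinstance(seq, np.ndarray) else encode(seq))
        for name, seq in zip(list(names), list(seqs)):
            names.append(name)
            seqs.append(revcomp_u8(seq))
        self.index = KmerIndex(names, seqs, k=self.params.k)

    # -- internals ---------------------------------------------------------

    def _gapless(self, q: np.ndarray, t: np.ndarray, diag: int,
                 min_len: int, min_identity: float) -> tuple | None:
        a = max(0, -diag)
        b = min(len(q), len(t) - diag)
        if b - a <= 0:
            return None
        cmp = (q[a:b] == t[diag + a : diag + b]) & (q[a:b] < 4)
        s, e, score, m = _kadane(cmp, self.params.match, self.params.mismatch)
        seg_len = e - s
        if seg_len < min_len or (seg_len and m / seg_len < min_identity):
            # the maximal-score segment can fail the gate while a shorter
            # qualifying stretch exists on the same diagonal
            w = _qualifying_window(cmp, min_len, min_identity)
            if w is not None:
                s, e = w
                m = int(np.count_nonzero(cmp[s:e]))
                score = m * self.params.match + (e - s - m) * self.params.mismatch
        if e <= s:
            return None
        qs, qe = a + s, a + e
        return qs, qe, diag + qs, diag + qe, m, e - s, score

    def _banded(self, q: np.ndarray, t: np.ndarray, qlo: int, qhi: int,
                tlo: int, thi: int) -> tuple | None:
        if edlib is None:  # pragma: no cover
            raise RuntimeError("edlib is required for gapped extension")
        pad = 16 + (qhi - qlo) // 10
        # extend the seed span outward a little; terminal junk is trimmed below
        qs = max(0, qlo - pad)
        qe = min(len(q), qhi + pad)
        ts = max(0, tlo - 2 * pad)
        te = min(len(t), thi + 2 * pad)
        qsub = decode(q[qs:qe])
        tsub = decode(t[ts:te])
        if len(qsub) <= len(tsub):
            res = edlib.align(qsub, tsub, mode="HW", task="path")
            swapped = False
        else:
            res = edlib.align(tsub, qsub, mode="HW", task="path")
            swapped = True
        if res["editDistance"] < 0 or not res.get("cigar"):
            return None
        loc = res["locations"][0]
        ops = [(int(n), op) for n, op in _CIG_RE.findall(res["cigar"])]
        # trim low-scoring ends (recovers local semantics from semi-global edlib)
        trimmed = self._trim_ops(ops)
        if trimmed is None:
            return None
        ops, q_trim_l, t_trim_l = trimmed
        m = sum(n for n, op in ops if op == "=")
        aln_len = sum(n for n, op in ops)
        x = sum(n for n, op in ops if op == "X")
        score = m * self.params.match + x * self.params.mismatch
        for n, op in ops:
            if op in "ID":
                score += self.params.gap_open + (n - 1) * self.params.gap_extend
        q_span = sum(n for n, op in ops if op in _Q_OPS)
        t_span = sum(n for n, op in ops if op in _T_OPS)
        if swapped:
            # edlib query was the target sub-sequence
            t0 = ts + q_trim_l
            q0 = qs + loc[0] + t_trim_l
        else:
            q0 = qs + q_trim_l
            t0 = ts + loc[0] + t_trim_l
        if swapped:
            q_span, t_span = t_span, q_span
        return q0, q0 + q_span, t0, t0 + t_span, m, aln_len, score

    def _trim_ops(self, ops):
        """Maximal-score run of cigar operations (drops low-scoring ends).

        Recovers local-alignment semantics at run granularity from edlib's
        semi-global alignment.  Returns (kept_ops, q_trim, t_trim) where the
        trims count edlib-query / edlib-target bases dropped at the front.
        """
        if not ops:
            return None
        score_of = {"=": self.params.match, "X": self.params.mismatch}

        def run_score(n, op):
            if op in "ID":
                return self.params.gap_open + (n - 1) * self.params.gap_extend
            return n * score_of.get(op, self.params.mismatch)

        prefix = [0]
        for n, op in ops:
            prefix.append(prefix[-1] + run_score(n, op))
        best = None
        best_i = best_j = 0
        min_pref, min_i = 0, 0
        for j in range(1, len(prefix)):
            val = prefix[j] - min_pref
            if best is None or val > best:
                best, best_i, best_j = val, min_i, j
            if prefix[j] < min_pref:
                min_pref, min_i = prefix[j], j
        if best is None or best <= 0 or best_j <= best_i:
            return None
        kept = ops[best_i:best_j]
        q_trim = sum(n for n, op in ops[:best_i] if op in _Q_OPS)
        t_trim = sum(n for n, op in ops[:best_i] if op in _T_OPS)
        return kept, q_trim, t_trim

    def _clusters(self, qpos, gpos):
        seq_i, tpos = self.index.locate(gpos)
        diag = tpos - qpos
        order = np.lexsort((qpos, diag, seq_i))
        seq_i, tpos, qpos, diag = seq_i[order], tpos[order], qpos[order], diag[order]
        out = []
        start = 0
        n = len(diag)
        for i in range(1, n + 1):
            if (
                i == n
                or seq_i[i] != seq_i[start]
                or diag[i] - diag[i - 1] > self.params.diag_band
            ):
                out.append((int(seq_i[start]),
                            qpos[start:i], tpos[start:i], diag[start:i]))
                start = i
        return out

    # -- public ------------------------------------------------------------

    def align(self, query: str | np.ndarray, query_id: str = "query",
              min_len: int | None = None, min_identity: float | None = None,
              gate: bool = True) -> list[LocalAlignment]:
        """All gate-passing local alignments of ``query``, best score first."""
        q = query if isinstance(query, np.ndarray) else encode(query)
        p = self.params
        min_len = p.min_len if min_len is None else min_len
        min_identity = p.min_identity if min_identity is None else min_identity
        codes, valid = kmer_codes(q, p.k)
        qpos, gpos = self.index.seed_hits(codes, valid, p.max_kmer_occ)
        if len(qpos) == 0:
            return []
        results: list[LocalAlignment] = []
        for seq_i, cq, ct, cd in self._clusters(qpos, gpos):
            t = self.index.seqs[seq_i]
            if cd.min() == cd.max():
                r = self._gapless(q, t, int(cd[0]), min_len, min_identity)
            else:
                r = self._banded(q, t, int(cq.min()), int(cq.max()) + p.k,
                                 int(ct.min()), int(ct.max()) + p.k)
            if r is None:
                continue
            qs, qe, ts, te, m, aln_len, score = r
            if gate and (aln_len < min_len or (aln_len and m / aln_len < min_identity)):
                continue
            if aln_len == 0 or score <= 0:
                continue
            name = self.index.names[seq_i]
            if seq_i >= self._fwd_n:
                # hit on the reverse-complement copy: report forward target
                # coords; query coords stay in the query's own orientation
                L = int(self.index.lengths[seq_i])
                ts, te = L - te, L - ts
                strand = "-"
            else:
                strand = "+"
            results.append(LocalAlignment(query_id, name, int(qs), int(qe),
                                          int(ts), int(te), strand, int(m),
                                          int(aln_len), int(score)))
        results = self._dedup(results)
        results.sort(key=lambda a: (-a.score, a.target_id, a.target_start, a.strand))
        return results

    @staticmethod
    def _dedup(alns: list[LocalAlignment]) -> list[LocalAlignment]:
        """Drop re-discoveries of the same placement: alignments overlapping
        a better one heavily on BOTH query and target.  Distinct placements
        (different target loci, or repeated query content hitting the same
        target region) are kept."""
        kept: list[LocalAlignment] = []
        for a in sorted(alns, key=lambda x: -x.score):
            dup = False
            for b in kept:
                if a.target_id != b.target_id or a.strand != b.strand:
                    continue
                t_ov = min(a.target_end, b.target_end) - max(a.target_start, b.target_start)
                q_ov = min(a.query_end, b.query_end) - max(a.query_start, b.query_start)
                t_min = min(a.target_end - a.target_start, b.target_end - b.target_start)
                q_min = min(a.query_end - a.query_start, b.query_end - b.query_start)
                if t_ov > 0.5 * t_min and q_ov > 0.5 * q_min:
                    dup = True
                    break
            if not dup:
                kept.append(a)
        return kept


def local_align(query: str, target: str, min_score: int = 20,
                params: AlignmentParams | None = None) -> list[LocalAlignment]:
    """Generic local alignment of one query against one target.

    Convenience wrapper building a throwaway index; alignments are returned
    sorted by score (descending) and filtered at ``min_score`` only — no
    length/identity gate is applied here.
    """
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    p = params or AlignmentParams(min_len=1, min_identity=0.0)
    aligner = SeedAligner({"target": target}, p)
    alns = aligner.align(query, gate=False)
    return [a for a in alns if a.score >= min_score]


# ---------------------------------------------------------------------------
# read-level operations


class TEAligner:
    """Read-vs-TE-family matching over a consensus library."""

    def __init__(self, library, params: AlignmentParams | None = None,
                 min_len: int = 50, min_identity: float = 0.90):
        # families indexed by consensus; a read maps to the best-scoring family
        self.params = params or AlignmentParams()
        self.min_len = min_len
        self.min_identity = min_identity
        fams = list(library)
        if not fams:
            raise ValueError("empty TE library")
        self.families = {f.family_id: f for f in fams}
        if len(self.families) != len(fams):
            raise ValueError("duplicate family_id in library")
        self.aligner = SeedAligner({f.family_id: f.consensus for f in fams}, self.params)

    def best_family(self, read: str | np.ndarray) -> tuple[str | None, bool]:
        """(family_id, multi_family_flag) of the best qualifying alignment.

        Ties on score are broken toward the lexicographically smallest
        family_id and flagged, so the result is deterministic.
        """
        alns = self.aligner.align(read, min_len=self.min_len,
                                  min_identity=self.min_identity)
        if not alns:
            return None, False
        best = alns[0].score
        top = sorted({a.target_id for a in alns if a.score == best})
        return top[0], len(top) > 1


def map_read_to_te(read: str, te_aligner: TEAligner) -> str | None:
    """Family of the best qualifying read-vs-consensus alignment, or None."""
    fam, _ = te_aligner.best_family(read)
    return fam


class ReferenceAligner:
    """Unique anchoring of reads onto the reference genome."""

    def __init__(self, genome: Mapping[str, str], params: AlignmentParams | None = None):
        self.params = params or AlignmentParams()
        self.aligner = SeedAligner(dict(genome), self.params)

    def anchor(self, read: str | np.ndarray, accession_id: str = "",
               family_id: str = "") -> AnchorHit:
        """Place a read; unique only under the best-vs-second margin rule."""
        alns = self.aligner.align(read)
        if not alns:
            return AnchorHit(accession_id, family_id, None, None, "none")
        best = alns[0]
        if len(alns) > 1 and best.score - alns[1].score < self.params.score_margin:
            return AnchorHit(accession_id, family_id, None, None, "ambiguous")
        return AnchorHit(accession_id, family_id, best.target_id,
                         best.target_start, "unique")


def anchor_to_genome(read: str, ref_aligner: ReferenceAligner,
                     accession_id: str = "", family_id: str = "") -> AnchorHit:
    return ref_aligner.anchor(read, accession_id, family_id)


# ---------------------------------------------------------------------------
# batch k-mer screening (hot path of the detector)


def batch_te_candidates(reads: Iterable[str], te_aligner: TEAligner) -> np.ndarray:
    """Boolean mask over ``reads``: True when a read shares >=1 exact k-mer
    with any consensus (either strand).  A cheap necessary condition used to
    avoid aligning the overwhelmingly genomic majority of a library."""
    k = te_aligner.params.k
    idx = te_aligner.aligner.index
    parts = []
    offsets = [0]
    gap = np.full(k, 4, dtype=np.uint8)
    total = 0
    for r in reads:
        e = encode(r)
        parts.append(e)
        parts.append(gap)
        total += len(e) + k
        offsets.append(total)
    n_reads = len(parts) // 2
    if n_reads == 0:
        return np.empty(0, dtype=bool)
    cat = np.concatenate(parts)
    codes, valid = kmer_codes(cat, k)
    lo, hi = idx.occurrences(codes)
    present = ((hi > lo) & valid)
    # pad so that reduceat slices line up with read boundaries
    present = np.concatenate([present, np.zeros(len(cat) - len(present), dtype=bool)])
    starts = np.array(offsets[:-1], dtype=np.int64)
    out = np.maximum.reduceat(present.astype(np.int8), starts)
    return out.astype(bool)
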