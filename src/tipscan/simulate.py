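"""Ground-truth simulation: reference, accession panels, and reads.

The generator emulates a rice-like short-read panel at desk scale: an i.i.d.
background genome of configurable GC content with planted duplicated blocks
(so that mappability is genuinely heterogeneous, echoing the ~40 % repeat
content of the real genome), a panel of accessions carrying full-length
LTR-retrotransposon insertions at population frequencies drawn from an
L-shaped law (most insertions private or nearly so), and paired-end /
long-read sets with uniform sequencing error.  Every generator is
deterministic for a given seed and all truth is recorded in reference
coordinates.

Default study conditions used throughout the test-bench: 12 accessions, a
2-Mb reference at 40 % planted repeats, two LTR families, 60 insertion loci,
15x 2x100-bp paired reads with 0.5 % substitution error and 350+-50-bp
inserts, long reads at 11x with log-normal lengths (median 8 kb).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import TEFamily, WindowSet, make_windows
from .align import encode, decode, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

MOLECULAR_CLOCK_RATE = 1.3e-8  # substitutions / site / year


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_sequence(length: int, rng, gc: float = 0.44) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = _rng(rng).choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def mutate(seq: str, per_site_prob: float, rng) -> str:
    """Independent per-site substitution to a uniformly-chosen other base."""
    rng = _rng(rng)
    arr = encode(seq).copy()
    hit = np.nonzero(rng.random(len(arr)) < per_site_prob)[0]
    if len(hit):
        shift = rng.integers(1, 4, size=len(hit)).astype(np.uint8)
        arr[hit] = (arr[hit] + shift) % 4
    return decode(arr)


# ---------------------------------------------------------------------------
# TE library


def synthetic_te_library(rng=0, *, n_ltr_families: int = 2) -> list[TEFamily]:
    """A small consensus library of full-length LTR retrotransposons.

    Each consensus is LTR + internal + LTR with identical terminal repeats
    (age zero) and an annotated RT-domain interval in the internal region.
    """
    rng = _rng(rng)
    sizes = [(5000, 800), (4000, 600), (6000, 1000), (4500, 700)]
    supers = ["Gypsy", "Copia", "Gypsy", "Copia"]
    names = ["gypsy1", "copia1", "gypsy2", "copia2"]
    fams = []
    for i in range(n_ltr_families):
        total, ltr = sizes[i % len(sizes)]
        ltr_seq = random_sequence(ltr, rng)
        internal = random_sequence(total - 2 * ltr, rng)
        rt_len = 600
        rt_start = ltr + (total - 2 * ltr - rt_len) // 2
        fams.append(TEFamily(
            family_id=names[i],
            superfamily=supers[i],
            consensus=ltr_seq + internal + ltr_seq,
            ltr_length=ltr,
            rt_domain=(rt_start, rt_start + rt_len),
        ))
    return fams


def element_sequence(family: TEFamily, rng=0, age_years: float = 0.0,
                     rate: float = MOLECULAR_CLOCK_RATE) -> str:
    """A full element copy whose two LTRs have diverged for ``age_years``.

    Each LTR copy accumulates substitutions independently at per-site
    probability ``rate * age_years``, so the expected LTR-LTR divergence is
    ~2 * rate * age_years, matching the molecular-clock convention.
    """
    rng = _rng(rng)
    if family.ltr_length is None:
        return family.consensus
    q = rate * age_years
    ltr = family.ltr5
    return mutate(ltr, q, rng) + family.internal + mutate(ltr, q, rng)


# ---------------------------------------------------------------------------
# reference


@dataclass
class SimReference:
    genome: dict[str, str]
    repeats: pd.DataFrame  # chrom, start, end, repeat_id
    seed: int | None = None

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.genome.values())

    def repeat_bases(self) -> int:
        return int((self.repeats["end"] - self.repeats["start"]).sum())


def simulate_reference(length: int = 2_000_000, gc: float = 0.44,
                       repeat_fraction: float = 0.4, seed=0,
                       chrom: str = "chr1",
                       unit_len: tuple[int, int] = (2_000, 12_000),
                       inverted_prob: float = 0.25) -> SimReference:
    """Background genome with planted duplicated blocks.

    Repeat units are drawn once, then pasted in 2-4 copies (some reverse
    complemented) interleaved with unique background until the duplicated
    bases reach ``repeat_fraction`` of the genome; all copies are annotated.
    """
    if length < 100_000:
        raise ValueError("length must be >= 1e5")
    if repeat_fraction >= 1:
        raise ValueError("repeat_fraction must be < 1")
    rng = _rng(seed)
    target = repeat_fraction * length
    pieces: list[tuple[str, str | None]] = []  # (seq, repeat_id or None)
    rep_bases = 0
    uid = 0
    copies_pool: list[tuple[str, str]] = []
    while rep_bases < target:
        u = int(rng.integers(unit_len[0], unit_len[1]))
        n_copies = int(rng.integers(2, 5))
        remaining = target - rep_bases
        if u * n_copies > remaining:  # last unit: trim to land on target
            n_copies = 2
            u = max(300, int(remaining // 2))
        unit = random_sequence(u, rng, gc)
        uid += 1
        for _ in range(n_copies):
            s = revcomp(unit) if rng.random() < inverted_prob else unit
            copies_pool.append((s, f"rep{uid}"))
            rep_bases += u
    rng.shuffle(copies_pool)
    unique_total = max(0, length - rep_bases)
    # split unique background into one spacer per repeat copy (+ flanks)
    n_gaps = len(copies_pool) + 1
    cuts = np.sort(rng.integers(0, unique_total + 1, size=n_gaps - 1))
    gap_lens = np.diff(np.concatenate([[0], cuts, [unique_total]]))
    seq_parts = []
    records = []
    pos = 0
    for i, g in enumerate(gap_lens):
        u = random_sequence(int(g), rng, gc)
        seq_parts.append(u)
        pos += int(g)
        if i < len(copies_pool):
            s, rid = copies_pool[i]
            records.append((chrom, pos, pos + len(s), rid))
            seq_parts.append(s)
            pos += len(s)
    genome = {chrom: "".join(seq_parts)}
    rep = pd.DataFrame(records, columns=["chrom", "start", "end", "repeat_id"])
    return SimReference(genome=genome, repeats=rep,
                        seed=seed if isinstance(seed, int) else None)


# ---------------------------------------------------------------------------
# panel


def l_shaped_frequency(rng, a: float = 0.3, b: float = 5.0) -> float:
    """Beta(a, b) insertion frequency: heavy mass near zero (L-shape)."""
    return float(_rng(rng).beta(a, b))


@dataclass
class SimPanel:
    """Simulated accession panel plus its complete ground truth."""

    reference: SimReference
    library: list[TEFamily]
    loci: pd.DataFrame       # locus_id, chrom, pos, family_id, frequency
    carriers: pd.DataFrame   # loci x accessions boolean
    genomes: dict[str, str] = field(repr=False, default_factory=dict)
    tsd: int = 5
    seed: int | None = None

    @property
    def accessions(self) -> list[str]:
        return list(self.carriers.columns)

    def carrier_counts(self) -> pd.Series:
        return self.carriers.sum(axis=1)

    def truth_windows(self, windows: WindowSet) -> pd.DataFrame:
        w = [windows.window_of(c, p).window_id
             for c, p in zip(self.loci["chrom"], self.loci["pos"])]
        out = self.loci.copy()
        out["window_id"] = w
        return out


def simulate_panel(reference: SimReference, library: Sequence[TEFamily],
                   n_accessions: int = 12, n_loci: int = 60,
                   frequency_law: Callable | None = None, seed=0,
                   tsd: int = 5, min_spacing: int = 1_000,
                   edge_margin: int = 2_000,
                   age_years: float = 0.0) -> SimPanel:
    """Plant ``n_loci`` TE insertions at drawn population frequencies.

    Each locus gets a frequency from ``frequency_law`` (default: L-shaped
    Beta(0.3, 5)); each accession then carries the insertion independently
    with that probability (re-drawn if a locus ends up with zero carriers,
    so every locus exists somewhere in the panel).  Insertions are clean
    full-length splice-ins with a ``tsd``-bp target-site duplication.
    """
    rng = _rng(seed)
    law = frequency_law or (lambda r: l_shaped_frequency(r))
    chrom = list(reference.genome)[0]
    L = len(reference.genome[chrom])
    positions: list[int] = []
    tries = 0
    while len(positions) < n_loci:
        tries += 1
        if tries > 200 * n_loci:
            raise RuntimeError("could not place loci with required spacing")
        p = int(rng.integers(edge_margin, L - edge_margin))
        if all(abs(p - q) >= min_spacing for q in positions):
            positions.append(p)
    positions.sort()
    fam_ids = [library[int(rng.integers(0, len(library)))].family_id
               for _ in positions]
    freqs = [law(rng) for _ in positions]
    acc_ids = [f"acc{i:02d}" for i in range(n_accessions)]
    carrier_rows = []
    for f in freqs:
        f = max(f, 1e-9)
        while True:
            row = rng.random(n_accessions) < f
            if row.any():
                break
        carrier_rows.append(row)
    carriers = pd.DataFrame(np.array(carrier_rows), columns=acc_ids)
    loci = pd.DataFrame({
        "locus_id": [f"L{i:03d}" for i in range(len(positions))],
        "chrom": chrom,
        "pos": positions,
        "family_id": fam_ids,
        "frequency": freqs,
    })
    fam_by_id = {f.family_id: f for f in library}
    # one element sequence per locus (shared by all carriers of that locus)
    elements = [element_sequence(fam_by_id[f], rng, age_years) for f in fam_ids]
    genomes = {}
    ref_seq = reference.genome[chrom]
    for j, acc in enumerate(acc_ids):
        parts = []
        prev = 0
        for i, p in enumerate(positions):
            if not carriers.iloc[i, j]:
                continue
            parts.append(ref_seq[prev : p + tsd])
            parts.append(elements[i])
            prev = p  # duplicate the tsd bases after the element
        parts.append(ref_seq[prev:])
        genomes[acc] = "".join(parts)
    return SimPanel(reference=reference, library=list(library), loci=loci,
                    carriers=carriers, genomes=genomes, tsd=tsd,
                    seed=seed if isinstance(seed, int) else None)


# ---------------------------------------------------------------------------
# reads


def generate_reads(genome: str | Mapping[str, str], coverage: float,
                   read_len: int = 100, insert_mean: int = 350,
                   insert_sd: int = 50, error_rate: float = 0.005,
                   seed=0, name_prefix: str = "read") -> tuple[list[str], list[str]]:
    """Paired-end reads: mate1 forward from fragment start, mate2 reverse
    complement from fragment end; uniform substitution errors."""
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if insert_mean < 2 * read_len:
        raise ValueError("insert_mean must be >= 2 * read_len")
    rng = _rng(seed)
    seq = genome if isinstance(genome, str) else "".join(genome.values())
    L = len(seq)
    n_pairs = int(round(coverage * L / (2 * read_len)))
    inserts = np.clip(np.round(rng.normal(insert_mean, insert_sd, n_pairs)),
                      2 * read_len, None).astype(np.int64)
    inserts = np.minimum(inserts, L)
    starts = (rng.random(n_pairs) * (L - inserts + 1)).astype(np.int64)
    arr = encode(seq)
    offs = np.arange(read_len)
    m1 = arr[starts[:, None] + offs]
    tails = arr[(starts + inserts - read_len)[:, None] + offs]
    tails = tails[:, ::-1]
    m2 = np.where(tails < 4, 3 - tails, tails).astype(np.uint8)
    for m in (m1, m2):
        err = rng.random(m.shape) < error_rate
        shift = rng.integers(1, 4, size=m.shape).astype(np.uint8)
        m[err] = (m[err] + shift[err]) % 4
    to_str = lambda mat: [decode(mat[i]) for i in range(len(mat))]
    return to_str(m1), to_str(m2)


def generate_long_reads(genome: str | Mapping[str, str], coverage: float = 11.0,
                        median_len: int = 8_000, sigma: float = 0.4,
                        error_rate: float = 0.0, seed=0) -> list[str]:
    """Single-molecule long reads: log-normal lengths, substitution + indel
    errors split evenly between the three error types."""
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = _rng(seed)
    seq = genome if isinstance(genome, str) else "".join(genome.values())
    L = len(seq)
    reads = []
    total = 0
    target = coverage * L
    while total < target:
        rl = int(np.clip(rng.lognormal(np.log(median_len), sigma), 500, L))
        s = int(rng.integers(0, L - rl + 1))
        r = seq[s : s + rl]
        if rng.random() < 0.5:
            r = revcomp(r)
        if error_rate > 0:
            r = _long_read_errors(r, error_rate, rng)
        reads.append(r)
        total += rl
    return reads


def _long_read_errors(seq: str, rate: float, rng) -> str:
    """Apply substitutions, insertions and deletions (each at rate/3)."""
    arr = encode(seq)
    n = len(arr)
    u = rng.random(n)
    third = rate / 3
    sub = u < third
    ins = (u >= third) & (u < 2 * third)
    dele = (u >= 2 * third) & (u < rate)
    shift = rng.integers(1, 4, size=n).astype(np.uint8)
    arr = arr.copy()
    arr[sub] = (arr[sub] + shift[sub]) % 4
    out = []
    ins_base = rng.integers(0, 4, size=n).astype(np.uint8)
    for i in range(n):
        if dele[i]:
            continue
        out.append(arr[i])
        if ins[i]:
            out.append(ins_base[i])
    return decode(np.array(out, dtype=np.uint8))


def write_fastq(reads: Sequence[str], path, name_prefix: str = "read",
                suffix: str = "", qual_char: str = "?") -> None:
    """Constant-quality FASTQ (Phred 30); detection never uses qualities."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@{name_prefix}_{i}{suffix}\n{r}\n+\n{qual_char * len(r)}\n")


# ---------------------------------------------------------------------------
# assembly trio (paleontology test-bench)

DEFAULT_CATEGORY_AGES = {
    # specific insertions post-date the splits; common ones pre-date them
    "Indica-specific": 230_000.0,
    "Japonica-specific": 310_000.0,
    "Aus-specific": 380_000.0,
    "common-IndJap": 800_000.0,
    "common-IndAus": 540_000.0,
    "common-JapAus": 1_400_000.0,
    "common-all": 1_200_000.0,
}

_CATEGORY_PRESENCE = {
    "Japonica-specific": ("japonica",),
    "Indica-specific": ("indica",),
    "Aus-specific": ("aus",),
    "common-all": ("japonica", "indica", "aus"),
    "common-IndJap": ("japonica", "indica"),
    "common-IndAus": ("indica", "aus"),
    "common-JapAus": ("japonica", "aus"),
}


@dataclass
class SimTrio:
    """Three assemblies sharing an ancestral background, with planted
    full-length elements whose presence pattern defines seven categories."""

    genomes: dict[str, dict[str, str]]  # genome_id -> {chrom: seq}
    groups: dict[str, str]              # genome_id -> varietal group
    library: list[TEFamily]
    truth: pd.DataFrame  # element_id, family_id, category, age_years,
    #                      ancestral_pos, start_<genome> per genome (or -1)
    seed: int | None = None


def simulate_trio(seed: int = 0, *, length: int = 700_000,
                  per_category: int = 4, spacing: int = 25_000,
                  category_ages: Mapping[str, float] | None = None,
                  tsd: int = 5,
                  genome_ids: tuple[str, str, str] = ("japonica_asm", "indica_asm", "aus_asm"),
                  ) -> SimTrio:
    """Plant ``per_category`` elements of each of the seven categories.

    Backgrounds are identical across the three assemblies (insertions are
    the only differences), so orthologous flanks are unique by construction.
    Loci are kept well over 15 kb apart in ancestral coordinates, so each
    orthology scan is clear of neighbouring loci.  Ages follow
    the default history: group-specific insertions young, shared ones old.
    """
    streams = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(streams[1])
    lib = synthetic_te_library(np.random.default_rng(streams[0]),
                               n_ltr_families=2)
    ages = dict(category_ages or DEFAULT_CATEGORY_AGES)
    cats = [c for c in _CATEGORY_PRESENCE for _ in range(per_category)]
    n = len(cats)
    need = n * spacing + 2 * spacing
    if length < need:
        length = need
    ancestor = random_sequence(length, rng)
    # spacing-stride grid plus sub-window jitter: loci stay >= 2*spacing/3
    # apart in ancestral coordinates, clear of the 15-kb orthology scan
    grid = np.arange(spacing, length - spacing, spacing)
    picks = np.sort(rng.choice(len(grid), size=n, replace=False))
    positions = grid[picks] + rng.integers(0, spacing // 3, size=n)
    rng.shuffle(cats)
    rows = []
    elements = []
    for i, (pos, cat) in enumerate(zip(positions, cats)):
        fam = lib[i % len(lib)]
        seq = element_sequence(fam, rng, ages[cat])
        elements.append(seq)
        rows.append({"element_id": f"E{i:03d}", "family_id": fam.family_id,
                     "category": cat, "age_years": ages[cat],
                     "ancestral_pos": int(pos)})
    roles = {"japonica": genome_ids[0], "indica": genome_ids[1], "aus": genome_ids[2]}
    genomes = {}
    for role, gid in roles.items():
        parts = []
        prev = 0
        for i, (pos, cat) in enumerate(zip(positions, cats)):
            if role not in _CATEGORY_PRESENCE[cat]:
                rows[i][f"start_{gid}"] = -1
                continue
            parts.append(ancestor[prev : pos + tsd])
            rows[i][f"start_{gid}"] = sum(len(p) for p in parts)
            parts.append(elements[i])
            prev = pos
        parts.append(ancestor[prev:])
        genomes[gid] = {"chr1": "".join(parts)}
    groups = {genome_ids[0]: "Japonica", genome_ids[1]: "Indica",
              genome_ids[2]: "Aus/Boro"}
    return SimTrio(genomes=genomes, groups=groups, library=lib,
                   truth=pd.DataFrame(rows), seed=seed)


def trio_panel_matrix(trio: SimTrio, n_per_group: Mapping[str, int] | None = None,
                      carrier_rate: float = 0.9, seed: int = 0):
    """A presence/absence matrix + accession groups consistent with the trio.

    For every planted element and every assembly carrying it, a matrix row
    is created for the window containing the element start in that assembly
    (plus its neighbours, since a recovered start may sit a few bp from a
    boundary); accessions of implicated groups carry it at ``carrier_rate``.
    """
    from .core import make_windows
    from .detect import TIPMatrix

    rng = np.random.default_rng(seed)
    n_per_group = dict(n_per_group or {"Indica": 10, "Japonica": 10, "Aus/Boro": 6})
    accs = {}
    acc_ids = []
    for grp, n in n_per_group.items():
        ids = [f"{grp.split('/')[0].lower()}{i:02d}" for i in range(n)]
        accs[grp] = ids
        acc_ids += ids
    groups_of_acc = {a: g for g, ids in accs.items() for a in ids}
    windows = {gid: make_windows(g) for gid, g in trio.genomes.items()}
    group_role = {"Japonica": "japonica", "Indica": "indica", "Aus/Boro": "aus"}
    rows = {}
    for _, r in trio.truth.iterrows():
        implicated = _CATEGORY_PRESENCE[r["category"]]
        pattern = {}
        for grp, ids in accs.items():
            if group_role[grp] in implicated:
                carried = rng.random(len(ids)) < carrier_rate
                if not carried.any():
                    carried[0] = True
                # guarantee the threshold is actually met in expectation-free way
                while carried.mean() < 0.85:
                    carried[int(rng.integers(len(ids)))] = True
                pattern.update(dict(zip(ids, carried.astype(int))))
            else:
                pattern.update({a: 0 for a in ids})
        for gid in trio.genomes:
            start = int(r[f"start_{gid}"])
            if start < 0:
                continue
            ws = windows[gid]
            w = ws.window_of("chr1", start)
            for cand in {w.window_id,
                         f"chr1:{max(0, w.start - 10_000)}-{w.start}" if w.start else None,
                         f"chr1:{w.end}-{w.end + 10_000}"}:
                if cand:
                    rows[(r["family_id"], cand)] = pattern
    idx = pd.MultiIndex.from_tuples(sorted(rows), names=["family_id", "window_id"])
    df = pd.DataFrame([rows[k] for k in sorted(rows)], index=idx,
                      columns=acc_ids).fillna(0).astype(np.int8)
    return TIPMatrix(df), groups_of_acc, windows


# ---------------------------------------------------------------------------
# full study bundle


@dataclass
class SimStudy:
    reference: SimReference
    library: list[TEFamily]
    panel: SimPanel
    reads: dict[str, tuple[list[str], list[str]]]
    seed: int


def simulate_study(seed: int = 0, *, length: int = 2_000_000,
                   repeat_fraction: float = 0.4, n_accessions: int = 12,
                   n_loci: int = 60, n_families: int = 2,
                   coverage: float = 15.0, read_len: int = 100,
                   insert_mean: int = 350, insert_sd: int = 50,
                   error_rate: float = 0.005,
                   frequency_law: Callable | None = None) -> SimStudy:
    """One complete simulated study under the default conditions.

    Library, reference, panel and per-accession read sets each get an
    independent child RNG stream spawned from ``seed`` (sharing one stream
    would correlate the reference background with the consensus sequences).
    """
    streams = np.random.SeedSequence(seed).spawn(3 + n_accessions)
    lib = synthetic_te_library(np.random.default_rng(streams[0]),
                               n_ltr_families=n_families)
    ref = simulate_reference(length=length, repeat_fraction=repeat_fraction,
                             seed=np.random.default_rng(streams[1]))
    panel = simulate_panel(ref, lib, n_accessions=n_accessions, n_loci=n_loci,
                           frequency_law=frequency_law,
                           seed=np.random.default_rng(streams[2]))
    reads = {}
    for i, acc in enumerate(panel.accessions):
        reads[acc] = generate_reads(panel.genomes[acc], coverage,
                                    read_len=read_len,
                                    insert_mean=insert_mean,
                                    insert_sd=insert_sd,
                                    error_rate=error_rate,
                                    seed=np.random.default_rng(streams[3 + i]))
    return SimStudy(ref, lib, panel, reads, seed)


# ---------------------------------------------------------------------------
# scoring detection output against truth


def score_detection(calls_df: pd.DataFrame, panel: SimPanel, windows: WindowSet,
                    mappability: Mapping[str, float] | None = None,
                    min_mappability: float = 0.8,
                    margin: int = 500) -> dict:
    """Locus-level recall/precision of TIP calls against simulator truth.

    A call (accession, family, window) is a true positive when a truth locus
    of that family carried by that accession lies within the window extended
    by ``margin`` bp (anchor mates land up to about one insert size from the
    junction, so calls can spill into the neighbouring window).  Recall is
    reported over carried loci overall and restricted to windows at or above
    ``min_mappability``.
    """
    by_id = windows.by_id()
    truth = panel.truth_windows(windows)
    loci_pos = truth.set_index("locus_id")[["chrom", "pos", "family_id", "window_id"]]

    def matching_loci(fam, w, acc_col):
        w_obj = by_id[w]
        sel = (truth["family_id"] == fam) & (truth["chrom"] == w_obj.chrom) & \
              (truth["pos"] >= w_obj.start - margin) & (truth["pos"] < w_obj.end + margin)
        ids = truth.loc[sel, "locus_id"]
        return [l for l in ids if panel.carriers.loc[truth["locus_id"] == l, acc_col].any()]

    tp = 0
    fp = 0
    detected: set[tuple[str, str]] = set()
    for _, c in calls_df.iterrows():
        hits = matching_loci(c["family_id"], c["window_id"], c["accession_id"])
        if hits:
            tp += 1
            for l in hits:
                detected.add((l, c["accession_id"]))
        else:
            fp += 1
    total_carr = 0
    found_carr = 0
    total_carr_mapp = 0
    found_carr_mapp = 0
    for i, row in truth.iterrows():
        l = row["locus_id"]
        mapp_ok = True
        if mappability is not None:
            mapp_ok = mappability.get(row["window_id"], 0.0) >= min_mappability
        for acc in panel.accessions:
            if not panel.carriers.loc[truth.index == i, acc].any():
                continue
            total_carr += 1
            hit = (l, acc) in detected
            found_carr += hit
            if mapp_ok:
                total_carr_mapp += 1
                found_carr_mapp += hit
    return {
        "tp": tp,
        "fp": fp,
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "recall": found_carr / total_carr if total_carr else float("nan"),
        "recall_mappable": (found_carr_mapp / total_carr_mapp
                            if total_carr_mapp else float("nan")),
        "n_carried": total_carr,
        "n_carried_mappable": total_carr_mapp,
    }
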