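"""Per-window mappability: the fraction of 100-bp tiles placing uniquely.

Each 10-kb window is sliced into non-overlapping 100-bp tiles; a tile is
mappable when anchoring it on the genome yields a unique placement under the
same length/identity gate and uniqueness rule as short-read anchoring, so
the track is by construction the detectability bound of TIP anchoring.
Trailing fragments shorter than one tile are excluded from both numerator
and denominator.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .align import AlignmentParams, ReferenceAligner, encode, kmer_codes
from .core import GenomeWindow, WindowSet, make_windows

TILE = 100
MAX_N_PER_TILE = 10


def tile_window(window: GenomeWindow, genome: Mapping[str, str],
                tile: int = TILE) -> list[str]:
    """Consecutive non-overlapping tiles of a window (trailing fragment dropped)."""
    seq = genome[window.chrom][window.start : window.end]
    return [seq[i : i + tile] for i in range(0, len(seq) - tile + 1, tile)]


def tile_is_unique(tile_seq: str, ref_aligner: ReferenceAligner) -> bool:
    """True iff the tile anchors uniquely (its own locus being the one placement)."""
    if tile_seq.count("N") > MAX_N_PER_TILE:
        return False
    return ref_aligner.anchor(tile_seq).uniqueness == "unique"


def window_mappability(genome: Mapping[str, str],
                       windows: WindowSet | None = None,
                       params: AlignmentParams | None = None,
                       tile: int = TILE) -> dict[str, float]:
    """Mappability track for every window of the genome.

    Fast path: querying a tile k-mer against the genome indexed on both
    strands returns one occurrence for the tile's own locus plus one per
    additional placement on either strand (a k-mer shows up in the
    reverse-strand entry only where its reverse complement lies in the
    forward text).  A tile whose k-mers all occur exactly once has no exact
    k-length match anywhere else and is unique without further work; only
    tiles with repeated k-mers are fully anchored.
    """
    params = params or AlignmentParams()
    windows = windows or make_windows(genome)
    ref_aligner = ReferenceAligner(genome, params)
    index = ref_aligner.aligner.index
    track: dict[str, float] = {}
    for w in windows:
        tiles = tile_window(w, genome, tile)
        if not tiles:
            track[w.window_id] = 0.0
            continue
        n_unique = 0
        for t in tiles:
            arr = encode(t)
            if int(np.sum(arr >= 4)) > MAX_N_PER_TILE:
                continue
            codes, valid = kmer_codes(arr, params.k)
            lo, hi = index.occurrences(codes)
            occ = hi - lo
            if valid.all() and bool(np.all(occ[valid] == 1)):
                n_unique += 1  # no k-mer repeats anywhere: self placement only
            elif tile_is_unique(t, ref_aligner):
                n_unique += 1
        track[w.window_id] = n_unique / len(tiles)
    return track


def mean_mappability(track: Mapping[str, float]) -> float:
    return float(np.mean(list(track.values()))) if track else float("nan")


def write_bedgraph(track: Mapping[str, float], path) -> None:
    with open(path, "w") as fh:
        for window_id, frac in track.items():
            chrom, rest = window_id.split(":")
            start, end = rest.split("-")
            fh.write(f"{chrom}\t{start}\t{end}\t{frac:.4f}\n")
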