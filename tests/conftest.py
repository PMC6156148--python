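"""Shared fixtures and naive per-base oracles for window statistics."""

from __future__ import annotations

import numpy as np
import pytest

from airechrom.genomic_signal import DEFAULT_RATIO, SignalTrack, TssAnnotation


def track_to_base_array(track: SignalTrack, chrom: str, length: int,
                        default: float = 0.0) -> np.ndarray:
    """Expand a track to one value per base (``default`` where uncovered)."""
    arr = np.full(length, default, dtype=float)
    if chrom in track.data:
        s, e, v = track.data[chrom]
        for a, b, val in zip(s, e, v):
            arr[a:min(b, length)] = val
    return arr


def naive_ratio(chip: np.ndarray, input_: np.ndarray,
                pseudocount: float) -> np.ndarray:
    return (chip + pseudocount) / (input_ + pseudocount)


def naive_tss_max(ratio_by_base: np.ndarray, tss_positions, window: int) -> float:
    """Per-base oracle: max over the union of closed TSS windows."""
    length = len(ratio_by_base)
    best = -np.inf
    for pos in tss_positions:
        lo = max(0, pos - window)
        hi = min(length, pos + window + 1)
        if hi > lo:
            best = max(best, ratio_by_base[lo:hi].max())
    return best


def naive_bin_means(ratio_by_base: np.ndarray, tss: int, strand: str,
                    window: int, bin_bp: int) -> np.ndarray:
    """Per-base oracle: mean per strand-oriented bin (NaN off-chromosome)."""
    length = len(ratio_by_base)
    n_bins = 2 * window // bin_bp
    out = np.full(n_bins, np.nan)
    for k in range(n_bins):
        lo = -window + k * bin_bp
        vals = []
        for r in range(lo, lo + bin_bp):
            g = tss + r if strand == "+" else tss - r
            if 0 <= g < length:
                vals.append(ratio_by_base[g])
        if vals:
            out[k] = np.mean(vals)
    return out


def random_track(rng: np.random.Generator, length: int, n_intervals: int,
                 library_size: float = 1e6, chrom: str = "chr1") -> SignalTrack:
    """Random sorted non-overlapping intervals with gaps, on one chromosome."""
    cuts = np.sort(rng.choice(length, size=2 * n_intervals, replace=False))
    starts, ends = cuts[0::2], cuts[1::2]
    keep = ends > starts
    values = rng.uniform(0, 10, size=keep.sum())
    return SignalTrack(data={chrom: (starts[keep], ends[keep], values)},
                       library_size=library_size)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_annotation():
    return TssAnnotation(
        tss={
            "gA": [("chr1", 3000, "+")],
            "gB": [("chr1", 6000, "-"), ("chr1", 6400, "-")],
        },
        gene_bodies={"gA": ("chr1", 3000, 5000), "gB": ("chr1", 4001, 6001)},
        chrom_lengths={"chr1": 10_000},
    )
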