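"""Genomic signal tracks and TSS-proximal feature extraction.

Coverage tracks (bedGraph-style) are held as per-chromosome arrays of
non-overlapping, sorted ``[start, end)`` intervals with a value each, plus a
library size.  All coordinates are 0-based half-open, the BED/bedGraph
convention.  A TSS window of half-width ``w`` is the closed interval of
``2*w + 1`` bases centred on the TSS base.

The per-gene chromatin feature used throughout the package is the maximum
library-scaled ChIP/input ratio within 1 kb of any of the gene's transcript
start sites; category-wise metagene profiles summarise the same ratio as the
median over genes in strand-oriented distance bins around the TSS.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("airechrom")

AIRE_CATEGORIES = (
    "AIRE_DEPENDENT",
    "AIRE_ENHANCED",
    "AIRE_INDEPENDENT_TRA",
    "OTHER",
)
#: categories treated as AIRE-induced in two-class analyses
INDUCED_CATEGORIES = ("AIRE_DEPENDENT", "AIRE_ENHANCED")

SCALED_LIBRARY = 1_000_000.0
#: neutral ChIP/input ratio assumed where a track has no coverage
DEFAULT_RATIO = 1.0


class TrackError(ValueError):
    """Malformed or invariant-violating track/annotation data."""


# ---------------------------------------------------------------------------
# SignalTrack
# ---------------------------------------------------------------------------

@dataclass
class SignalTrack:
    """Binned genomic coverage with a library size.

    ``data`` maps chromosome name to a ``(starts, ends, values)`` triple of
    equal-length numpy arrays; intervals are sorted and non-overlapping,
    values finite and non-negative.
    """

    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    library_size: float

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise TrackError("library_size must be positive")
        canon = {}
        for chrom, (s, e, v) in self.data.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=np.float64)
            order = np.argsort(s, kind="stable")
            s, e, v = s[order], e[order], v[order]
            if np.any(e <= s):
                raise TrackError(f"{chrom}: interval with end <= start")
            if np.any(s[1:] < e[:-1]):
                raise TrackError(f"{chrom}: overlapping intervals")
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise TrackError(f"{chrom}: values must be finite and >= 0")
            canon[chrom] = (s, e, v)
        self.data = canon

    def chroms(self) -> list[str]:
        return sorted(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if self.library_size != other.library_size:
            return False
        if set(self.data) != set(other.data):
            return False
        return all(
            all(np.array_equal(a, b) for a, b in zip(self.data[c], other.data[c]))
            for c in self.data
        )

    def value_at(self, chrom: str, pos: int) -> float:
        """Track value covering base ``pos`` (``0.0`` where uncovered)."""
        if chrom not in self.data:
            return 0.0
        s, e, v = self.data[chrom]
        i = int(np.searchsorted(s, pos, side="right")) - 1
        if i >= 0 and e[i] > pos:
            return float(v[i])
        return 0.0


def read_bedgraph(path, library_size: float) -> SignalTrack:
    """Read a 4-column bedGraph file into a :class:`SignalTrack`.

    Malformed lines raise :class:`TrackError` naming the 1-based line number;
    overlapping intervals are rejected.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str}, float_precision="round_trip",
        )
    except Exception as exc:  # noqa: BLE001 - rewrap any parse failure
        raise TrackError(f"{path}: cannot parse bedGraph: {exc}") from exc
    for col in ("start", "end", "value"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise TrackError(f"{path}:{line}: non-numeric {col!r} field")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["value"] = df["value"].astype(np.float64)
    df["line"] = np.arange(1, len(df) + 1)
    if (df["value"] < 0).any():
        line = int(df.loc[df["value"] < 0, "line"].iloc[0])
        raise TrackError(f"{path}:{line}: negative value")
    if (df["end"] <= df["start"]).any():
        line = int(df.loc[df["end"] <= df["start"], "line"].iloc[0])
        raise TrackError(f"{path}:{line}: end <= start")
    data = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        grp = grp.sort_values("start", kind="stable")
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        if np.any(s[1:] < e[:-1]):
            j = int(np.flatnonzero(s[1:] < e[:-1])[0]) + 1
            line = int(grp["line"].to_numpy()[j])
            raise TrackError(f"{path}:{line}: overlapping interval on {chrom}")
        data[chrom] = (s, e, grp["value"].to_numpy())
    return SignalTrack(data=data, library_size=library_size)


def write_bedgraph(track: SignalTrack, path) -> None:
    frames = []
    for chrom in track.chroms():
        s, e, v = track.data[chrom]
        frames.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e, "value": v}))
    out = pd.concat(frames) if frames else pd.DataFrame(
        columns=["chrom", "start", "end", "value"])
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.17g")


def scale_to_library(track: SignalTrack) -> SignalTrack:
    """Scale values to a nominal library of 1e6 fragments (CPM-style)."""
    f = SCALED_LIBRARY / track.library_size
    data = {c: (s.copy(), e.copy(), v * f) for c, (s, e, v) in track.data.items()}
    return SignalTrack(data=data, library_size=SCALED_LIBRARY)


def pool_tracks(tracks: Sequence[SignalTrack]) -> SignalTrack:
    """Pool replicate tracks: values summed piecewise, library sizes summed."""
    if not tracks:
        raise TrackError("no tracks to pool")
    pooled = tracks[0]
    for t in tracks[1:]:
        pooled = _combine(pooled, t, lambda a, b: a + b,
                          library_size=pooled.library_size + t.library_size)
    return pooled


def _segments(track: SignalTrack, chrom: str, bounds: np.ndarray) -> np.ndarray:
    """Track value on each segment between consecutive ``bounds`` (0 where absent)."""
    out = np.zeros(len(bounds) - 1)
    if chrom not in track.data:
        return out
    s, e, v = track.data[chrom]
    left = bounds[:-1]
    idx = np.searchsorted(s, left, side="right") - 1
    ok = (idx >= 0) & (e[np.clip(idx, 0, None)] > left)
    out[ok] = v[idx[ok]]
    return out


def _combine(a: SignalTrack, b: SignalTrack, op, library_size: float) -> SignalTrack:
    data = {}
    for chrom in sorted(set(a.data) | set(b.data)):
        bounds = [arr for t in (a, b) if chrom in t.data
                  for arr in t.data[chrom][:2]]
        bp = np.unique(np.concatenate(bounds))
        va = _segments(a, chrom, bp)
        vb = _segments(b, chrom, bp)
        covered = np.zeros(len(bp) - 1, dtype=bool)
        for t in (a, b):
            if chrom in t.data:
                s, e, _ = t.data[chrom]
                idx = np.searchsorted(s, bp[:-1], side="right") - 1
                covered |= (idx >= 0) & (e[np.clip(idx, 0, None)] > bp[:-1])
        val = op(va, vb)
        keep = covered
        data[chrom] = (bp[:-1][keep], bp[1:][keep], val[keep])
    return SignalTrack(data=data, library_size=library_size)


def chip_input_ratio(chip: SignalTrack, input_: SignalTrack,
                     pseudocount: float = 0.5) -> SignalTrack:
    """Piecewise (chip + pc) / (input + pc) over the union of breakpoints.

    Both tracks must be library-scaled.  Regions covered by neither track are
    left unrepresented; downstream window statistics treat them as the
    neutral ratio 1.
    """
    if pseudocount <= 0:
        raise TrackError("pseudocount must be positive")
    for t, name in ((chip, "chip"), (input_, "input")):
        if t.library_size != SCALED_LIBRARY:
            raise TrackError(f"{name} track must be library-scaled first")
    return _combine(chip, input_,
                    lambda a, b: (a + pseudocount) / (b + pseudocount),
                    library_size=SCALED_LIBRARY)


# ---------------------------------------------------------------------------
# TSS annotation
# ---------------------------------------------------------------------------

@dataclass
class TssAnnotation:
    """Gene -> transcript TSS coordinates, with optional gene bodies.

    ``tss`` maps gene id to a list of ``(chrom, position, strand)``; the first
    entry is the primary (metagene) TSS.  ``gene_bodies`` maps gene id to
    ``(chrom, start, end)`` half-open intervals where available (used as the
    enrichment workspace).  ``chrom_lengths`` enables edge clipping.
    """

    tss: dict[str, list[tuple[str, int, str]]]
    gene_bodies: dict[str, tuple[str, int, int]] | None = None
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        for gene, sites in self.tss.items():
            if not sites:
                raise TrackError(f"gene {gene} has no TSS")
            for chrom, pos, strand in sites:
                if strand not in "+-":
                    raise TrackError(f"gene {gene}: bad strand {strand!r}")
                if pos < 0:
                    raise TrackError(f"gene {gene}: negative TSS position")
                if self.chrom_lengths and chrom in self.chrom_lengths \
                        and pos >= self.chrom_lengths[chrom]:
                    raise TrackError(f"gene {gene}: TSS beyond {chrom} end")

    def genes(self) -> list[str]:
        return sorted(self.tss)

    def chrom_end(self, chrom: str) -> int | None:
        if self.chrom_lengths is None:
            return None
        return self.chrom_lengths.get(chrom)


def write_tss_bed(annotation: TssAnnotation, path) -> None:
    """One BED6 line per transcript TSS (name = gene id, 1 bp interval)."""
    rows = []
    for gene in annotation.genes():
        for chrom, pos, strand in annotation.tss[gene]:
            rows.append((chrom, pos, pos + 1, gene, 0, strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_tss_bed(path, chrom_lengths: dict[str, int] | None = None) -> TssAnnotation:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene", "score", "strand"],
                     dtype={"chrom": str, "gene": str})
    tss: dict[str, list[tuple[str, int, str]]] = {}
    for row in df.itertuples(index=False):
        tss.setdefault(row.gene, []).append((row.chrom, int(row.start), row.strand))
    return TssAnnotation(tss=tss, chrom_lengths=chrom_lengths)


def write_gene_bodies_bed(annotation: TssAnnotation, path) -> None:
    if annotation.gene_bodies is None:
        raise TrackError("annotation has no gene bodies")
    rows = []
    for gene in annotation.genes():
        chrom, start, end = annotation.gene_bodies[gene]
        strand = annotation.tss[gene][0][2]
        rows.append((chrom, start, end, gene, 0, strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_gene_bodies_bed(path) -> dict[str, tuple[str, int, int]]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene", "score", "strand"],
                     dtype={"chrom": str, "gene": str})
    return {r.gene: (r.chrom, int(r.start), int(r.end))
            for r in df.itertuples(index=False)}


# ---------------------------------------------------------------------------
# Window statistics
# ---------------------------------------------------------------------------

def _window_max(track: SignalTrack, chrom: str, lo: int, hi: int) -> float:
    """Maximum value over genomic bases [lo, hi); uncovered bases count as 1."""
    if hi <= lo:
        return DEFAULT_RATIO
    if chrom not in track.data:
        return DEFAULT_RATIO
    s, e, v = track.data[chrom]
    i0 = int(np.searchsorted(e, lo, side="right"))
    i1 = int(np.searchsorted(s, hi, side="left"))
    if i1 <= i0:
        return DEFAULT_RATIO
    vals = v[i0:i1]
    covered = int(np.sum(np.minimum(e[i0:i1], hi) - np.maximum(s[i0:i1], lo)))
    m = float(vals.max())
    if covered < hi - lo:
        m = max(m, DEFAULT_RATIO)
    return m


def tss_max_signal(ratio: SignalTrack, annotation: TssAnnotation,
                   window_bp: int = 1000) -> pd.Series:
    """Per-gene maximum ratio within ``window_bp`` of any transcript TSS.

    The window is the closed interval of ``2*window_bp + 1`` bases centred on
    each TSS, clipped at chromosome edges; genes whose windows overlap no
    track data get the neutral ratio 1.
    """
    if window_bp <= 0:
        raise TrackError("window_bp must be positive")
    out = {}
    for gene in annotation.genes():
        best = -np.inf
        for chrom, pos, _strand in annotation.tss[gene]:
            lo = max(0, pos - window_bp)
            hi = pos + window_bp + 1
            end = annotation.chrom_end(chrom)
            if end is not None:
                hi = min(hi, end)
            best = max(best, _window_max(ratio, chrom, lo, hi))
        out[gene] = best
    return pd.Series(out, name="feature").sort_index()


# ---------------------------------------------------------------------------
# FeatureMatrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Genes x chromatin marks matrix of TSS-window maxima plus categories."""

    values: pd.DataFrame            # genes x marks, lexicographic order both axes
    categories: pd.Series           # gene -> AIRE category
    window_bp: int = 1000

    def __post_init__(self) -> None:
        self.values = self.values.sort_index(axis=0).sort_index(axis=1)
        self.categories = self.categories.reindex(self.values.index)
        if self.values.isna().any().any():
            raise TrackError("feature matrix has missing cells")
        bad = self.categories.isna() | ~self.categories.isin(AIRE_CATEGORIES)
        if bad.any():
            raise TrackError(
                "genes with missing/unknown category: "
                + ", ".join(self.values.index[bad][:10]))

    @property
    def marks(self) -> list[str]:
        return list(self.values.columns)

    def induced_labels(self) -> pd.Series:
        """Binary labels: 1 for AIRE-induced, 0 for AIRE-independent."""
        return self.categories.isin(INDUCED_CATEGORIES).astype(int)

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out["category"] = self.categories
        return out


def build_feature_matrix(ratio_tracks: Mapping[str, SignalTrack],
                         annotation: TssAnnotation,
                         categories: Mapping[str, str] | pd.Series,
                         window_bp: int = 1000) -> FeatureMatrix:
    """One column of TSS-window maxima per mark, one row per gene."""
    categories = pd.Series(dict(categories) if not isinstance(categories, pd.Series)
                           else categories)
    missing = [g for g in annotation.genes() if g not in categories.index]
    if missing:
        raise TrackError("genes missing from category table: "
                         + ", ".join(missing[:10]))
    cols = {mark: tss_max_signal(track, annotation, window_bp)
            for mark, track in ratio_tracks.items()}
    values = pd.DataFrame(cols)
    return FeatureMatrix(values=values,
                         categories=categories.loc[values.index],
                         window_bp=window_bp)


# ---------------------------------------------------------------------------
# Metagene profiles
# ---------------------------------------------------------------------------

def _gene_bin_means(track: SignalTrack, chrom: str, tss: int, strand: str,
                    window_bp: int, bin_bp: int,
                    chrom_end: int | None) -> np.ndarray:
    """Mean ratio per strand-oriented bin for one gene (NaN off-chromosome)."""
    n_bins = 2 * window_bp // bin_bp
    rel_lo = -window_bp + np.arange(n_bins) * bin_bp
    means = np.full(n_bins, np.nan)
    for k in range(n_bins):
        a, b = rel_lo[k], rel_lo[k] + bin_bp
        if strand == "+":
            glo, ghi = tss + a, tss + b
        else:
            # base at oriented offset r sits at genomic tss - r
            glo, ghi = tss - b + 1, tss - a + 1
        glo = max(glo, 0)
        if chrom_end is not None:
            ghi = min(ghi, chrom_end)
        width = ghi - glo
        if width <= 0:
            continue
        total = 0.0
        covered = 0
        if chrom in track.data:
            s, e, v = track.data[chrom]
            i0 = int(np.searchsorted(e, glo, side="right"))
            i1 = int(np.searchsorted(s, ghi, side="left"))
            if i1 > i0:
                ov = (np.minimum(e[i0:i1], ghi) - np.maximum(s[i0:i1], glo))
                total = float(np.sum(ov * v[i0:i1]))
                covered = int(ov.sum())
        total += (width - covered) * DEFAULT_RATIO
        means[k] = total / width
    return means


@dataclass
class MetageneProfile:
    """Median ratio per strand-oriented TSS-distance bin and AIRE category."""

    medians: pd.DataFrame   # index: bin centre (bp relative to TSS); columns: categories
    bin_bp: int
    window_bp: int


def metagene_profile(ratio: SignalTrack, annotation: TssAnnotation,
                     categories: Mapping[str, str] | pd.Series,
                     window_bp: int = 5000, bin_bp: int = 50) -> MetageneProfile:
    """Category-wise median ratio in strand-oriented bins around the TSS.

    Each gene contributes the coverage-weighted mean ratio of its primary
    TSS's window in each bin (negative-strand genes flipped so upstream is
    negative).  Empty categories are omitted with a warning.
    """
    if window_bp % bin_bp != 0:
        raise TrackError("window_bp must be divisible by bin_bp")
    categories = pd.Series(dict(categories) if not isinstance(categories, pd.Series)
                           else categories)
    n_bins = 2 * window_bp // bin_bp
    centers = -window_bp + np.arange(n_bins) * bin_bp + bin_bp / 2
    per_cat: dict[str, list[np.ndarray]] = {}
    for gene in annotation.genes():
        chrom, pos, strand = annotation.tss[gene][0]
        cat = categories.get(gene)
        if cat is None:
            raise TrackError(f"gene {gene} missing from category table")
        row = _gene_bin_means(ratio, chrom, pos, strand, window_bp, bin_bp,
                              annotation.chrom_end(chrom))
        per_cat.setdefault(cat, []).append(row)
    cols = {}
    for cat in AIRE_CATEGORIES:
        if cat not in per_cat:
            logger.warning("metagene: category %s has no genes; omitted", cat)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            cols[cat] = np.nanmedian(np.vstack(per_cat[cat]), axis=0)
    medians = pd.DataFrame(cols, index=pd.Index(centers, name="bin_center"))
    return MetageneProfile(medians=medians, bin_bp=bin_bp, window_bp=window_bp)
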