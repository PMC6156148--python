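"""Synthetic inputs with the statistical structure the analysis assumes.

Every pipeline stage can be exercised without any download: this module
generates a TSS annotation, ChIP/input signal tracks with category-dependent
Gaussian bumps at TSSs, a tissue expression atlas with controllable tau, a
single-cell count matrix with ERCC spike-in rows, and peak sets with a
plantable enrichment factor.  The generating parameters (per-category
log-signal shifts, detection-proportion distributions, enrichment factor)
are recorded as ground truth so that downstream estimates can be checked
against what was planted.

Default conditions: 2,000 genes on two chromosomes, the eight chromatin
inputs used for mTEC promoter analysis (ATAC accessibility plus seven
histone marks), repressive marks elevated and active marks depleted around
AIRE-induced TSSs (about one log unit for the strongest), a 19-tissue
atlas, and 167 single cells (so one cell is ~0.6% detection resolution).

One master seed fans out to fixed per-generator substreams, so partial runs
reproduce exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_signal import (
    AIRE_CATEGORIES,
    INDUCED_CATEGORIES,
    SignalTrack,
    TssAnnotation,
)
from .enrichment import IntervalSet, flank_genes, genome_workspace


class ConfigError(ValueError):
    pass


class SizingError(ConfigError):
    """Genome too small for the requested gene count at the required spacing."""


DEFAULT_MARKS = (
    "ATAC", "H3K27ac", "H3K27me3", "H3K4ac",
    "H3K4me1", "H3K4me3", "H3K9ac", "H3K9me3",
)
REPRESSIVE_MARKS = ("H3K27me3", "H3K9me3")

#: per-category mean log-signal shift at the TSS (natural-log units); the
#: AIRE-induced categories carry elevated repressive and depleted active marks
DEFAULT_MARK_EFFECTS: dict[str, dict[str, float]] = {
    "H3K27me3": {"AIRE_DEPENDENT": 1.2, "AIRE_ENHANCED": 1.0},
    "H3K9me3": {"AIRE_DEPENDENT": 1.0, "AIRE_ENHANCED": 0.6},
    "ATAC": {"AIRE_DEPENDENT": 0.6, "AIRE_ENHANCED": 0.5},
    "H3K4me1": {"AIRE_DEPENDENT": 0.4, "AIRE_ENHANCED": 0.3},
    "H3K4me3": {"AIRE_DEPENDENT": -1.2, "AIRE_ENHANCED": -0.9},
    "H3K9ac": {"AIRE_DEPENDENT": -0.8, "AIRE_ENHANCED": -0.5},
    "H3K4ac": {"AIRE_DEPENDENT": -0.5, "AIRE_ENHANCED": -0.3},
    "H3K27ac": {"AIRE_DEPENDENT": -0.5, "AIRE_ENHANCED": -0.3},
}

#: Beta(alpha, beta) of the true single-cell detection proportion per category;
#: induced genes are detected in few cells, housekeeping-like genes in most
DEFAULT_DETECTION_MODEL: dict[str, tuple[float, float]] = {
    "AIRE_DEPENDENT": (1.5, 30.0),
    "AIRE_ENHANCED": (2.0, 18.0),
    "AIRE_INDEPENDENT_TRA": (2.5, 16.0),
    "OTHER": (8.0, 3.0),
}

DEFAULT_CATEGORY_PROPORTIONS = {
    "AIRE_DEPENDENT": 0.08,
    "AIRE_ENHANCED": 0.12,
    "AIRE_INDEPENDENT_TRA": 0.30,
    "OTHER": 0.50,
}

#: target tau of the atlas generator per category (tissue-restricted vs not)
TAU_TARGETS = {
    "AIRE_DEPENDENT": 0.9,
    "AIRE_ENHANCED": 0.9,
    "AIRE_INDEPENDENT_TRA": 0.9,
    "OTHER": 0.23,
}

# fixed substream keys so partial runs reproduce
_STAGE_TRUTH, _STAGE_ANNOT, _STAGE_TRACKS, _STAGE_ATLAS, _STAGE_CELLS, \
    _STAGE_PEAKS = range(6)


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    n_transcripts_per_gene: float = 1.5   # mean of 1 + Poisson(mean - 1)
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 30_000_000, "chr2": 20_000_000})
    category_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROPORTIONS))
    mark_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(DEFAULT_MARK_EFFECTS.get(m, {}))
                                 for m in DEFAULT_MARKS})
    bump_sd_bp: float = 300.0
    noise_sd: float = 0.1            # per-gene log-amplitude noise
    track_noise_sd: float = 0.02     # per-bin log noise (ChIP and input)
    baseline_value: float = 20.0     # library-scaled input level on covered bins
    bin_bp: int = 50
    region_halfwidth_bp: int = 6000  # simulated signal extent around each TSS
    feature_window_bp: int = 1000
    tss_jitter_bp: int = 300         # extra transcript TSSs within this span
    gene_length_bp: int = 2000
    n_tissues: int = 19
    n_cells: int = 167
    detection_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DETECTION_MODEL))
    n_spikeins: int = 92
    capture_efficiency: float = 0.1
    spikein_noise_sd: float = 0.25   # lognormal (natural-log) sd on spike-in counts
    peak_length_bp: int = 200
    input_library_size: float = 1_000_000.0
    chip_library_size: float = 1_500_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.category_proportions.get(c, 0.0) for c in AIRE_CATEGORIES)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError("category_proportions must sum to 1")
        if any(v < 0 for v in self.category_proportions.values()):
            raise ConfigError("category_proportions must be non-negative")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ConfigError("chromosome lengths must be positive")
        if not self.chrom_lengths:
            raise ConfigError("chrom_lengths must be nonempty")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        for mark, eff in self.mark_effects.items():
            bad = set(eff) - set(AIRE_CATEGORIES)
            if bad:
                raise ConfigError(f"mark_effects[{mark}]: unknown categories {bad}")
        for cat, (a, b) in self.detection_model.items():
            if cat not in AIRE_CATEGORIES:
                raise ConfigError(f"detection_model: unknown category {cat}")
            if a <= 0 or b <= 0:
                raise ConfigError("detection_model Beta parameters must be > 0")

    @property
    def marks(self) -> list[str]:
        return sorted(self.mark_effects)

    def rng(self, stage: int, extra: tuple[int, ...] = ()) -> np.random.Generator:
        """Per-stage substream of the master seed (fixed spawn keys)."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage, *extra)))


@dataclass
class SyntheticTruth:
    """Planted ground truth: one row per simulated gene."""

    table: pd.DataFrame   # index: gene id; category, true_tau, true_detection
    mark_effects: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ConfigError("duplicate gene ids in truth table")

    @property
    def categories(self) -> pd.Series:
        return self.table["category"]

    def induced_genes(self) -> list[str]:
        return list(self.table.index[self.table["category"].isin(INDUCED_CATEGORIES)])

    def genes_in(self, category: str) -> list[str]:
        return list(self.table.index[self.table["category"] == category])


def _exact_category_counts(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n genes over categories."""
    raw = {c: proportions.get(c, 0.0) * n for c in AIRE_CATEGORIES}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - math.floor(raw[c]), reverse=True)[:short]:
        counts[c] += 1
    return counts


def generate_truth(config: SimulationConfig) -> SyntheticTruth:
    """Assign categories (exact proportions, shuffled) and per-gene truths."""
    rng = config.rng(_STAGE_TRUTH)
    counts = _exact_category_counts(config.category_proportions, config.n_genes)
    cats = [c for c in AIRE_CATEGORIES for _ in range(counts[c])]
    rng.shuffle(cats)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    detection = np.empty(config.n_genes)
    for i, c in enumerate(cats):
        a, b = config.detection_model[c]
        detection[i] = rng.beta(a, b)
    table = pd.DataFrame({
        "category": cats,
        "true_tau": [TAU_TARGETS[c] for c in cats],
        "true_detection": detection,
    }, index=pd.Index(genes, name="gene_id"))
    return SyntheticTruth(table=table, mark_effects=config.mark_effects)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def generate_annotation(config: SimulationConfig) -> TssAnnotation:
    """Place gene TSSs uniformly at random with guaranteed spacing.

    Primary TSSs of distinct genes are at least ``2 * feature_window_bp +
    tss_jitter_bp`` apart, so that 1 kb feature windows of different genes
    can never share signal; extra transcript TSSs sit within
    ``tss_jitter_bp`` downstream of the primary.  A genome too small for the
    requested gene count raises :class:`SizingError`.
    """
    rng = config.rng(_STAGE_ANNOT)
    spacing = 2 * config.feature_window_bp + config.tss_jitter_bp
    margin = config.region_halfwidth_bp + config.tss_jitter_bp
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    # apportion genes to chromosomes by length (largest remainder)
    raw = lengths / lengths.sum() * config.n_genes
    per = np.floor(raw).astype(int)
    for i in np.argsort(raw - np.floor(raw))[::-1][: config.n_genes - per.sum()]:
        per[i] += 1
    tss: dict[str, list[tuple[str, int, str]]] = {}
    bodies: dict[str, tuple[str, int, int]] = {}
    gene_iter = iter(f"g{i:05d}" for i in range(config.n_genes))
    for chrom, L, n_c in zip(chroms, lengths.astype(int), per):
        if n_c == 0:
            continue
        slack = L - 2 * margin - (n_c - 1) * spacing - 1
        if slack < 0:
            raise SizingError(
                f"{chrom} ({L} bp) too small for {n_c} genes at "
                f"{spacing} bp spacing with {margin} bp margins")
        u = np.sort(rng.integers(0, slack + 1, size=n_c))
        positions = margin + u + np.arange(n_c) * spacing
        for pos in positions:
            gene = next(gene_iter)
            strand = "+" if rng.random() < 0.5 else "-"
            n_tx = 1 + rng.poisson(max(config.n_transcripts_per_gene - 1, 0))
            sites = [(chrom, int(pos), strand)]
            for _ in range(n_tx - 1):
                off = int(rng.integers(1, config.tss_jitter_bp + 1))
                p = pos + off if strand == "+" else pos - off
                sites.append((chrom, int(p), strand))
            tss[gene] = sites
            if strand == "+":
                body = (chrom, int(pos), int(min(pos + config.gene_length_bp, L)))
            else:
                body = (chrom, int(max(pos + 1 - config.gene_length_bp, 0)),
                        int(pos + 1))
            bodies[gene] = body
    return TssAnnotation(tss=tss, gene_bodies=bodies,
                         chrom_lengths=dict(config.chrom_lengths))


# ---------------------------------------------------------------------------
# ChIP / input tracks
# ---------------------------------------------------------------------------

def _binned_regions(annotation: TssAnnotation, config: SimulationConfig):
    """Merged, binned simulation regions (TSS +/- region_halfwidth) per chrom.

    Returns ``{chrom: (starts, ends, centers)}`` covering the union of the
    per-gene regions in ``bin_bp`` bins.
    """
    out = {}
    R, B = config.region_halfwidth_bp, config.bin_bp
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for gene, sites in annotation.tss.items():
        chrom, pos, _ = sites[0]
        L = annotation.chrom_end(chrom)
        lo = max(0, pos - R)
        hi = pos + R if L is None else min(pos + R, L)
        by_chrom.setdefault(chrom, []).append((lo, hi))
    for chrom, regions in by_chrom.items():
        merged = IntervalSet.from_intervals((chrom, a, b) for a, b in regions)
        starts_list, ends_list = [], []
        for a, b in zip(*merged.data[chrom]):
            edges = np.arange(a, b, B)
            starts_list.append(edges)
            ends_list.append(np.minimum(edges + B, b))  # clip to region end
        starts = np.concatenate(starts_list)
        ends = np.concatenate(ends_list)
        limit = annotation.chrom_end(chrom)
        if limit is not None:
            ends = np.minimum(ends, limit)
        out[chrom] = (starts, ends, (starts + ends) / 2.0)
    return out


def simulate_chip_tracks(annotation: TssAnnotation, truth: SyntheticTruth,
                         config: SimulationConfig
                         ) -> dict[str, dict[str, SignalTrack]]:
    """Per mark, a ChIP and an input track over binned TSS neighbourhoods.

    Input tracks are category-independent baseline noise; ChIP tracks
    multiply the baseline by ``exp(amplitude * g(d))`` where ``g`` is a
    Gaussian of sd ``bump_sd_bp`` in the distance ``d`` from the bin to the
    TSS, and the per-gene amplitude is the planted per-category shift plus
    ``N(0, noise_sd)``.  Values are stored at raw scale so that
    library-scaling recovers ``baseline_value`` units.
    """
    for mark, eff in truth.mark_effects.items():
        if mark not in config.mark_effects:
            raise ConfigError(f"unknown mark in mark_effects: {mark}")
    missing = [g for g in annotation.genes() if g not in truth.table.index]
    if missing:
        raise ConfigError(f"genes without category in truth: {missing[:5]}")
    regions = _binned_regions(annotation, config)
    genes = annotation.genes()
    cats = truth.categories
    tracks: dict[str, dict[str, SignalTrack]] = {}
    for mi, mark in enumerate(config.marks):
        rng = config.rng(_STAGE_TRACKS, (mi,))
        effects = config.mark_effects.get(mark, {})
        amp = {g: effects.get(cats[g], 0.0)
               + (rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0)
               for g in genes}
        chip_data, input_data = {}, {}
        for chrom, (starts, ends, centers) in regions.items():
            log_bump = np.zeros(len(starts))
            for g in genes:
                c0, pos, _ = annotation.tss[g][0]
                if c0 != chrom:
                    continue
                lo = np.searchsorted(ends, pos - config.region_halfwidth_bp,
                                     side="right")
                hi = np.searchsorted(starts, pos + config.region_halfwidth_bp,
                                     side="left")
                if hi <= lo:
                    continue
                # distance from the bin interval to the TSS, so the bin
                # containing the TSS carries the full planted amplitude
                d = np.maximum(
                    0.0, np.abs(centers[lo:hi] - pos) - config.bin_bp / 2.0)
                log_bump[lo:hi] += amp[g] * np.exp(
                    -0.5 * (d / config.bump_sd_bp) ** 2)
            if config.track_noise_sd > 0:
                eps_c = rng.normal(0.0, config.track_noise_sd, len(starts))
                eps_i = rng.normal(0.0, config.track_noise_sd, len(starts))
            else:
                eps_c = eps_i = np.zeros(len(starts))
            base = config.baseline_value
            chip_scaled = base * np.exp(log_bump + eps_c)
            input_scaled = base * np.exp(eps_i)
            chip_data[chrom] = (starts, ends,
                                chip_scaled * config.chip_library_size / 1e6)
            input_data[chrom] = (starts, ends,
                                 input_scaled * config.input_library_size / 1e6)
        tracks[mark] = {
            "chip": SignalTrack(data=chip_data,
                                library_size=config.chip_library_size),
            "input": SignalTrack(data=input_data,
                                 library_size=config.input_library_size),
        }
    return tracks


# ---------------------------------------------------------------------------
# Expression atlas
# ---------------------------------------------------------------------------

def simulate_expression_atlas(truth: SyntheticTruth,
                              config: SimulationConfig) -> pd.DataFrame:
    """Gene x tissue FPKM-like matrix with controllable tissue restriction.

    Tissue-restricted categories express strongly in one random tissue with
    the remaining tissues at Uniform(0, 0.2) of the maximum (tau ~ 0.9);
    OTHER genes are near-uniform, Uniform(0.7, 1.3) around a common level
    (tau ~ 0.23).
    """
    if config.n_tissues < 2:
        raise ConfigError("n_tissues must be >= 2 for tau to be defined")
    rng = config.rng(_STAGE_ATLAS)
    n_t = config.n_tissues
    tissues = [f"tissue_{i:02d}" for i in range(n_t)]
    rows = np.empty((len(truth.table), n_t))
    for i, (gene, row) in enumerate(truth.table.iterrows()):
        if row["category"] == "OTHER":
            level = rng.lognormal(2.0, 0.5)
            rows[i] = level * rng.uniform(0.7, 1.3, n_t)
        else:
            dom = int(rng.integers(n_t))
            peak = rng.lognormal(4.0, 0.5)
            x = peak * rng.uniform(0.0, 0.2, n_t)
            x[dom] = peak
            rows[i] = x
    return pd.DataFrame(rows, index=truth.table.index, columns=tissues)


# ---------------------------------------------------------------------------
# Single-cell counts
# ---------------------------------------------------------------------------

def simulate_single_cell(truth: SyntheticTruth, config: SimulationConfig):
    """Gene x cell counts plus ERCC spike-in rows with known molecules.

    A gene is detected (count >= 1) in Binomial(n_cells, p) cells for its
    planted detection proportion p; detected entries get 1 + NB(2, 0.5)
    counts.  Spike-in counts are ``capture_efficiency * molecules`` with
    lognormal noise, rounded; known molecules span 1..10^4 log-uniformly.

    Returns a :class:`airechrom.single_cell.CellCountMatrix`.
    """
    from .single_cell import SPIKEIN_PREFIX, CellCountMatrix

    if config.n_cells < 10:
        raise ConfigError("n_cells must be >= 10")
    p = truth.table["true_detection"].to_numpy()
    if np.any((p < 0) | (p > 1)):
        raise ConfigError("detection proportions must be in [0, 1]")
    rng = config.rng(_STAGE_CELLS)
    n_g, n_c = len(p), config.n_cells
    detected = rng.random((n_g, n_c)) < p[:, None]
    counts = np.where(detected, 1 + rng.negative_binomial(2, 0.5, (n_g, n_c)), 0)
    mol = np.logspace(0, 4, config.n_spikeins)
    noise = rng.normal(0.0, config.spikein_noise_sd,
                       (config.n_spikeins, n_c))
    spike_counts = np.floor(
        config.capture_efficiency * mol[:, None] * np.exp(noise) + 0.5
    ).astype(int)
    spike_ids = [f"{SPIKEIN_PREFIX}{i + 1:05d}" for i in range(config.n_spikeins)]
    cells = [f"cell_{j:04d}" for j in range(n_c)]
    frame = pd.DataFrame(
        np.vstack([counts, spike_counts]),
        index=pd.Index(list(truth.table.index) + spike_ids, name="gene_id"),
        columns=cells)
    molecules = pd.Series(mol, index=spike_ids, name="molecules")
    return CellCountMatrix(counts=frame, spikein_molecules=molecules)


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

def simulate_peaks(annotation: TssAnnotation, enrichment_factor: float,
                   config: SimulationConfig, n_peaks: int = 500,
                   flank_bp: int = 5000) -> IntervalSet:
    """Fixed-length peaks with plantable enrichment in gene +/- flank regions.

    Peak start positions are sampled from a density proportional to
    ``enrichment_factor`` inside the flanked gene bodies and 1 elsewhere in
    the genome; ``enrichment_factor == 1`` is exactly uniform placement over
    the genome (matching the null of :func:`randomized_enrichment`).
    """
    if enrichment_factor <= 0:
        raise ConfigError("enrichment_factor must be > 0")
    if n_peaks == 0:
        return IntervalSet(data={})
    rng = config.rng(_STAGE_PEAKS)
    genome = genome_workspace(config.chrom_lengths)
    target = flank_genes(annotation, flank_bp).intersect(genome)
    L = config.peak_length_bp
    # piecewise-constant start density over the concatenated genome
    segments = []   # (chrom, start, end, weight)
    for chrom in genome.chroms():
        gs, ge = genome.data[chrom]
        ts = target.data.get(chrom, (np.array([]), np.array([])))
        bounds = np.unique(np.concatenate([gs, ge, ts[0], ts[1]]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            inside = len(ts[0]) and bool(
                np.any((ts[0] <= a) & (ts[1] >= b)))
            segments.append((chrom, int(a), int(b),
                             enrichment_factor if inside else 1.0))
    weights = np.array([(b - a) * w for _, a, b, w in segments])
    probs = weights / weights.sum()
    choices = rng.choice(len(segments), size=n_peaks, p=probs)
    intervals = []
    for k in choices:
        chrom, a, b, _ = segments[k]
        start = int(rng.integers(a, b))
        end = min(start + L, int(config.chrom_lengths[chrom]))
        intervals.append((chrom, start, end))
    return IntervalSet.from_intervals(intervals)


# ---------------------------------------------------------------------------
# File output and config parsing
# ---------------------------------------------------------------------------

def parse_config_file(path) -> SimulationConfig:
    """Plain-text ``key = value`` config; dotted keys set nested maps.

    Example::

        n_genes = 500
        chrom_lengths.chr1 = 10000000
        mark_effects.H3K27me3.AIRE_DEPENDENT = 1.2
        detection_model.OTHER = 8, 3
    """
    kv: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key.startswith("pipeline."):
            continue  # orchestration settings live in the pipeline layer
        kv[key] = value
    fields = SimulationConfig.__dataclass_fields__
    kwargs: dict = {}
    for key, value in kv.items():
        parts = key.split(".")
        name = parts[0]
        if name not in fields:
            raise ConfigError(f"unknown config field {name!r}")
        if len(parts) == 1:
            typ = fields[name].type
            if name in ("chrom_lengths",):
                raise ConfigError(f"{name} needs a dotted key, e.g. {name}.chr1")
            if typ == "int":
                kwargs[name] = int(value)
            elif typ == "float":
                kwargs[name] = float(value)
            else:
                kwargs[name] = value
        elif name in ("chrom_lengths",):
            kwargs.setdefault(name, {})[parts[1]] = int(value)
        elif name == "category_proportions":
            kwargs.setdefault(name, {})[parts[1]] = float(value)
        elif name == "detection_model":
            a, b = (float(x) for x in value.split(","))
            kwargs.setdefault(name, dict(DEFAULT_DETECTION_MODEL))[parts[1]] = (a, b)
        elif name == "mark_effects":
            if len(parts) != 3:
                raise ConfigError("mark_effects keys are mark_effects.MARK.CATEGORY")
            d = kwargs.setdefault(
                name, {m: dict(DEFAULT_MARK_EFFECTS.get(m, {}))
                       for m in DEFAULT_MARKS})
            d.setdefault(parts[1], {})[parts[2]] = float(value)
        else:
            raise ConfigError(f"field {name!r} does not take dotted keys")
    return SimulationConfig(**kwargs)


def simulate_all(config: SimulationConfig):
    """Run every generator; returns (truth, annotation, tracks, atlas, cells, peaks)."""
    truth = generate_truth(config)
    annotation = generate_annotation(config)
    tracks = simulate_chip_tracks(annotation, truth, config)
    atlas = simulate_expression_atlas(truth, config)
    cells = simulate_single_cell(truth, config)
    peaks = simulate_peaks(annotation, enrichment_factor=3.0, config=config)
    return truth, annotation, tracks, atlas, cells, peaks


def write_outputs(outdir, config: SimulationConfig) -> dict[str, str]:
    """Generate everything and write the standard text formats to ``outdir``."""
    from . import genomic_signal as gs
    from .enrichment import write_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth, annotation, tracks, atlas, cells, peaks = simulate_all(config)
    paths: dict[str, str] = {}

    def _p(name: str) -> Path:
        paths[name] = str(outdir / name)
        return outdir / name

    truth.table.to_csv(_p("truth.tsv"), sep="\t")
    gs.write_tss_bed(annotation, _p("tss.bed"))
    gs.write_gene_bodies_bed(annotation, _p("genes.bed"))
    libs = []
    for mark, pair in tracks.items():
        for kind in ("chip", "input"):
            gs.write_bedgraph(pair[kind], _p(f"{mark}.{kind}.bedgraph"))
            libs.append((mark, kind, pair[kind].library_size))
    pd.DataFrame(libs, columns=["mark", "kind", "library_size"]).to_csv(
        _p("library_sizes.tsv"), sep="\t", index=False)
    atlas.to_csv(_p("expression_atlas.tsv"), sep="\t")
    cells.counts.to_csv(_p("sc_counts.tsv"), sep="\t")
    cells.spikein_molecules.to_frame().to_csv(_p("spikein_molecules.tsv"), sep="\t")
    write_bed(peaks, _p("peaks.bed"))
    return paths
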