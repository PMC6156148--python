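"""Single-cell count normalisation, spike-in calibration, and gene matching.

Counts are library-size adjusted with the DESeq median-of-ratios estimator,
converted to absolute molecule estimates per cell by ordinary least squares
of log10(known spike-in molecules) on log10(adjusted expression) over the
detected ERCC spike-ins, and summarised per gene as the detection
proportion: the fraction of calibratable cells with an estimated >= 1
molecule.  AIRE-induced genes are then matched one-to-one at random to
AIRE-independent tissue-restricted genes with a near-identical detection
proportion (within one cell's worth, +/-0.6% by default); induced genes
with no viable partner are discarded and reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("airechrom")

SPIKEIN_PREFIX = "ERCC-"
MATCH_TOLERANCE = 0.006   # "within detection in one cell" at ~167 cells
MIN_SPIKEINS_DETECTED = 3


@dataclass
class CellCountMatrix:
    """Genes (+ flagged spike-in rows) x cells of non-negative integer counts."""

    counts: pd.DataFrame                 # rows: genes and spike-ins; columns: cells
    spikein_molecules: pd.Series | None = None  # known molecules per spike-in row

    def __post_init__(self) -> None:
        if self.counts.shape[1] < 1:
            raise ValueError("count matrix needs >= 1 cell")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.spikein_molecules is not None:
            extra = set(self.spikein_molecules.index) - set(self.counts.index)
            if extra:
                raise ValueError(f"spike-in rows absent from matrix: {sorted(extra)[:5]}")

    @property
    def spikein_rows(self) -> pd.Index:
        return self.counts.index[self.counts.index.str.startswith(SPIKEIN_PREFIX)]

    @property
    def gene_rows(self) -> pd.Index:
        return self.counts.index[~self.counts.index.str.startswith(SPIKEIN_PREFIX)]

    @property
    def cells(self) -> pd.Index:
        return self.counts.columns


def size_factors(matrix: CellCountMatrix) -> pd.Series:
    """DESeq median-of-ratios size factor per cell.

    The reference set is the rows (genes and spike-ins) with a non-zero
    count in every cell; each cell's factor is the median over that set of
    count / geometric-mean-across-cells.
    """
    k = matrix.counts.to_numpy(dtype=float)
    ref = np.all(k > 0, axis=1)
    if not ref.any():
        raise ValueError(
            "median-of-ratios reference set is empty (no row detected in every "
            "cell); a pseudo-reference fallback is not applied silently")
    kr = k[ref]
    geo = np.exp(np.mean(np.log(kr), axis=1))
    factors = np.median(kr / geo[:, None], axis=0)
    return pd.Series(factors, index=matrix.cells, name="size_factor")


@dataclass
class SpikeinCalibration:
    """Per-cell log10-log10 regression of molecules on adjusted expression."""

    slope: pd.Series
    intercept: pd.Series
    r_squared: pd.Series
    calibratable: pd.Series   # bool per cell (>= 3 detected spike-ins)

    @property
    def retained_cells(self) -> pd.Index:
        return self.calibratable.index[self.calibratable]


def fit_spikein_calibration(matrix: CellCountMatrix,
                            factors: pd.Series | None = None) -> SpikeinCalibration:
    """OLS of log10(known molecules) on log10(adjusted counts), per cell.

    Only spike-ins detected in the cell (count > 0) enter the fit; cells with
    fewer than 3 detected spike-ins are flagged uncalibratable.
    """
    if matrix.spikein_molecules is None or len(matrix.spikein_molecules) == 0:
        raise ValueError("matrix has no spike-in molecule table")
    if factors is None:
        factors = size_factors(matrix)
    spike = matrix.counts.loc[matrix.spikein_molecules.index]
    mol = matrix.spikein_molecules.to_numpy(dtype=float)
    slope, intercept, r2, calib = {}, {}, {}, {}
    for cell in matrix.cells:
        c = spike[cell].to_numpy(dtype=float) / factors[cell]
        det = c > 0
        if det.sum() < MIN_SPIKEINS_DETECTED:
            slope[cell] = np.nan
            intercept[cell] = np.nan
            r2[cell] = np.nan
            calib[cell] = False
            continue
        res = stats.linregress(np.log10(c[det]), np.log10(mol[det]))
        slope[cell] = res.slope
        intercept[cell] = res.intercept
        r2[cell] = res.rvalue ** 2
        calib[cell] = True
    n_bad = sum(not v for v in calib.values())
    if n_bad:
        logger.info("spike-in calibration: %d cells uncalibratable", n_bad)
    return SpikeinCalibration(slope=pd.Series(slope), intercept=pd.Series(intercept),
                              r_squared=pd.Series(r2),
                              calibratable=pd.Series(calib))


@dataclass
class DetectionTable:
    """Gene -> proportion of retained cells with estimated molecules >= 1."""

    proportions: pd.Series
    n_cells: int


def detection_proportions(matrix: CellCountMatrix,
                          calibration: SpikeinCalibration,
                          factors: pd.Series | None = None) -> DetectionTable:
    """Per-gene fraction of calibratable cells with >= 1 estimated molecule.

    The molecule estimate is ``10 ** (intercept + slope * log10(adjusted
    count))`` for non-zero counts and 0 otherwise; the continuous estimate is
    thresholded at 1.
    """
    cells = calibration.retained_cells
    if len(cells) == 0:
        raise ValueError("no calibratable cells retained")
    if factors is None:
        factors = size_factors(matrix)
    counts = matrix.counts.loc[matrix.gene_rows, cells].to_numpy(dtype=float)
    adj = counts / factors[cells].to_numpy()
    with np.errstate(divide="ignore"):
        logc = np.log10(adj, where=adj > 0, out=np.full_like(adj, -np.inf))
    logmol = (calibration.intercept[cells].to_numpy()
              + calibration.slope[cells].to_numpy() * logc)
    # >= 1 estimated molecule; tiny slack so exact-boundary estimates
    # (log10 = 0 up to rounding) count as detected
    detected = (adj > 0) & (logmol >= -1e-9)
    props = pd.Series(detected.mean(axis=1), index=matrix.gene_rows,
                      name="detection_proportion")
    return DetectionTable(proportions=props, n_cells=len(cells))


@dataclass
class MatchedGeneSet:
    """Induced genes paired one-to-one with detection-matched independent TRAs."""

    pairs: pd.DataFrame           # induced, independent, abs_difference
    discarded: list[str] = field(default_factory=list)

    def genes(self) -> list[str]:
        return list(self.pairs["induced"]) + list(self.pairs["independent"])

    def labels(self) -> pd.Series:
        """1 for the induced member of each pair, 0 for the independent one."""
        lab = {g: 1 for g in self.pairs["induced"]}
        lab.update({g: 0 for g in self.pairs["independent"]})
        return pd.Series(lab)


def match_by_proportion(induced, candidates, detection: DetectionTable,
                        tolerance: float = MATCH_TOLERANCE,
                        seed: int = 0) -> MatchedGeneSet:
    """Randomly pair induced genes with candidates of similar detection.

    Induced genes are processed in seeded random order; each is matched
    uniformly at random, without replacement, to a candidate whose detection
    proportion differs by at most ``tolerance`` (genes expressed in no cells
    pair with genes expressed in no cells).  Induced genes with no viable
    partner are discarded and reported.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    induced = list(induced)
    candidates = list(candidates)
    if set(induced) & set(candidates):
        raise ValueError("induced and candidate lists must be disjoint")
    props = detection.proportions
    missing = [g for g in induced + candidates if g not in props.index]
    if missing:
        raise ValueError(f"genes without detection proportions: {missing[:5]}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(induced)))
    available = set(candidates)
    cand_props = props[candidates]
    rows = []
    discarded = []
    for i in order:
        g = induced[i]
        p = props[g]
        ok = cand_props.index[(cand_props - p).abs() <= tolerance]
        viable = [c for c in ok if c in available]
        if not viable:
            discarded.append(g)
            continue
        pick = viable[int(rng.integers(len(viable)))]
        available.discard(pick)
        rows.append((g, pick, abs(props[g] - props[pick])))
    pairs = pd.DataFrame(rows, columns=["induced", "independent", "abs_difference"])
    if discarded:
        logger.info("match_by_proportion: %d induced genes discarded", len(discarded))
    return MatchedGeneSet(pairs=pairs, discarded=discarded)


def read_counts_tsv(path, molecules_path=None) -> CellCountMatrix:
    """Count TSV (rows = genes, spike-ins prefixed 'ERCC-'; columns = cells)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    molecules = None
    if molecules_path is not None:
        molecules = pd.read_csv(molecules_path, sep="\t", index_col=0).iloc[:, 0]
    return CellCountMatrix(counts=counts, spikein_molecules=molecules)
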