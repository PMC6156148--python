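"""PCA of TSS chromatin features with covariate correlation overlays.

The genes x marks feature matrix is column-centred (and unit-scaled by
default, since marks differ in dynamic range) and decomposed by SVD.
Component signs are canonicalised so that each rotation's largest-magnitude
element is positive; for reporting correlations with per-gene covariates
(single-cell detection proportion, tau) PC1 may additionally be oriented by
its correlation with a reference feature, e.g. the mean repressive-mark
signal, so that "high PC1" reads as "repressive chromatin".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PcaResult:
    scores: pd.DataFrame       # genes x components (PC1, PC2, ...)
    rotations: pd.DataFrame    # marks x components
    variance_explained: np.ndarray  # fraction per component, non-increasing

    def oriented_pc1(self, reference: pd.Series) -> pd.Series:
        """PC1 scores with sign flipped, if needed, to correlate positively
        with ``reference`` (a per-gene feature such as mean repressive signal)."""
        pc1 = self.scores["PC1"]
        ref = reference.reindex(pc1.index)
        r = np.corrcoef(pc1, ref)[0, 1]
        return -pc1 if r < 0 else pc1


def pca(features, scale: bool = True) -> PcaResult:
    """Principal components of a genes x marks matrix.

    ``features`` is a DataFrame (or an object with ``.values`` DataFrame,
    e.g. a FeatureMatrix).  Columns are centred, and unit-scaled when
    ``scale`` is true; a zero-variance column with scaling requested is an
    error naming the column.
    """
    df = features if isinstance(features, pd.DataFrame) else features.values
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("PCA needs >= 2 genes and >= 2 marks")
    if df.isna().any().any():
        raise ValueError("PCA input has missing values")
    X = df.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if len(zero):
            raise ValueError(f"zero-variance column: {df.columns[zero[0]]!r}")
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|rotation| element of each component positive
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    names = [f"PC{k + 1}" for k in range(len(S))]
    scores = pd.DataFrame(U * S, index=df.index, columns=names)
    rotations = pd.DataFrame(Vt.T, index=df.columns, columns=names)
    var = S ** 2 / (df.shape[0] - 1)
    return PcaResult(scores=scores, rotations=rotations,
                     variance_explained=var / var.sum())


def spearman_with_pc1(result_or_scores, covariate: pd.Series):
    """Spearman rank correlation of PC1 scores with a per-gene covariate.

    Average ranks are used for ties; the two-sided p-value comes from the
    t-approximation.  Returns ``(rho, p)``.
    """
    if isinstance(result_or_scores, PcaResult):
        pc1 = result_or_scores.scores["PC1"]
    else:
        pc1 = pd.Series(result_or_scores)
    cov = covariate.reindex(pc1.index)
    if cov.isna().any():
        raise ValueError("covariate missing for some scored genes")
    rho, p = stats.spearmanr(pc1.to_numpy(), cov.to_numpy())
    return float(rho), float(p)
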