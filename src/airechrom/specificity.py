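"""Tau tissue-specificity index and tissue-restricted antigen calls.

For a gene with non-negative expression ``x_i`` across ``n`` tissues,

    tau = sum_i (1 - x_i / max(x)) / (n - 1)

tau is 0 for perfectly uniform expression and 1 for single-tissue
expression.  Genes with all-zero expression have no defined tau and are
flagged rather than silently assigned a value.  Genes with tau >= 0.8 are
called tissue-restricted antigens (TRAs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("airechrom")

TRA_TAU_THRESHOLD = 0.8


@dataclass
class TauResult:
    gene_id: str
    tau: float | None          # None when undefined (all-zero profile)
    scaled: np.ndarray | None  # x_i / max(x)

    @property
    def defined(self) -> bool:
        return self.tau is not None


def tau(x, gene_id: str = "") -> TauResult:
    """Tau of one expression profile across tissues."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("tau requires a 1-D profile over >= 2 tissues")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{gene_id or 'profile'}: non-finite expression")
    if np.any(x < 0):
        raise ValueError(f"{gene_id or 'profile'}: negative expression")
    m = x.max()
    if m == 0:
        return TauResult(gene_id=gene_id, tau=None, scaled=None)
    scaled = x / m
    t = float(np.sum(1.0 - scaled) / (len(x) - 1))
    return TauResult(gene_id=gene_id, tau=t, scaled=scaled)


def tau_table(expression: pd.DataFrame) -> pd.DataFrame:
    """Tau per gene of a genes x tissues matrix.

    Returns a DataFrame indexed by gene with columns ``tau`` (NaN when
    undefined) and ``is_tra``.
    """
    if expression.shape[1] < 2:
        raise ValueError("need >= 2 tissues to compute tau")
    x = expression.to_numpy(dtype=float)
    if np.any(x < 0):
        bad = expression.index[np.any(x < 0, axis=1)]
        raise ValueError(f"negative expression for genes: {list(bad[:5])}")
    m = x.max(axis=1)
    n = x.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.sum(1.0 - x / m[:, None], axis=1) / (n - 1)
    t[m == 0] = np.nan
    n_undef = int(np.sum(m == 0))
    if n_undef:
        logger.info("tau: %d all-zero genes flagged undefined", n_undef)
    out = pd.DataFrame({"tau": t}, index=expression.index)
    out["is_tra"] = classify_tra(out["tau"])
    return out


def classify_tra(tau_values: pd.Series | float,
                 threshold: float = TRA_TAU_THRESHOLD):
    """TRA call: tau >= threshold (boundary inclusive); undefined -> False + excluded."""
    if isinstance(tau_values, pd.Series):
        return (tau_values >= threshold).where(tau_values.notna(), other=False)
    if tau_values is None or np.isnan(tau_values):
        raise ValueError("tau undefined; gene should be excluded")
    return bool(tau_values >= threshold)


def read_expression_tsv(path) -> pd.DataFrame:
    """Gene x tissue TSV with a header row of tissue names."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tau_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")
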