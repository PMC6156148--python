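"""Ensemble neural-network classification of AIRE regulatory status.

Genes are classified as AIRE-induced (1) vs AIRE-independent (0) from their
TSS-proximal chromatin features with single-hidden-layer feedforward
networks (logistic activations on hidden and output units, sum-of-squared
-error loss, full-batch gradient descent).  Training stops when the SSE
decrease between successive epochs falls below 0.01.  Each of the (by
default 100) ensemble runs draws a fresh 67/33 train/test split, picks the
hidden-layer size by inner validation among 1 .. ceil(0.8 * n_inputs) - 1
candidates, chooses the output threshold empirically on the training set,
and reports:

* test accuracy — fraction of held-out genes categorised correctly;
* null accuracy — the accuracy obtained by predicting labels resampled
  i.i.d. from the empirical test-label distribution (closed form
  ``sum_c p_c**2``);
* Olden connection-weight importances — per input, the sum over hidden
  units of (input->hidden weight) * (hidden->output weight), scaled across
  inputs to [-1, 1] by the maximum absolute value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("airechrom")


class TrainingFailure(RuntimeError):
    """Non-finite loss or otherwise unusable training run."""


@dataclass
class TrainConfig:
    improvement_threshold: float = 0.01   # absolute SSE decrease per epoch
    train_fraction: float = 0.67
    max_epochs: int = 10_000
    min_epochs: int = 100                 # stopping rule applies after this
    learning_rate: float = 0.05           # applied to the mean-SSE gradient
    momentum: float = 0.9
    init_scale: float = 0.5
    inner_validation_fraction: float = 0.25
    n_null_resamples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.improvement_threshold <= 0:
            raise ValueError("improvement_threshold must be positive")


@dataclass
class MlpModel:
    """A trained single-hidden-layer network with logistic activations."""

    input_names: list[str]
    W_ih: np.ndarray          # (n_inputs, n_hidden)
    b_h: np.ndarray           # (n_hidden,)
    w_ho: np.ndarray          # (n_hidden,)
    b_o: float
    feature_mean: np.ndarray  # training-set standardisation
    feature_sd: np.ndarray
    output_threshold: float = 0.5
    converged: bool = False
    final_sse: float = np.nan
    epochs: int = 0

    @property
    def n_hidden(self) -> int:
        return self.W_ih.shape[1]

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Network output in (0, 1) for standardised features X."""
        H = _sigmoid(X @ self.W_ih + self.b_h)
        return _sigmoid(H @ self.w_ho + self.b_o)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.forward(X) >= self.output_threshold).astype(int)

    def standardize(self, features: np.ndarray) -> np.ndarray:
        return (features - self.feature_mean) / self.feature_sd


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def standardize_features(train: np.ndarray, *others: np.ndarray):
    """Zero-mean unit-variance scaling fit on the training set.

    Zero-variance columns are left centred only (scale 1).
    """
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    out = [(train - mean) / sd] + [(o - mean) / sd for o in others]
    return mean, sd, *out


def split_train_test(index, fraction: float = 0.67, seed: int = 0):
    """Seeded uniform split of gene ids; train size = floor(fraction * n)."""
    index = np.asarray(index)
    n = len(index)
    n_train = int(np.floor(fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError("split leaves an empty partition")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return index[perm[:n_train]], index[perm[n_train:]]


def train_mlp(X: np.ndarray, y: np.ndarray, n_hidden: int,
              config: TrainConfig, rng: np.random.Generator) -> MlpModel:
    """Full-batch gradient descent (with momentum) on SSE, logistic units.

    ``X`` must already be standardised on the training set.  Training stops
    when the decrease in training SSE between successive epochs falls below
    ``config.improvement_threshold`` (checked after ``min_epochs``, so the
    rule measures post-plateau progress), or at ``max_epochs``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    W = rng.normal(0, config.init_scale, size=(d, n_hidden))
    b_h = rng.normal(0, config.init_scale, size=n_hidden)
    v = rng.normal(0, config.init_scale, size=n_hidden)
    b_o = float(rng.normal(0, config.init_scale))
    lr, mom = config.learning_rate, config.momentum
    vel_W = np.zeros_like(W)
    vel_bh = np.zeros_like(b_h)
    vel_v = np.zeros_like(v)
    vel_bo = 0.0
    prev_sse = np.inf
    converged = False
    sse = np.nan
    epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        H = _sigmoid(X @ W + b_h)
        out = _sigmoid(H @ v + b_o)
        err = out - y
        sse = float(err @ err)
        if not np.isfinite(sse):
            raise TrainingFailure(f"non-finite SSE at epoch {epoch}")
        if epoch > config.min_epochs and prev_sse - sse < config.improvement_threshold:
            converged = True
            break
        prev_sse = sse
        # gradient of mean SSE (SSE / n), so the step size is n-independent
        d_out = (2.0 / n) * err * out * (1.0 - out)
        g_v = H.T @ d_out
        g_bo = d_out.sum()
        d_h = np.outer(d_out, v) * H * (1.0 - H)
        g_W = X.T @ d_h
        g_bh = d_h.sum(axis=0)
        vel_v = mom * vel_v - lr * g_v
        vel_bo = mom * vel_bo - lr * g_bo
        vel_W = mom * vel_W - lr * g_W
        vel_bh = mom * vel_bh - lr * g_bh
        v += vel_v
        b_o += vel_bo
        W += vel_W
        b_h += vel_bh
    return MlpModel(input_names=[], W_ih=W, b_h=b_h, w_ho=v, b_o=b_o,
                    feature_mean=np.zeros(d), feature_sd=np.ones(d),
                    converged=converged, final_sse=sse, epochs=epoch)


def hidden_node_candidates(n_inputs: int) -> list[int]:
    """Hidden-layer sizes tried: 1 .. ceil(0.8 * n_inputs) - 1."""
    if n_inputs < 2:
        raise ValueError("need >= 2 inputs to choose hidden-layer size")
    upper = int(np.ceil(0.8 * n_inputs)) - 1
    return list(range(1, max(upper, 1) + 1))


def select_hidden_nodes(X: np.ndarray, y: np.ndarray, config: TrainConfig,
                        rng: np.random.Generator) -> int:
    """Pick the hidden-layer size with best inner-validation accuracy.

    The training set is split 75/25 into an inner train/validation pair; for
    each candidate size a network is trained on the inner training portion,
    its output threshold chosen there, and accuracy measured on the inner
    validation portion.  Ties go to the smaller network.
    """
    n = len(y)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.inner_validation_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]
    best_h, best_acc = None, -np.inf
    for h in hidden_node_candidates(X.shape[1]):
        try:
            model = train_mlp(Xtr, ytr, h, config, rng)
            model = replace(model,
                            output_threshold=choose_output_threshold(model, Xtr, ytr))
            acc = evaluate(model, Xval, yval)
        except TrainingFailure:
            continue
        if acc > best_acc:  # strict: ties keep the smaller earlier candidate
            best_h, best_acc = h, acc
    if best_h is None:
        raise TrainingFailure("all hidden-node candidates failed to train")
    return best_h


def choose_output_threshold(model: MlpModel, X: np.ndarray,
                            y: np.ndarray) -> float:
    """Threshold maximising balanced accuracy on the training set.

    Candidates are the observed training outputs; ties resolve to the
    smallest threshold.  With single-class training labels balanced accuracy
    is undefined and 0.5 is returned with a warning.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        logger.warning("single-class training labels; output threshold 0.5")
        return 0.5
    out = model.forward(X)
    n_pos = int((y == 1).sum())
    n_neg = len(y) - n_pos
    grid = np.unique(out)
    best_t, best_bal = 0.5, -np.inf
    for t in grid:   # ascending, so strict > keeps the smallest tied threshold
        pred = out >= t
        tpr = np.sum(pred & (y == 1)) / n_pos
        tnr = np.sum(~pred & (y == 0)) / n_neg
        bal = (tpr + tnr) / 2
        if bal > best_bal:
            best_t, best_bal = float(t), bal
    return best_t


def evaluate(model: MlpModel, X: np.ndarray, y: np.ndarray) -> float:
    """Fraction of genes whose thresholded output matches the label."""
    return float(np.mean(model.predict(X) == np.asarray(y)))


@dataclass
class NullAccuracyResult:
    class_proportions: dict
    resampled_mean: float
    closed_form: float        # sum_c p_c ** 2
    n_resamples: int


def null_accuracy(test_labels, n_resamples: int = 1000,
                  seed: int = 0) -> NullAccuracyResult:
    """Accuracy from predicting resampled test-set categories.

    Predictions are drawn i.i.d. from the empirical label distribution of the
    test set and compared against the actual labels; the mean accuracy over
    resamples converges to the closed form ``sum_c p_c**2``.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    y = np.asarray(test_labels)
    classes, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    rng = np.random.default_rng(seed)
    draws = rng.choice(classes, size=(n_resamples, len(y)), p=p)
    acc = float(np.mean(draws == y[None, :]))
    return NullAccuracyResult(
        class_proportions=dict(zip(classes.tolist(), p.tolist())),
        resampled_mean=acc, closed_form=float(np.sum(p ** 2)),
        n_resamples=n_resamples)


def olden_importance(model: MlpModel, scaling: str = "max_abs") -> np.ndarray:
    """Olden connection-weight importance per input, scaled across inputs.

    ``raw_i = sum_h W_ih[i, h] * w_ho[h]`` (bias weights excluded); the raw
    values are scaled by the maximum absolute value (``max_abs``, default) or
    the sum of absolute values (``sum_abs``), preserving sign.  An all-zero
    raw vector scales to all zeros.
    """
    raw = model.W_ih @ model.w_ho
    if scaling == "max_abs":
        denom = np.max(np.abs(raw))
    elif scaling == "sum_abs":
        denom = np.sum(np.abs(raw))
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    if denom == 0:
        return np.zeros_like(raw)
    return raw / denom


@dataclass
class ClassifierReport:
    """Per-run metrics and ensemble summaries over the seeded runs."""

    runs: pd.DataFrame             # accuracy, null_accuracy, n_hidden, threshold
    importances: pd.DataFrame      # runs x inputs, scaled Olden importances
    mean_accuracy: float
    mean_null_accuracy: float
    accuracy_vs_null_p: float      # two-sided Wilcoxon signed-rank across runs
    importance_summary: pd.DataFrame  # mean, median, p (Wilcoxon vs 0) per input
    n_failed: int = 0


def _wilcoxon_p(diffs: np.ndarray) -> float:
    diffs = diffs[diffs != 0]
    if len(diffs) == 0:
        return 1.0
    return float(stats.wilcoxon(diffs).pvalue)


def run_ensemble(features: pd.DataFrame, labels: pd.Series, n_runs: int = 100,
                 config: TrainConfig | None = None,
                 reselect_hidden: bool = True) -> ClassifierReport:
    """Train and evaluate ``n_runs`` independently seeded networks.

    Each run: fresh 67/33 split, feature standardisation on the training
    portion, hidden-size selection (per run unless ``reselect_hidden`` is
    False), training, empirical output threshold, test accuracy, resampling
    null accuracy, and Olden importances.  Runs whose training produces a
    non-finite loss are excluded and logged; more than 20% failures aborts.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    config = config or TrainConfig()
    features = features.sort_index()
    labels = labels.reindex(features.index)
    if labels.isna().any():
        raise ValueError("labels missing for some genes")
    if labels.nunique() < 2:
        raise ValueError("need both classes present")
    X_all = features.to_numpy(dtype=float)
    y_all = labels.to_numpy(dtype=int)
    idx = np.arange(len(y_all))
    ss = np.random.SeedSequence(config.seed)
    rows, imps = [], []
    n_failed = 0
    fixed_hidden: int | None = None
    for run, child in enumerate(ss.spawn(n_runs)):
        rng = np.random.default_rng(child)
        split_seed = int(rng.integers(2 ** 31))
        tr, te = split_train_test(idx, config.train_fraction, split_seed)
        Xtr_raw, Xte_raw = X_all[tr], X_all[te]
        ytr, yte = y_all[tr], y_all[te]
        mean, sd, Xtr, Xte = standardize_features(Xtr_raw, Xte_raw)
        try:
            if reselect_hidden or fixed_hidden is None:
                h = select_hidden_nodes(Xtr, ytr, config, rng)
                if not reselect_hidden:
                    fixed_hidden = h
            else:
                h = fixed_hidden
            model = train_mlp(Xtr, ytr, h, config, rng)
        except TrainingFailure as exc:
            logger.warning("run %d failed: %s", run, exc)
            n_failed += 1
            continue
        model.input_names = list(features.columns)
        model.feature_mean, model.feature_sd = mean, sd
        model.output_threshold = choose_output_threshold(model, Xtr, ytr)
        acc = evaluate(model, Xte, yte)
        null = null_accuracy(yte, config.n_null_resamples,
                             seed=int(rng.integers(2 ** 31)))
        rows.append({"run": run, "accuracy": acc,
                     "null_accuracy": null.resampled_mean,
                     "null_closed_form": null.closed_form,
                     "n_hidden": h, "threshold": model.output_threshold,
                     "epochs": model.epochs, "converged": model.converged})
        imps.append(olden_importance(model))
    if n_failed > 0.2 * n_runs:
        raise TrainingFailure(f"{n_failed}/{n_runs} runs failed")
    runs = pd.DataFrame(rows).set_index("run")
    importances = pd.DataFrame(np.vstack(imps), columns=features.columns,
                               index=runs.index)
    diffs = (runs["accuracy"] - runs["null_accuracy"]).to_numpy()
    summary = pd.DataFrame({
        "mean": importances.mean(),
        "median": importances.median(),
        "p": [_wilcoxon_p(importances[c].to_numpy()) for c in importances],
    })
    return ClassifierReport(
        runs=runs, importances=importances,
        mean_accuracy=float(runs["accuracy"].mean()),
        mean_null_accuracy=float(runs["null_accuracy"].mean()),
        accuracy_vs_null_p=_wilcoxon_p(diffs),
        importance_summary=summary, n_failed=n_failed)
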