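"""Diagnostic-performance evaluation.

Implements the validation harness for the posterior-probability
diagnostic index:

* ROC curves and AUC by the rank (Mann-Whitney) method, ties counted 1/2;
* repeated random partitioning: B times (default 500), split the cohort
  into stratified training and validation halves, fit LogitBoost on the
  training half, score the validation half, and record the validation
  AUC — reported as mean +/- SD over the B partitions;
* a label-permutation null: each of B iterations couples one fresh
  uniform permutation of the cohort labels with one fresh partition and
  one fit/score cycle; the null AUC distribution centers at 0.5 for any
  unbiased procedure, and the empirical one-sided p-value for the
  observed mean AUC uses the add-one estimator (1 + k)/(1 + B), whose
  floor 1/501 at B = 500 is just under 0.002;
* sub-panel evaluation (e.g. 7 of 42 markers) through the identical
  pipeline, and a PCA score projection for cohort visualisation.

All randomness flows from one root seed through per-iteration spawned
streams, so observed and null runs are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import (
    DEFAULT_M,
    DEFAULT_Z_MAX,
    fit_logitboost,
    predict_posterior,
)

__all__ = [
    "ROCResult",
    "PartitionScheme",
    "ClassifierConfig",
    "EvaluationResult",
    "PCAResult",
    "roc_auc",
    "stratified_partition",
    "repeated_partition_eval",
    "permutation_null",
    "evaluate_comparison",
    "subset_panel_eval",
    "pca_scores",
    "summarize_table",
]


@dataclass(frozen=True)
class ROCResult:
    """ROC curve (FPR, TPR pairs) and its area."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class ClassifierConfig:
    """LogitBoost settings used inside the evaluation loops."""

    M: int = DEFAULT_M
    z_max: float = DEFAULT_Z_MAX


@dataclass(frozen=True)
class PartitionScheme:
    """Repeated random-partition settings.

    Defaults mirror the validation protocol: 500 iterations, two-thirds
    training fraction, stratified splits (required for cohorts of 20-38
    samples so both halves retain at least two members of each class).
    """

    n_iterations: int = 500
    train_fraction: float = 2.0 / 3.0
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class EvaluationResult:
    """AUC distributions for one comparison (observed and/or null)."""

    comparison: str
    panel_size: int
    aucs: np.ndarray | None = None
    null_aucs: np.ndarray | None = None
    seed: int | None = None

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.aucs, ddof=1))

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_aucs))

    @property
    def p_value(self) -> float:
        """Add-one empirical p: (1 + #{null AUC >= observed mean})/(B + 1)."""
        if self.aucs is None or self.null_aucs is None:
            raise ValueError("p-value requires both observed and null samples")
        b = len(self.null_aucs)
        k = int(np.sum(self.null_aucs >= self.mean_auc))
        return (1.0 + k) / (b + 1.0)

    @property
    def p_at_floor(self) -> bool:
        return self.null_aucs is not None and not np.any(
            self.null_aucs >= self.mean_auc
        )


@dataclass(frozen=True)
class PCAResult:
    """Principal-component score projection of a samples × markers matrix."""

    scores: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC by the rank method.

    The AUC equals the Mann-Whitney pair statistic: the fraction of
    (positive, negative) pairs in which the positive sample outscores the
    negative, ties contributing 1/2.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool) if np.asarray(labels).dtype != bool else np.asarray(labels)
    y = np.asarray(y, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    ranks = stats.rankdata(s, method="average")
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    # curve: sweep thresholds from high to low over distinct score values
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    return ROCResult(fpr=fpr, tpr=tpr, auc=float(auc))


def stratified_partition(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator, stratified: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/validation split leaving >= 2 of each class per half."""
    y = np.asarray(y)
    n = y.shape[0]
    idx = np.arange(n)
    if stratified:
        train_parts = []
        for cls in np.unique(y):
            members = idx[y == cls]
            if members.size < 4:
                raise ValueError(
                    f"class {cls!r} has {members.size} members; stratified "
                    "partitioning needs >= 4 per class"
                )
            k = int(round(train_fraction * members.size))
            k = max(2, min(members.size - 2, k))
            train_parts.append(rng.permutation(members)[:k])
        train = np.sort(np.concatenate(train_parts))
    else:
        for _ in range(1000):
            perm = rng.permutation(idx)
            k = max(4, min(n - 4, int(round(train_fraction * n))))
            train = np.sort(perm[:k])
            val = np.setdiff1d(idx, train)
            if all(
                min(np.sum(y[part] == cls) for part in (train, val)) >= 2
                for cls in np.unique(y)
            ):
                break
        else:
            raise ValueError("could not find a valid unstratified partition")
    val = np.setdiff1d(idx, train)
    return train, val


def _one_partition_auc(
    Xm: np.ndarray,
    y: np.ndarray,
    scheme: PartitionScheme,
    config: ClassifierConfig,
    rng: np.random.Generator,
) -> float:
    train, val = stratified_partition(y, scheme.train_fraction, rng, scheme.stratified)
    model = fit_logitboost(Xm[train], y[train], M=config.M, z_max=config.z_max)
    post = predict_posterior(model, Xm[val])
    return roc_auc(post, y[val] == 1).auc


def _coerce_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    Xm = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if y.dtype == bool:
        y = y.astype(int)
    return Xm, np.asarray(y, dtype=int)


def repeated_partition_eval(
    X,
    y,
    scheme: PartitionScheme,
    config: ClassifierConfig | None = None,
    comparison: str = "",
) -> EvaluationResult:
    """Mean and SD of validation AUC over B random partitions.

    Each iteration draws a fresh stratified split from its own spawned
    random stream, fits LogitBoost on the training half and scores the
    validation half; two runs with the same scheme seed give identical
    AUC samples.
    """
    config = config or ClassifierConfig()
    Xm, y = _coerce_xy(X, y)
    streams = np.random.SeedSequence([int(scheme.seed), 0]).spawn(scheme.n_iterations)
    aucs = np.array(
        [
            _one_partition_auc(Xm, y, scheme, config, np.random.default_rng(s))
            for s in streams
        ]
    )
    return EvaluationResult(
        comparison=comparison, panel_size=Xm.shape[1], aucs=aucs, seed=scheme.seed
    )


def permutation_null(
    X,
    y,
    scheme: PartitionScheme,
    config: ClassifierConfig | None = None,
    comparison: str = "",
) -> EvaluationResult:
    """Null AUC distribution under random permutation of cohort labels.

    Each of the B iterations permutes the labels uniformly at random,
    draws one fresh partition of the permuted data, fits, and records the
    validation AUC.  The resulting distribution centers at 0.5 when the
    procedure is unbiased, regardless of any true effect in the data.
    """
    config = config or ClassifierConfig()
    Xm, y = _coerce_xy(X, y)
    streams = np.random.SeedSequence([int(scheme.seed), 1]).spawn(scheme.n_iterations)
    null_aucs = np.empty(scheme.n_iterations)
    for b, s in enumerate(streams):
        rng = np.random.default_rng(s)
        y_perm = rng.permutation(y)
        null_aucs[b] = _one_partition_auc(Xm, y_perm, scheme, config, rng)
    return EvaluationResult(
        comparison=comparison,
        panel_size=Xm.shape[1],
        null_aucs=null_aucs,
        seed=scheme.seed,
    )


def evaluate_comparison(
    X,
    y,
    scheme: PartitionScheme,
    config: ClassifierConfig | None = None,
    comparison: str = "",
) -> EvaluationResult:
    """Observed and permutation-null AUC distributions plus empirical p."""
    observed = repeated_partition_eval(X, y, scheme, config, comparison)
    null = permutation_null(X, y, scheme, config, comparison)
    return EvaluationResult(
        comparison=comparison,
        panel_size=observed.panel_size,
        aucs=observed.aucs,
        null_aucs=null.null_aucs,
        seed=scheme.seed,
    )


def subset_panel_eval(
    X: pd.DataFrame,
    y,
    panel_subset,
    scheme: PartitionScheme,
    config: ClassifierConfig | None = None,
    comparison: str = "",
    with_null: bool = True,
) -> EvaluationResult:
    """Run the identical pipeline restricted to a marker subset.

    With the full panel this reproduces :func:`evaluate_comparison`
    exactly; with e.g. 7 of 42 markers it quantifies panel redundancy.
    """
    subset = list(panel_subset)
    if len(subset) == 0:
        raise ValueError("panel subset must be non-empty")
    if not isinstance(X, pd.DataFrame):
        raise ValueError("subset_panel_eval requires a marker-named DataFrame")
    missing = [m for m in subset if m not in X.columns]
    if missing:
        raise ValueError(f"unknown marker ids: {missing}")
    X_sub = X[subset]
    if with_null:
        return evaluate_comparison(X_sub, y, scheme, config, comparison)
    return repeated_partition_eval(X_sub, y, scheme, config, comparison)


def pca_scores(X, n_components: int) -> PCAResult:
    """Column-centered SVD projection for cohort visualisation.

    Scores are the sample coordinates on the leading principal axes;
    component variances are non-increasing and equal the eigenvalues of
    the sample covariance matrix.
    """
    Xm = np.asarray(X, dtype=float)
    n, p = Xm.shape
    if not (1 <= n_components <= min(n, p)):
        raise ValueError(f"n_components must lie in [1, {min(n, p)}]")
    centered = Xm - Xm.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    explained = (s[:n_components] ** 2) / (n - 1)
    return PCAResult(
        scores=scores, components=vt[:n_components], explained_variance=explained
    )


def summarize_table(results: list[EvaluationResult]) -> pd.DataFrame:
    """Report table: one row per comparison × panel size.

    Columns are Comparison, Biomarker Set, Mean, SD and P-value; the
    p-value is printed as "< 1/(B+1)" when no null AUC reaches the
    observed mean.
    """
    rows = []
    for r in results:
        if r.null_aucs is not None and r.aucs is not None:
            b = len(r.null_aucs)
            p_str = f"< {1.0 / (b + 1):.3g}" if r.p_at_floor else f"{r.p_value:.4g}"
        else:
            p_str = ""
        rows.append(
            {
                "Comparison": r.comparison,
                "Biomarker Set": r.panel_size,
                "Mean": round(r.mean_auc, 3) if r.aucs is not None else np.nan,
                "SD": round(r.sd_auc, 4) if r.aucs is not None else np.nan,
                "P-value": p_str,
            }
        )
    return pd.DataFrame(rows, columns=["Comparison", "Biomarker Set", "Mean", "SD", "P-value"])
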