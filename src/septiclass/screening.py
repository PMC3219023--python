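"""Marker-level screening statistics.

Two screening devices sit upstream of the classifier:

* a hard inclusion filter on signal intensity and fold change (strict
  ``signal > 100`` and ``fold change > 2.0`` by default, with fold change
  treated symmetrically so down-regulated markers also pass);
* a two-group moderated t-test in which per-marker variances are shrunk
  toward a common prior by empirical Bayes, with Holm step-down
  adjustment of the resulting p-values for family-wise error control.

The moderated statistic uses s~^2 = (d0 s0^2 + d s^2) / (d0 + d), where d
is the residual degrees of freedom of the two-group design and (d0, s0^2)
are prior degrees of freedom and prior variance.  When not supplied they
are estimated by method of moments from the marker-wise distribution of
s^2, using the fact that under the hierarchical model s^2 / s0^2 follows
an F(d, d0) distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreeningConfig",
    "expression_filter",
    "moderated_t",
    "holm_adjust",
    "estimate_prior",
]

_LARGE_D0 = 1e6  # effectively "all variances equal" when moments underdisperse


@dataclass(frozen=True)
class ScreeningConfig:
    """Thresholds and prior hyperparameters for marker screening."""

    signal_threshold: float = 100.0
    fold_change_threshold: float = 2.0
    two_sided_fold_change: bool = True
    prior_df: float | None = None
    prior_variance: float | None = None

    def __post_init__(self) -> None:
        if self.signal_threshold <= 0 or self.fold_change_threshold <= 0:
            raise ValueError("thresholds must be strictly positive")


def expression_filter(
    signal: float, fold_change: float, config: ScreeningConfig | None = None
) -> bool:
    """Inclusion filter: keep a marker iff signal AND fold change exceed
    their thresholds (strict inequalities).

    With ``two_sided_fold_change`` (the default) the effective fold change
    is max(ratio, 1/ratio), so a 2.5-fold down-regulation passes the same
    as a 2.5-fold up-regulation.
    """
    config = config or ScreeningConfig()
    if signal < 0:
        raise ValueError("signal must be >= 0")
    if fold_change <= 0:
        raise ValueError("fold_change must be > 0")
    fc = max(fold_change, 1.0 / fold_change) if config.two_sided_fold_change else fold_change
    return signal > config.signal_threshold and fc > config.fold_change_threshold


def estimate_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Method-of-moments estimate of (d0, s0^2) from marker-wise variances.

    Under the hierarchical model s^2 = s0^2 F with F ~ F(d, d0):
    E[F] = d0/(d0-2) and Var[F]/E[F]^2 = 2 (d + d0 - 2) / (d (d0 - 4)).
    Solving the second relation for d0 from the empirical dispersion ratio
    gives d0; the first then gives s0^2.  When the variances are no more
    dispersed than a single chi-square allows, d0 is effectively infinite
    and a large finite value is returned.
    """
    s2 = np.asarray(s2, dtype=float)
    m1 = float(np.mean(s2))
    v = float(np.var(s2, ddof=1)) if s2.size > 1 else 0.0
    if m1 <= 0:
        return _LARGE_D0, max(m1, np.finfo(float).tiny)
    r = v / m1**2
    denom = r * d - 2.0
    if denom <= 0:
        d0 = _LARGE_D0
    else:
        d0 = (4.0 * r * d + 2.0 * d - 4.0) / denom
        d0 = float(np.clip(d0, 1e-3, _LARGE_D0))
    s0_sq = m1 * (d0 - 2.0) / d0 if d0 > 2 else m1
    return d0, max(s0_sq, np.finfo(float).tiny)


def moderated_t(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated t-test per marker with Holm adjustment.

    ``matrix`` is samples × markers; ``labels`` is a boolean or two-level
    vector over samples (True/first level = group 1).  Returns one row per
    marker with group means, pooled SD, moderated SD, moderated t, raw p
    (two-sided, t distribution with d0 + d degrees of freedom) and the
    Holm-adjusted p.  With ``d0 = 0`` the statistic reduces exactly to the
    ordinary pooled-variance two-sample t.
    """
    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype != bool:
        levels = pd.unique(labels)
        if len(levels) != 2:
            raise ValueError(f"labels must have exactly two levels, got {len(levels)}")
        labels = labels == levels[0]
    n1 = int(labels.sum())
    n2 = int((~labels).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 samples")

    g1 = X[labels]
    g2 = X[~labels]
    mean1 = g1.mean(axis=0)
    mean2 = g2.mean(axis=0)
    v1 = g1.var(axis=0, ddof=1)
    v2 = g2.var(axis=0, ddof=1)
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d

    if d0 is None or s0_sq is None:
        d0_hat, s0_hat = estimate_prior(s2, d)
        d0 = d0_hat if d0 is None else d0
        s0_sq = s0_hat if s0_sq is None else s0_sq
    if d0 < 0 or s0_sq <= 0:
        raise ValueError("prior_df must be >= 0 and prior_variance > 0")

    s2_mod = (d0 * s0_sq + d * s2) / (d0 + d)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mean1 - mean2) / se, 0.0)
    df_total = min(d0 + d, _LARGE_D0)
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.minimum(p, 1.0)

    return pd.DataFrame(
        {
            "marker_id": list(matrix.columns),
            "mean_group1": mean1,
            "mean_group2": mean2,
            "pooled_sd": np.sqrt(s2),
            "moderated_sd": np.sqrt(s2_mod),
            "t": t,
            "p_value": p,
            "p_holm": holm_adjust(list(p)),
        }
    ).set_index("marker_id")


def holm_adjust(p_values: list[float]) -> np.ndarray:
    """Holm step-down family-wise-error adjustment.

    Sort ascending; adjusted p_(i) = max_{j <= i} min(1, (m - j + 1) p_(j));
    return in the original order.  Uniformly dominates Bonferroni.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adjusted_sorted = np.maximum.accumulate(scaled)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted
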