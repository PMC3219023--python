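"""Binary LogitBoost with weighted regression stumps.

LogitBoost performs stagewise additive logistic regression: it minimizes
the binomial negative log-likelihood by Newton steps, each step fitting a
weighted least-squares base learner to the working response

    z_i = (y*_i - p_i) / w_i,   w_i = p_i (1 - p_i),   y* in {0, 1},

and updating the additive score F <- F + f/2, with posterior probability
p(x) = 1 / (1 + exp(-2 F(x))).  The posterior is the diagnostic index
reported for each sample.

The base learner is a depth-1 regression stump: prediction is the left
value when the feature is <= the threshold, else the right value.  The
stump search is exact — every threshold midway between consecutive sorted
unique feature values is scored, on every feature — and fitting is fully
deterministic given (X, y, M, z_max).

Numerical safeguards follow standard practice: the working response is
clamped to +/- z_max (default 4) and the Newton weights are floored at
twice machine epsilon, so the algorithm remains stable as posteriors
approach 0 or 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Stump",
    "LogitBoostModel",
    "fit_stump_weighted",
    "fit_logitboost",
    "predict_score",
    "predict_posterior",
    "loocv_posteriors",
]

_W_FLOOR = 2.0 * np.finfo(float).eps
DEFAULT_M = 50
DEFAULT_Z_MAX = 4.0
_NLL_TOL = 1e-6


@dataclass(frozen=True)
class Stump:
    """Depth-1 regression tree: left value if x[feature] <= threshold."""

    feature: int
    threshold: float
    left: float
    right: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        x = np.asarray(X, dtype=float)[:, self.feature]
        return np.where(x <= self.threshold, self.left, self.right)


@dataclass(frozen=True)
class LogitBoostModel:
    """Fitted ensemble: F(x) = sum_m f_m(x) / 2, p(x) = 1/(1+exp(-2F))."""

    stumps: tuple[Stump, ...]
    n_features: int
    z_max: float = DEFAULT_Z_MAX
    feature_names: tuple[str, ...] | None = None
    nll_path: tuple[float, ...] = field(default_factory=tuple)

    @property
    def n_iterations(self) -> int:
        return len(self.stumps)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_features": self.n_features,
                "z_max": self.z_max,
                "feature_names": list(self.feature_names) if self.feature_names else None,
                "stumps": [
                    {"feature": s.feature, "threshold": s.threshold, "left": s.left, "right": s.right}
                    for s in self.stumps
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "LogitBoostModel":
        obj = json.loads(text)
        return cls(
            stumps=tuple(
                Stump(int(s["feature"]), float(s["threshold"]), float(s["left"]), float(s["right"]))
                for s in obj["stumps"]
            ),
            n_features=int(obj["n_features"]),
            z_max=float(obj["z_max"]),
            feature_names=tuple(obj["feature_names"]) if obj.get("feature_names") else None,
        )


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...] | None]:
    if isinstance(X, pd.DataFrame):
        return np.asarray(X, dtype=float), tuple(str(c) for c in X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, None


def _best_stump_matrix(
    Xs: np.ndarray, order: np.ndarray, z: np.ndarray, w: np.ndarray
) -> Stump:
    """Exact weighted least-squares stump over all features and thresholds.

    ``Xs`` is the column-wise pre-sorted feature matrix and ``order`` the
    per-column sort permutation; both are computed once per training set
    since they do not change across boosting iterations.  Ties in loss are
    broken toward the smallest threshold within a feature and the smallest
    feature index across features.
    """
    n, p = Xs.shape
    zs = z[order]
    ws = w[order]
    cum_w = np.cumsum(ws, axis=0)
    cum_s = np.cumsum(ws * zs, axis=0)
    w_tot = cum_w[-1]
    s_tot = cum_s[-1]
    c_tot = float(np.sum(w * z * z))

    mean_all = s_tot / w_tot
    loss_const = c_tot - float((s_tot[0] ** 2) / w_tot[0])
    const_stump = Stump(0, float(Xs[0, 0] - 1.0), float(mean_all[0]), float(mean_all[0]))
    if n < 2:
        return const_stump

    w_l = cum_w[:-1]
    s_l = cum_s[:-1]
    w_r = w_tot[None, :] - w_l
    s_r = s_tot[None, :] - s_l
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(w_l > 0, s_l * s_l / w_l, 0.0) + np.where(
            w_r > 0, s_r * s_r / w_r, 0.0
        )
    valid = Xs[1:] > Xs[:-1]
    gain = np.where(valid, gain, -np.inf)

    best_i = np.argmax(gain, axis=0)  # first max -> smallest threshold
    best_gain = gain[best_i, np.arange(p)]
    j = int(np.argmax(best_gain))  # first max -> smallest feature index
    if not np.isfinite(best_gain[j]):
        return const_stump
    loss_split = c_tot - float(best_gain[j])
    if loss_const <= loss_split + 1e-12 * max(1.0, abs(loss_split)):
        return const_stump

    i = int(best_i[j])
    threshold = 0.5 * (Xs[i, j] + Xs[i + 1, j])
    left = float(s_l[i, j] / w_l[i, j]) if w_l[i, j] > 0 else float(mean_all[j])
    right = float(s_r[i, j] / w_r[i, j]) if w_r[i, j] > 0 else float(mean_all[j])
    return Stump(j, float(threshold), left, right)


def fit_stump_weighted(feature_values, z, w) -> Stump:
    """Fit the loss-minimizing stump on a single feature.

    Minimizes sum_i w_i (z_i - f(x_i))^2 over thresholds midway between
    consecutive sorted unique feature values, with the left/right values
    the weighted means of z on each side.  A constant fit (threshold below
    the minimum) is returned when no split improves on it.
    """
    x = np.asarray(feature_values, dtype=float)
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (x.shape == z.shape == w.shape) or x.ndim != 1:
        raise ValueError("feature_values, z and w must be 1-D and equal length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if not np.sum(w) > 0:
        raise ValueError("total weight must be positive")
    order = np.argsort(x, kind="stable")[:, None]
    return _best_stump_matrix(x[order[:, 0]][:, None], order, z, w)


def stump_loss(stump: Stump, x: np.ndarray, z: np.ndarray, w: np.ndarray) -> float:
    """Weighted squared-error loss of a single-feature stump."""
    pred = np.where(np.asarray(x, float) <= stump.threshold, stump.left, stump.right)
    return float(np.sum(np.asarray(w, float) * (np.asarray(z, float) - pred) ** 2))


def _nll(y: np.ndarray, prob: np.ndarray) -> float:
    eps = np.finfo(float).eps
    prob = np.clip(prob, eps, 1.0 - eps)
    return float(-np.sum(y * np.log(prob) + (1.0 - y) * np.log(1.0 - prob)))


def fit_logitboost(
    X,
    y,
    M: int = DEFAULT_M,
    z_max: float = DEFAULT_Z_MAX,
    tol: float = _NLL_TOL,
) -> LogitBoostModel:
    """Fit binary LogitBoost with stump base learners.

    Initializes F = 0 (posterior 1/2 everywhere) and performs up to ``M``
    Newton steps, stopping early when the training negative log-likelihood
    improves by less than ``tol``.  Requires both classes present.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y)
    if y.dtype == bool:
        y = y.astype(int)
    y = np.asarray(y, dtype=float)
    if Xm.shape[0] != y.shape[0]:
        raise ValueError("X and y have mismatched lengths")
    if not (np.any(y == 0) and np.any(y == 1)) or np.any((y != 0) & (y != 1)):
        raise ValueError("y must contain both classes, coded 0/1")
    if M < 0:
        raise ValueError("M must be >= 0")

    n, p = Xm.shape
    order = np.argsort(Xm, axis=0, kind="stable")
    Xs = np.take_along_axis(Xm, order, axis=0)

    F = np.zeros(n)
    prob = np.full(n, 0.5)
    stumps: list[Stump] = []
    nll_path = [_nll(y, prob)]
    for _ in range(M):
        w = np.maximum(prob * (1.0 - prob), _W_FLOOR)
        z = np.clip((y - prob) / w, -z_max, z_max)
        stump = _best_stump_matrix(Xs, order, z, w)
        stumps.append(stump)
        F = F + 0.5 * stump.predict(Xm)
        prob = 1.0 / (1.0 + np.exp(-2.0 * F))
        nll = _nll(y, prob)
        nll_path.append(nll)
        if nll_path[-2] - nll < tol:
            break
    return LogitBoostModel(
        stumps=tuple(stumps),
        n_features=p,
        z_max=z_max,
        feature_names=names,
        nll_path=tuple(nll_path),
    )


def predict_score(model: LogitBoostModel, X) -> np.ndarray:
    """Additive score F(x) = sum of half stump outputs."""
    Xm, _ = _as_matrix(X)
    if Xm.shape[1] != model.n_features:
        raise ValueError(
            f"model expects {model.n_features} features, got {Xm.shape[1]}"
        )
    F = np.zeros(Xm.shape[0])
    for stump in model.stumps:
        F += 0.5 * stump.predict(Xm)
    return F


def predict_posterior(model: LogitBoostModel, X) -> np.ndarray:
    """Posterior probability of the positive class, the diagnostic index."""
    F = predict_score(model, X)
    return 1.0 / (1.0 + np.exp(-2.0 * F))


def loocv_posteriors(
    X,
    y,
    M: int = DEFAULT_M,
    z_max: float = DEFAULT_Z_MAX,
    preselect_k: int | None = None,
) -> np.ndarray:
    """Leave-one-out cross-validated posteriors.

    For each sample the whole procedure — including the optional marker
    pre-selection by moderated-t rank — is refit on the other n-1 samples
    and the held-out posterior recorded, so the prediction for a sample
    never sees its own label.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=int)
    n = Xm.shape[0]
    if n < 4:
        raise ValueError("LOOCV requires at least 4 samples")
    if np.sum(y == 0) < 2 or np.sum(y == 1) < 2:
        raise ValueError("each class needs at least 2 members")

    posteriors = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, y_tr = Xm[mask], y[mask]
        cols = np.arange(Xm.shape[1])
        if preselect_k is not None and preselect_k < Xm.shape[1]:
            from .screening import moderated_t

            frame = pd.DataFrame(X_tr, columns=[str(c) for c in cols])
            stats_tbl = moderated_t(frame, y_tr == 1)
            rank = np.argsort(-np.abs(stats_tbl["t"].to_numpy()), kind="stable")
            cols = np.sort(rank[:preselect_k])
        model = fit_logitboost(X_tr[:, cols], y_tr, M=M, z_max=z_max)
        posteriors[i] = predict_posterior(model, Xm[i : i + 1, cols])[0]
    return posteriors
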