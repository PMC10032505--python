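"""Model families (Cox with Breslow ties, logistic, Gaussian) and ranking metrics.

The Cox family works on right-censored survival data and exposes the scaled
negative log partial likelihood ``-l(beta) = -(2/n) * sum_i [ sum_{j in D_i}
x_j'beta - d_i * log(sum_{j in R_i} exp(x_j'beta)) ]`` where the sum runs over
unique failure times, ``D_i`` is the set of subjects failing at time ``t_i``
(Breslow handling of ties) and ``R_i`` the risk set.  Logistic and Gaussian
families use the mean negative Bernoulli log-likelihood and the mean squared
error respectively; both carry an unpenalized intercept appended as the last
coefficient.

All losses are convex and continuously differentiable in the coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "SurvivalDataset",
    "RegressionDataset",
    "RiskSetIndex",
    "ModelFamily",
    "CoxFamily",
    "LogisticFamily",
    "GaussianFamily",
    "get_family",
    "build_risk_index",
    "neg_log_partial_likelihood",
    "neg_log_partial_likelihood_gradient",
    "family_loss",
    "concordance_index",
    "roc_auc",
]


def _as_2d_float(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"feature matrix must be 2-dimensional, got ndim={arr.ndim}")
    return arr


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored survival data: features, follow-up times, event labels.

    Invariants enforced at construction: strictly positive times, binary
    events with at least one event, finite feature values, distinct feature
    names matching the number of columns.
    """

    features: np.ndarray
    times: np.ndarray
    events: np.ndarray
    feature_names: tuple[str, ...] = ()

    def __post_init__(self):
        X = _as_2d_float(self.features)
        t = np.asarray(self.times, dtype=float).ravel()
        e = np.asarray(self.events, dtype=int).ravel()
        if not (X.shape[0] == t.shape[0] == e.shape[0]):
            raise ValueError("features, times and events must have equal length")
        if not np.all(np.isfinite(X)):
            bad = np.argwhere(~np.isfinite(X))[0]
            raise ValueError(f"missing/non-finite feature value at row {bad[0]}, column {bad[1]}")
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("all follow-up times must be finite and strictly positive")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        if e.sum() == 0:
            raise ValueError("no events observed: partial likelihood is undefined")
        names = tuple(self.feature_names) or tuple(f"x{j}" for j in range(X.shape[1]))
        if len(names) != X.shape[1]:
            raise ValueError("feature_names length must equal the number of columns")
        if len(set(names)) != len(names):
            raise ValueError("feature names must be distinct")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)
        object.__setattr__(self, "feature_names", names)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    def subset(self, rows) -> "SurvivalDataset":
        rows = np.asarray(rows)
        return SurvivalDataset(
            self.features[rows], self.times[rows], self.events[rows], self.feature_names
        )


@dataclass(frozen=True)
class RegressionDataset:
    """Outcome-bearing data for the logistic and Gaussian families."""

    features: np.ndarray
    outcome: np.ndarray
    feature_names: tuple[str, ...] = ()

    def __post_init__(self):
        X = _as_2d_float(self.features)
        y = np.asarray(self.outcome, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("features and outcome must have equal length")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("missing/non-finite values in features or outcome")
        names = tuple(self.feature_names) or tuple(f"x{j}" for j in range(X.shape[1]))
        if len(names) != X.shape[1]:
            raise ValueError("feature_names length must equal the number of columns")
        if len(set(names)) != len(names):
            raise ValueError("feature names must be distinct")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "outcome", y)
        object.__setattr__(self, "feature_names", names)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    def subset(self, rows) -> "RegressionDataset":
        rows = np.asarray(rows)
        return RegressionDataset(self.features[rows], self.outcome[rows], self.feature_names)


@dataclass(frozen=True)
class RiskSetIndex:
    """Explicit risk-set structure over the unique failure times.

    ``risk_sets[i]`` holds the indices still at risk just before
    ``unique_failure_times[i]``; they are nested (each is a superset of the
    next) and ``failure_sets[i]`` is always contained in ``risk_sets[i]``.
    """

    unique_failure_times: np.ndarray
    failure_sets: tuple[np.ndarray, ...]
    failure_counts: np.ndarray
    risk_sets: tuple[np.ndarray, ...]

    @property
    def m(self) -> int:
        return len(self.unique_failure_times)


def build_risk_index(data: SurvivalDataset) -> RiskSetIndex:
    """Build the unique-failure-time index (times with events only)."""
    if data.events.sum() == 0:  # defensive; the dataset enforces this too
        raise ValueError("no events observed: partial likelihood is undefined")
    uft = np.unique(data.times[data.events == 1])
    failure_sets = tuple(
        np.flatnonzero((data.times == t) & (data.events == 1)) for t in uft
    )
    risk_sets = tuple(np.flatnonzero(data.times >= t) for t in uft)
    counts = np.array([len(d) for d in failure_sets])
    return RiskSetIndex(uft, failure_sets, counts, risk_sets)


class _CoxWork:
    """Pre-sorted arrays for O(n*p) evaluation of the Cox loss/gradient."""

    def __init__(self, data: SurvivalDataset):
        order = np.argsort(data.times, kind="stable")
        self.X = data.features[order]
        ts = data.times[order]
        ev = data.events[order]
        self.n = data.n
        uft = np.unique(ts[ev == 1])
        # risk set for failure time t is the suffix starting at searchsorted(t)
        self.risk_start = np.searchsorted(ts, uft, side="left")
        self.d = np.array(
            [np.count_nonzero((ts == t) & (ev == 1)) for t in uft], dtype=float
        )
        self.event_rows = np.flatnonzero(ev == 1)
        # constant term: sum over all failures of x_j
        self.xd_sum = self.X[self.event_rows].sum(axis=0)

    def value(self, beta: np.ndarray) -> float:
        eta = self.X @ beta
        M = eta.max()
        w = np.exp(eta - M)
        suffix = np.cumsum(w[::-1])[::-1]
        log_denom = M + np.log(suffix[self.risk_start])
        lin = eta[self.event_rows].sum()
        val = -(2.0 / self.n) * (lin - float(self.d @ log_denom))
        if not np.isfinite(val):
            raise FloatingPointError("non-finite Cox partial likelihood value")
        return val

    def gradient(self, beta: np.ndarray) -> np.ndarray:
        eta = self.X @ beta
        M = eta.max()
        w = np.exp(eta - M)
        suffix = np.cumsum(w[::-1])[::-1]
        # suffix sums of x_j * w_j, per column
        xw_suffix = np.cumsum((self.X * w[:, None])[::-1], axis=0)[::-1]
        means = xw_suffix[self.risk_start] / suffix[self.risk_start, None]
        grad = (2.0 / self.n) * (self.d @ means - self.xd_sum)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite Cox gradient")
        return grad


class BoundLoss:
    """A loss bound to a dataset: callable value and gradient in beta."""

    def __init__(self, value, gradient, n_features: int, has_intercept: bool):
        self.value = value
        self.gradient = gradient
        self.n_features = n_features
        self.has_intercept = has_intercept

    @property
    def dim(self) -> int:
        return self.n_features + (1 if self.has_intercept else 0)


class ModelFamily:
    """Abstract model family: loss, gradient, risk scores, accuracy metric."""

    name: str = ""
    has_intercept: bool = False

    def bind(self, data) -> BoundLoss:
        raise NotImplementedError

    def loss(self, beta, data) -> float:
        return self.bind(data).value(np.asarray(beta, dtype=float))

    def gradient(self, beta, data) -> np.ndarray:
        return self.bind(data).gradient(np.asarray(beta, dtype=float))

    def risk_score(self, beta, X) -> np.ndarray:
        """Linear predictor used for ranking metrics (intercept irrelevant)."""
        beta = np.asarray(beta, dtype=float)
        p = np.asarray(X).shape[1]
        return np.asarray(X) @ beta[:p]

    def accuracy(self, beta, data) -> float:
        raise NotImplementedError


class CoxFamily(ModelFamily):
    name = "cox"
    has_intercept = False

    def bind(self, data: SurvivalDataset) -> BoundLoss:
        work = _CoxWork(data)
        return BoundLoss(work.value, work.gradient, data.p, False)

    def accuracy(self, beta, data: SurvivalDataset) -> float:
        return concordance_index(self.risk_score(beta, data.features), data.times, data.events)


class LogisticFamily(ModelFamily):
    name = "logistic"
    has_intercept = True

    def bind(self, data: RegressionDataset) -> BoundLoss:
        y = data.outcome
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("logistic family requires a binary 0/1 outcome")
        X, n, p = data.features, data.n, data.p

        def value(beta):
            z = X @ beta[:p] + beta[p]
            val = float(np.mean(np.logaddexp(0.0, z) - y * z))
            if not np.isfinite(val):
                raise FloatingPointError("non-finite logistic loss")
            return val

        def gradient(beta):
            z = X @ beta[:p] + beta[p]
            r = 1.0 / (1.0 + np.exp(-z)) - y
            return np.concatenate([X.T @ r / n, [r.mean()]])

        return BoundLoss(value, gradient, p, True)

    def accuracy(self, beta, data: RegressionDataset) -> float:
        return roc_auc(self.risk_score(beta, data.features), data.outcome)


class GaussianFamily(ModelFamily):
    name = "gaussian"
    has_intercept = True

    def bind(self, data: RegressionDataset) -> BoundLoss:
        X, y, n, p = data.features, data.outcome, data.n, data.p

        def value(beta):
            r = y - (X @ beta[:p] + beta[p])
            return float(r @ r) / n

        def gradient(beta):
            r = y - (X @ beta[:p] + beta[p])
            return np.concatenate([-2.0 * (X.T @ r) / n, [-2.0 * r.mean()]])

        return BoundLoss(value, gradient, p, True)

    def accuracy(self, beta, data: RegressionDataset) -> float:
        # R^2 clipped to [0, 1]; only used when this family is cross-validated
        z = data.features @ np.asarray(beta)[: data.p] + np.asarray(beta)[data.p]
        ss_res = float(np.sum((data.outcome - z) ** 2))
        ss_tot = float(np.sum((data.outcome - data.outcome.mean()) ** 2))
        if ss_tot == 0:
            return 0.0
        return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))


_FAMILIES = {"cox": CoxFamily, "logistic": LogisticFamily, "gaussian": GaussianFamily}


def get_family(name) -> ModelFamily:
    if isinstance(name, ModelFamily):
        return name
    try:
        return _FAMILIES[name]()
    except KeyError:
        raise ValueError(f"unknown model family {name!r}; expected one of {sorted(_FAMILIES)}")


def neg_log_partial_likelihood(beta, data: SurvivalDataset) -> float:
    """Scaled negative log partial likelihood -l(beta), Breslow ties."""
    return CoxFamily().loss(beta, data)


def neg_log_partial_likelihood_gradient(beta, data: SurvivalDataset) -> np.ndarray:
    return CoxFamily().gradient(beta, data)


def family_loss(beta, data, family) -> float:
    return get_family(family).loss(beta, data)


def concordance_index(risk_scores, times, events) -> float:
    """Harrell's C-index.

    A pair (i, j) is comparable when ``times[i] < times[j]`` and subject i had
    an event.  Prediction ties within comparable pairs count 1/2; pairs with
    equal times are not comparable (so tied-event pairs never enter).
    """
    r = np.asarray(risk_scores, dtype=float).ravel()
    t = np.asarray(times, dtype=float).ravel()
    e = np.asarray(events, dtype=int).ravel()
    comparable = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs: C-index is undefined")
    concordant = int((comparable & (r[:, None] > r[None, :])).sum())
    tied = int((comparable & (r[:, None] == r[None, :])).sum())
    return (concordant + 0.5 * tied) / n_comp


def roc_auc(scores, labels) -> float:
    """Rank-statistic (Mann-Whitney) ROC-AUC; score ties count 1/2."""
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC-AUC requires both classes present")
    ranks = rankdata(s)
    return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
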