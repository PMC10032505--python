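"""Model assessment: cross-validation, bootstrap stability, kit costs,
Pareto fronts, SEM-based cardinality choice, and a greedy forward baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dc_penalty import KitStructure
from .likelihoods import get_family
from .nsopt import FitResult, SolverConfig, fit_smooth
from .path import CardinalityPath, fit_path

__all__ = [
    "CVSummary",
    "BootstrapSummary",
    "ParetoPoint",
    "kit_cost",
    "cross_validate",
    "bootstrap_selection",
    "pareto_front",
    "flag_dominated",
    "select_cardinality_sem",
    "greedy_forward_selection",
]

logger = logging.getLogger(__name__)


def kit_cost(selected_features, kits: KitStructure) -> float:
    """Total cost of the distinct kits touched by the selected features.

    Each kit's price is charged once no matter how many of its features are
    used; features absent from the kit table count as free singleton kits.
    """
    touched = set()
    total = 0.0
    for name in selected_features:
        kit = kits.kit_of.get(name, name)
        if kit not in touched:
            touched.add(kit)
            total += float(kits.kit_cost.get(kit, 0.0))
    return total


@dataclass(frozen=True)
class CVSummary:
    """Per-cardinality accuracy (mean and SEM over folds)."""

    cardinalities: np.ndarray
    mean_accuracy: np.ndarray
    sem_accuracy: np.ndarray
    fold_accuracies: np.ndarray  # folds x cardinalities
    folds: int
    metric: str

    def __post_init__(self):
        if np.any(self.sem_accuracy < 0):
            raise ValueError("SEM must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cardinality": self.cardinalities,
                "mean_accuracy": self.mean_accuracy,
                "sem_accuracy": self.sem_accuracy,
            }
        )


@dataclass(frozen=True)
class BootstrapSummary:
    """Feature-selection frequencies over bootstrap refits.

    ``frequency`` has one row per feature and one column per cardinality;
    entry (j, i) is the fraction of replicates whose stage-i model includes
    feature j.  ``sign`` holds the modal coefficient sign per cell.
    """

    frequency: pd.DataFrame
    sign: pd.DataFrame
    B: int


def _stratified_folds(strata, n_folds, rng):
    """Deterministic stratified fold assignment; returns an array of fold ids."""
    strata = np.asarray(strata)
    assignment = np.empty(strata.shape[0], dtype=int)
    for value in np.unique(strata):
        idx = np.flatnonzero(strata == value)
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(idx.size) % n_folds
    return assignment


def _fold_strata(data, family):
    if family.name == "cox":
        return data.events
    if family.name == "logistic":
        return data.outcome.astype(int)
    return np.zeros(data.n, dtype=int)


def _fold_ok(train, test, family):
    try:
        if family.name == "cox":
            if train.events.sum() == 0:
                return False
            comparable = (
                (test.times[:, None] < test.times[None, :]) & (test.events[:, None] == 1)
            )
            return bool(comparable.any())
        if family.name == "logistic":
            return len(np.unique(train.outcome)) == 2 and len(np.unique(test.outcome)) == 2
        return True
    except ValueError:
        return False


def cross_validate(data, family, K_max: int, folds: int = 5,
                   config: SolverConfig | None = None, seed: int = 0,
                   grouping: KitStructure | None = None, gamma: float | None = None,
                   standardize: bool = True) -> CVSummary:
    """K-fold cross-validation of the cardinality path.

    Folds are stratified on the event indicator (class label for logistic).
    Each fold refits the full path on its training split and scores every
    cardinality on the held-out split: C-index of the linear risk for Cox,
    ROC-AUC for logistic.  A split producing an unusable fold is redrawn with
    a fresh seed, up to 5 attempts.
    """
    family = get_family(family)
    config = config or SolverConfig()
    if folds < 2:
        raise ValueError("folds must be at least 2")
    strata = _fold_strata(data, family)
    for attempt in range(5):
        rng = np.random.default_rng(seed + attempt)
        assignment = _stratified_folds(strata, folds, rng)
        splits = []
        ok = True
        for f in range(folds):
            test_idx = np.flatnonzero(assignment == f)
            train_idx = np.flatnonzero(assignment != f)
            try:
                train, test = data.subset(train_idx), data.subset(test_idx)
            except ValueError:
                ok = False
                break
            if not _fold_ok(train, test, family):
                ok = False
                break
            splits.append((train, test))
        if ok:
            break
    else:
        raise ValueError("could not build valid folds after 5 attempts")

    metric = {"cox": "c-index", "logistic": "roc-auc"}.get(family.name, "r2")
    acc = np.empty((folds, K_max))
    for f, (train, test) in enumerate(splits):
        path = fit_path(train, family, K_max, config=config, grouping=grouping,
                        gamma=gamma, standardize=standardize)
        for i in range(1, K_max + 1):
            beta = path.solution(i).full_coefficients()
            acc[f, i - 1] = family.accuracy(beta, test)
    mean = acc.mean(axis=0)
    sem = acc.std(axis=0, ddof=1) / np.sqrt(folds)
    return CVSummary(
        cardinalities=np.arange(1, K_max + 1),
        mean_accuracy=mean,
        sem_accuracy=sem,
        fold_accuracies=acc,
        folds=folds,
        metric=metric,
    )


def bootstrap_selection(data, family, K_max: int, B: int = 100,
                        config: SolverConfig | None = None, seed: int = 0,
                        grouping: KitStructure | None = None,
                        gamma: float | None = None,
                        standardize: bool = True) -> BootstrapSummary:
    """Refit the path on B bootstrap resamples and tabulate how often each
    feature is selected at each cardinality, with the modal coefficient sign."""
    family = get_family(family)
    config = config or SolverConfig()
    if B < 1:
        raise ValueError("B must be at least 1")
    rng = np.random.default_rng(seed)
    p = data.p
    counts = np.zeros((p, K_max))
    sign_sum = np.zeros((p, K_max))
    retries = 0
    done = 0
    while done < B:
        idx = rng.integers(0, data.n, size=data.n)
        try:
            sample = data.subset(idx)
        except ValueError:
            retries += 1
            if retries > 10 * B:
                raise RuntimeError("bootstrap retry budget exhausted (degenerate resamples)")
            continue
        path = fit_path(sample, family, K_max, config=config, grouping=grouping,
                        gamma=gamma, standardize=standardize)
        for i in range(1, K_max + 1):
            coefs = path.solution(i).coefficients
            active = np.abs(coefs) > config.zero_tol
            counts[active, i - 1] += 1
            sign_sum[:, i - 1] += np.sign(coefs) * active
        done += 1
    freq = pd.DataFrame(
        counts / B,
        index=list(data.feature_names),
        columns=list(range(1, K_max + 1)),
    )
    sign = pd.DataFrame(
        np.sign(sign_sum),
        index=list(data.feature_names),
        columns=list(range(1, K_max + 1)),
    )
    return BootstrapSummary(frequency=freq, sign=sign, B=B)


@dataclass(frozen=True)
class ParetoPoint:
    """A (cost, accuracy) model summary; lower cost and higher accuracy win."""

    cost: float
    accuracy: float
    model_id: str = ""
    dominated: bool = False


def flag_dominated(points) -> list[ParetoPoint]:
    """Return copies of ``points`` (original order) with ``dominated`` set.

    A point is dominated when another point has cost <= and accuracy >= with
    at least one strict inequality; exact (cost, accuracy) ties are all kept.
    Sort-and-sweep implementation, invariant to input order.
    """
    points = list(points)
    if not points:
        return []
    order = sorted(range(len(points)), key=lambda i: (points[i].cost, -points[i].accuracy))
    flagged: list[ParetoPoint | None] = [None] * len(points)
    best_acc_cheaper = -np.inf
    i = 0
    while i < len(order):
        j = i
        cost = points[order[i]].cost
        while j < len(order) and points[order[j]].cost == cost:
            j += 1
        group = order[i:j]
        group_max = max(points[g].accuracy for g in group)
        for g in group:
            pt = points[g]
            dominated = not (pt.accuracy == group_max and group_max > best_acc_cheaper)
            flagged[g] = replace(pt, dominated=dominated)
        best_acc_cheaper = max(best_acc_cheaper, group_max)
        i = j
    return flagged


def pareto_front(points) -> list[ParetoPoint]:
    """The non-dominated subset, sorted by increasing cost."""
    return sorted(
        (pt for pt in flag_dominated(points) if not pt.dominated),
        key=lambda pt: (pt.cost, -pt.accuracy),
    )


def select_cardinality_sem(cv: CVSummary) -> int:
    """Smallest cardinality whose mean accuracy is within one SEM (taken at
    the best cardinality) of the maximum mean accuracy."""
    means = np.asarray(cv.mean_accuracy)
    if means.size == 0:
        raise ValueError("empty CV summary")
    i_star = int(np.argmax(means))  # ties -> smaller cardinality
    threshold = means[i_star] - cv.sem_accuracy[i_star]
    eligible = np.flatnonzero(means >= threshold)
    return int(cv.cardinalities[eligible[0]])


def greedy_forward_selection(data, family, K_max: int,
                             config: SolverConfig | None = None,
                             standardize: bool = True) -> CardinalityPath:
    """Greedy forward baseline: at each stage add the single feature whose
    unpenalized restricted refit most decreases the loss.  Returns a path in
    the same shape as the cardinality-constrained fit."""
    family = get_family(family)
    config = config or SolverConfig()
    if not 1 <= K_max <= data.p:
        raise ValueError(f"K_max={K_max} out of range [1, {data.p}]")
    if standardize:
        from .path import _standardize, _destandardize_result

        Xs, mu, sd = _standardize(data.features)
        args = (data.times, data.events) if hasattr(data, "times") else (data.outcome,)
        work = type(data)(Xs, *args, data.feature_names)
    else:
        work = data
        mu, sd = np.zeros(data.p), np.ones(data.p)
    bound = family.bind(work)
    full = fit_smooth(work, family)
    support: list[int] = []
    solutions = []
    for stage in range(1, K_max + 1):
        best = None
        for j in range(data.p):
            if j in support:
                continue
            trial = support + [j]
            beta = fit_smooth(work, family, support=trial)
            val = bound.value(beta)
            if best is None or val < best[0] - 1e-12:
                best = (val, j, beta)
        val, j, beta = best
        support.append(j)
        coefs = beta[: data.p]
        solutions.append(
            FitResult(
                coefficients=coefs,
                objective=val,
                penalty_residual=0.0,
                nnz=int(np.count_nonzero(np.abs(coefs) > config.zero_tol)),
                converged=True,
                rho_used=0.0,
                intercept=float(beta[data.p]) if bound.has_intercept else None,
            )
        )
    if standardize:
        from .path import _destandardize_result as _destd

        solutions = [_destd(s, mu, sd) for s in solutions]
        mle = full[: data.p] / sd
        if bound.has_intercept:
            mle = np.concatenate([mle, [full[data.p] - float(np.sum(full[: data.p] * mu / sd))]])
    else:
        mle = full
    return CardinalityPath(
        mle=mle,
        mle_objective=bound.value(full),
        solutions=tuple(solutions),
        K_max=K_max,
        family=family.name,
        feature_names=tuple(data.feature_names),
        config=config,
        standardized=standardize,
    )


def frequency_heatmap(summary: BootstrapSummary, ax=None):
    """Features x cardinality heatmap of bootstrap selection frequencies."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * len(summary.frequency) + 1))
    data = summary.frequency.values
    im = ax.imshow(data, aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_yticks(range(len(summary.frequency.index)))
    ax.set_yticklabels(summary.frequency.index)
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels(summary.frequency.columns)
    ax.set_xlabel("cardinality")
    ax.figure.colorbar(im, ax=ax, label="selection frequency")
    return ax


def pareto_plot(points, ax=None):
    """Scatter of cost vs accuracy with the non-dominated front highlighted."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    front = pareto_front(points)
    ax.scatter([p.cost for p in points], [p.accuracy for p in points],
               color="grey", label="all models")
    ax.plot([p.cost for p in front], [p.accuracy for p in front],
            "o-", color="crimson", label="Pareto front")
    ax.set_xlabel("cost")
    ax.set_ylabel("accuracy")
    ax.legend()
    return ax
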