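"""Incremental multi-start cardinality path.

Stage 0 solves the unregularized convex problem for the dense optimum
``beta_bar``.  Stage i (i = 1..K_max) builds starting points by substituting
one coordinate (one kit, in grouped mode) of the previous solution with its
value in ``beta_bar``, keeping only candidates whose support exceeds i-1,
solves the rho-escalated penalized problem from each, and selects the
candidate with the smallest model loss.  The previous stage's solution is
always included in the comparison, so the path objective is non-increasing
in the cardinality.

For high-dimensional problems a screening step ranks candidates by a
one-dimensional solve along the substituted coordinate and keeps only the
best fraction gamma of them; gamma = 1 reproduces the full multi-start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from io import StringIO

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.optimize import minimize_scalar

from .dc_penalty import KitStructure, group_indices, kit_l0, l0_pseudonorm
from .likelihoods import get_family
from .nsopt import FitResult, SolverConfig, fit_smooth, solve_penalized

__all__ = [
    "StartingPointSet",
    "CardinalityPath",
    "PathStageError",
    "generate_starting_points",
    "accelerate_starts",
    "fit_path",
]

logger = logging.getLogger(__name__)


class PathStageError(RuntimeError):
    pass


@dataclass(frozen=True)
class StartingPointSet:
    """Stage-i starting points; each differs from ``base`` in one candidate
    coordinate (or kit) whose index is recorded in ``candidate_ids``."""

    stage: int
    base: np.ndarray
    points: tuple
    candidate_ids: tuple

    def __len__(self):
        return len(self.points)


def _support_count(beta, groups):
    return kit_l0(beta, groups) if groups is not None else l0_pseudonorm(beta)


def generate_starting_points(beta_prev, beta_mle, stage: int, groups=None) -> StartingPointSet:
    """Substitute each coordinate (kit) of beta_prev with its unregularized
    value and keep candidates whose support strictly exceeds stage-1."""
    beta_prev = np.asarray(beta_prev, dtype=float)
    beta_mle = np.asarray(beta_mle, dtype=float)
    points, ids = [], []
    if groups is None:
        blocks = [np.array([j]) for j in range(beta_prev.size)]
    else:
        blocks = list(groups)
    for j, idx in enumerate(blocks):
        cand = beta_prev.copy()
        cand[idx] = beta_mle[idx]
        if _support_count(cand, groups) > stage - 1:
            points.append(cand)
            ids.append(j)
    return StartingPointSet(stage, beta_prev, tuple(points), tuple(ids))


def accelerate_starts(candidates: StartingPointSet, data, family, gamma: float,
                      beta_mle=None, intercept: float = 0.0) -> StartingPointSet:
    """Keep the ceil(gamma * |candidates|) starting points with the lowest
    one-dimensional loss along their substituted coordinate (kit)."""
    if not 0.0 < gamma <= 1.0:
        raise ValueError("gamma must lie in (0, 1]")
    if gamma == 1.0 or len(candidates) <= 1:
        return candidates
    family = get_family(family)
    bound = family.bind(data)
    base = candidates.base
    keep = int(np.ceil(gamma * len(candidates)))
    scores = []
    for point, j in zip(candidates.points, candidates.candidate_ids):
        direction = point - base  # supported on the substituted block only
        nrm = np.linalg.norm(direction)
        if nrm == 0:
            scores.append(bound_value_at(bound, base, intercept))
            continue
        unit = direction / nrm

        def phi(t):
            return bound_value_at(bound, base + t * unit, intercept)

        res = minimize_scalar(phi, bracket=(0.0, max(nrm, 1e-3)), options={"maxiter": 60})
        scores.append(float(res.fun) if np.isfinite(res.fun) else phi(nrm))
    order = np.argsort(np.asarray(scores), kind="stable")[:keep]
    order = np.sort(order)  # deterministic, preserves candidate ordering
    return StartingPointSet(
        candidates.stage,
        base,
        tuple(candidates.points[i] for i in order),
        tuple(candidates.candidate_ids[i] for i in order),
    )


def bound_value_at(bound, coefs, intercept):
    if bound.has_intercept:
        return bound.value(np.concatenate([coefs, [intercept]]))
    return bound.value(np.asarray(coefs, dtype=float))


def _standardize(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def _destandardize_result(res: FitResult, mu, sd) -> FitResult:
    coefs = res.coefficients / sd
    intercept = res.intercept
    if intercept is not None:
        intercept = float(intercept - np.sum(res.coefficients * mu / sd))
    return replace(res, coefficients=coefs, intercept=intercept)


@dataclass(frozen=True)
class CardinalityPath:
    """Solutions beta_i* for i = 1..K_max plus the dense optimum beta_bar."""

    mle: np.ndarray  # full coefficient vector (intercept last when present)
    mle_objective: float
    solutions: tuple  # FitResult per stage, index 0 <-> cardinality 1
    K_max: int
    family: str
    feature_names: tuple
    grouping: KitStructure | None = None
    config: SolverConfig = field(default_factory=SolverConfig)
    standardized: bool = True

    def __post_init__(self):
        for i, sol in enumerate(self.solutions, start=1):
            if sol.nnz > i:
                raise ValueError(f"stage {i} solution has {sol.nnz} active > {i}")

    def solution(self, cardinality: int) -> FitResult:
        return self.solutions[cardinality - 1]

    def support(self, cardinality: int, zero_tol: float | None = None) -> tuple:
        tol = self.config.zero_tol if zero_tol is None else zero_tol
        coefs = self.solution(cardinality).coefficients
        return tuple(
            n for n, c in zip(self.feature_names, coefs) if abs(c) > tol
        )

    @property
    def objectives(self) -> np.ndarray:
        return np.array([s.objective for s in self.solutions])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        p = len(self.feature_names)

        def fmt(vec):
            return ";".join(repr(float(v)) for v in vec)

        mle_coefs = self.mle[:p]
        rows.append(
            dict(
                stage=0,
                nnz=l0_pseudonorm(mle_coefs, self.config.zero_tol),
                objective=self.mle_objective,
                rho_used=0.0,
                converged=True,
                features=";".join(self.feature_names),
                coefficients=fmt(mle_coefs),
                intercept=float(self.mle[p]) if self.mle.size > p else np.nan,
            )
        )
        for i, sol in enumerate(self.solutions, start=1):
            rows.append(
                dict(
                    stage=i,
                    nnz=sol.nnz,
                    objective=sol.objective,
                    rho_used=sol.rho_used,
                    converged=sol.converged,
                    features=";".join(self.support(i)),
                    coefficients=fmt(sol.coefficients),
                    intercept=np.nan if sol.intercept is None else sol.intercept,
                )
            )
        return pd.DataFrame(rows)

    def to_csv(self, path_or_buf):
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, family: str = "cox",
                   config: SolverConfig | None = None) -> "CardinalityPath":
        config = config or SolverConfig()
        df = df.sort_values("stage").reset_index(drop=True)
        head = df.iloc[0]
        names = tuple(str(head["features"]).split(";"))
        mle_coefs = np.array([float(v) for v in str(head["coefficients"]).split(";")])
        intercept = head["intercept"]
        mle = mle_coefs if pd.isna(intercept) else np.concatenate([mle_coefs, [float(intercept)]])
        sols = []
        for _, row in df.iloc[1:].iterrows():
            icpt = row["intercept"]
            sols.append(
                FitResult(
                    coefficients=np.array(
                        [float(v) for v in str(row["coefficients"]).split(";")]
                    ),
                    objective=float(row["objective"]),
                    penalty_residual=0.0,
                    nnz=int(row["nnz"]),
                    converged=bool(row["converged"]),
                    rho_used=float(row["rho_used"]),
                    intercept=None if pd.isna(icpt) else float(icpt),
                )
            )
        return cls(
            mle=mle,
            mle_objective=float(head["objective"]),
            solutions=tuple(sols),
            K_max=len(sols),
            family=family,
            feature_names=names,
            config=config,
        )

    @classmethod
    def read_csv(cls, path, family: str = "cox") -> "CardinalityPath":
        return cls.from_frame(pd.read_csv(path), family=family)


def _solve_candidate(data, family, stage, start, config, groups, has_intercept, intercept):
    beta0 = np.concatenate([start, [intercept]]) if has_intercept else start
    return solve_penalized(data, family, stage, beta0, config, groups=groups)


def fit_path(data, family, K_max: int, config: SolverConfig | None = None,
             grouping: KitStructure | None = None, gamma: float | None = None,
             standardize: bool = True, n_jobs: int = 1) -> CardinalityPath:
    """Run the incremental multi-start path up to cardinality K_max.

    Features are z-scored internally by default (statistics from ``data``)
    and the reported coefficients are mapped back to the original scale.
    Candidate solves within one stage are independent; they are reduced in
    candidate order so parallel execution cannot change the selected model.
    """
    family = get_family(family)
    config = config or SolverConfig()
    groups = None
    if grouping is not None:
        groups = group_indices(grouping, data.feature_names)
    p = data.p
    limit = len(groups) if groups is not None else p
    if not 1 <= K_max <= limit:
        raise ValueError(f"K_max={K_max} out of range [1, {limit}]")

    if standardize:
        Xs, mu, sd = _standardize(data.features)
        work = type(data)(Xs, *_outcome_args(data), data.feature_names)
    else:
        work = data
        mu = np.zeros(p)
        sd = np.ones(p)

    bound = family.bind(work)
    beta_bar_full = fit_smooth(work, family)
    mle_objective = bound.value(beta_bar_full)
    beta_bar = beta_bar_full[:p]
    mle_intercept = float(beta_bar_full[p]) if bound.has_intercept else 0.0

    if gamma is None:
        gamma = 1.0 if limit < 100 else 0.2

    beta_prev = np.zeros(p)
    prev_result: FitResult | None = None
    solutions = []
    for stage in range(1, K_max + 1):
        sps = generate_starting_points(beta_prev, beta_bar, stage, groups=groups)
        if gamma < 1.0 and len(sps) > 1:
            sps = accelerate_starts(sps, work, family, gamma, intercept=mle_intercept)
        results = []
        if len(sps) > 0:
            if n_jobs == 1:
                results = [
                    _solve_candidate(work, family, stage, s, config, groups,
                                     bound.has_intercept, mle_intercept)
                    for s in sps.points
                ]
            else:
                results = Parallel(n_jobs=n_jobs)(
                    delayed(_solve_candidate)(
                        work, family, stage, s, config, groups,
                        bound.has_intercept, mle_intercept)
                    for s in sps.points
                )
        converged = [r for r in results if r is not None and r.converged]
        if not converged and prev_result is None:
            diag = [
                f"candidate {j}: nnz={r.nnz} rho={r.rho_used:.3g}"
                for j, r in zip(sps.candidate_ids, results) if r is not None
            ]
            raise PathStageError(
                f"no converged candidate at stage {stage}; " + "; ".join(diag)
            )
        best = min(converged, key=lambda r: r.objective) if converged else None
        # monotonicity guard: the previous solution is feasible at this stage
        if prev_result is not None and (best is None or prev_result.objective < best.objective):
            best = prev_result
        solutions.append(best)
        prev_result = best
        beta_prev = best.coefficients
        logger.info(
            "stage %d: %d starts, nnz=%d, objective=%.6g",
            stage, len(sps), best.nnz, best.objective,
        )

    mle_out = beta_bar / sd
    if bound.has_intercept:
        mle_out = np.concatenate(
            [mle_out, [mle_intercept - float(np.sum(beta_bar * mu / sd))]]
        )
    solutions = tuple(_destandardize_result(s, mu, sd) for s in solutions)
    return CardinalityPath(
        mle=mle_out,
        mle_objective=mle_objective,
        solutions=solutions,
        K_max=K_max,
        family=family.name,
        feature_names=tuple(data.feature_names),
        grouping=grouping,
        config=config,
        standardized=standardize,
    )


def _outcome_args(data):
    if hasattr(data, "times"):
        return (data.times, data.events)
    return (data.outcome,)
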