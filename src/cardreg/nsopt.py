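"""Nonsmooth DC descent solver and penalty-parameter escalation.

The penalized objective ``f(beta) = loss(beta) + rho*(||beta||_1 -
|||beta|||_[K])`` is minimized by a DCA-style outer loop: the concave part
``-f2`` is linearized at the current iterate through one of its subgradients,
and the resulting convex subproblem ``loss(beta) + rho*||beta||_1 -
g'beta`` is solved by a monotone accelerated proximal-gradient method with
backtracking (soft-thresholding proximal step, so coefficients become exact
zeros).  The penalty parameter rho is escalated on a geometric grid, always
restarting from the original starting point, until the solution satisfies the
cardinality bound or the grid is exhausted.

The escalation loop accepts a solution with *at most* K active features: a
sparser solution is feasible for the cardinality constraint and raising rho
further cannot fill the support back up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .dc_penalty import (
    dc_penalty_value,
    f2_subgradient,
    kit_l0,
    l0_pseudonorm,
    PenaltySpec,
)
from .likelihoods import get_family

__all__ = ["SolverConfig", "FitResult", "SolverError", "minimize_dc", "solve_penalized", "fit_smooth"]

logger = logging.getLogger(__name__)


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolverConfig:
    """Tolerances, iteration caps, and the geometric rho grid."""

    max_outer_iters: int = 50
    inner_tol: float = 1e-7
    outer_tol: float = 1e-9
    inner_max_iters: int = 1000
    rho_initial: float = 1.0
    rho_multiplier: float = 5.0
    rho_max: float = 1e6
    zero_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if min(self.inner_tol, self.outer_tol) <= 0:
            raise ValueError("tolerances must be positive")
        if self.rho_initial <= 0 or self.rho_max <= 0:
            raise ValueError("rho values must be positive")
        if self.rho_multiplier <= 1:
            raise ValueError("rho_multiplier must exceed 1")
        if self.rho_initial > self.rho_max:
            raise ValueError("rho_initial must not exceed rho_max")

    def rho_grid(self):
        rho = self.rho_initial
        while rho <= self.rho_max * (1 + 1e-12):
            yield rho
            rho *= self.rho_multiplier


@dataclass(frozen=True)
class FitResult:
    """Solution of one penalized solve (coefficients exclude any intercept)."""

    coefficients: np.ndarray
    objective: float  # model loss (-l for Cox) at the solution
    penalty_residual: float  # ||b||_1 - |||b|||_[K] (kit variant if grouped), >= 0
    nnz: int  # active features, or active kits in grouped mode
    converged: bool
    rho_used: float
    intercept: float | None = None

    def full_coefficients(self) -> np.ndarray:
        if self.intercept is None:
            return self.coefficients
        return np.concatenate([self.coefficients, [self.intercept]])


def _soft_threshold(x, thr):
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def _estimate_lipschitz(grad, dim: int, x0: np.ndarray) -> float:
    """Crude local curvature bound via two gradient probes (refined by
    backtracking during iterations)."""
    rng = np.random.default_rng(0)
    d = rng.standard_normal(dim)
    d /= np.linalg.norm(d)
    eps = 1e-3
    g1 = grad(x0 + eps * d)
    g0 = grad(x0)
    L = float(np.linalg.norm(g1 - g0) / eps)
    return max(L, 1e-3)


def _fista(smooth_val, smooth_grad, x0, rho, n_pen, tol, max_iters, L0=None):
    """Monotone FISTA for smooth(x) + rho * ||x[:n_pen]||_1.

    Backtracking line search on the smooth part; the accelerated candidate is
    accepted only when it does not increase the composite objective, so the
    returned objective never exceeds the starting one.
    """

    def composite(x):
        return smooth_val(x) + rho * np.abs(x[:n_pen]).sum()

    def prox(x, step):
        out = x.copy()
        if rho > 0:
            out[:n_pen] = _soft_threshold(x[:n_pen], step * rho)
        return out

    x = np.asarray(x0, dtype=float).copy()
    y = x.copy()
    t = 1.0
    L = L0 if L0 and np.isfinite(L0) else _estimate_lipschitz(smooth_grad, x.size, x)
    fx = composite(x)
    for _ in range(max_iters):
        gy = smooth_grad(y)
        fy = smooth_val(y)
        while True:
            z = prox(y - gy / L, 1.0 / L)
            dz = z - y
            fz = smooth_val(z)
            if fz <= fy + gy @ dz + 0.5 * L * (dz @ dz) + 1e-12 * max(1.0, abs(fy)):
                break
            L *= 2.0
            if L > 1e16:
                z = x
                fz = smooth_val(x)
                break
        cz = fz + rho * np.abs(z[:n_pen]).sum()
        x_prev, fx_prev = x, fx
        if cz <= fx:  # monotone safeguard
            x, fx = z, cz
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = x + (t / t_next) * (z - x) + ((t - 1.0) / t_next) * (x - x_prev)
        t = t_next
        L = max(L * 0.9, 1e-8)
        move = float(np.max(np.abs(x - x_prev))) if x is not x_prev else 0.0
        if move < tol and abs(fx_prev - fx) <= tol * max(1.0, abs(fx)):
            break
    return x, fx, L


def _nnz_of(beta, zero_tol, groups):
    if groups is not None:
        return kit_l0(beta, groups, zero_tol)
    return l0_pseudonorm(beta, zero_tol)


def minimize_dc(bound, K, rho, beta0, config: SolverConfig, groups=None):
    """Local descent on loss + rho*(||.||_1 - |||.|||_[K]) from beta0.

    ``bound`` is a smooth convex loss oracle with ``value``/``gradient``
    callables, ``n_features`` penalized coordinates and optionally one
    trailing unpenalized intercept.  Returns the final iterate; the outer
    objective sequence is checked to be non-increasing.
    """
    beta = np.asarray(beta0, dtype=float).copy()
    if beta.size != bound.dim:
        raise ValueError(f"beta0 has size {beta.size}, expected {bound.dim}")
    n_pen = bound.n_features
    spec = PenaltySpec(min(K, n_pen), max(rho, 1e-300), groups) if rho > 0 else None

    def f_total(b):
        val = bound.value(b)
        if spec is not None:
            val += dc_penalty_value(b[:n_pen], spec)
        return val

    # K covering every coordinate (kit) makes the penalty identically zero
    n_groups = len(groups) if groups is not None else n_pen
    if rho == 0 or K >= n_groups:
        beta, _, _ = _fista(
            bound.value, bound.gradient, beta, 0.0, n_pen,
            config.inner_tol, config.inner_max_iters * 4,
        )
        return beta

    f_curr = f_total(beta)
    L = None
    for outer in range(config.max_outer_iters):
        g = np.zeros_like(beta)
        g[:n_pen] = f2_subgradient(beta[:n_pen], K, rho, groups)

        def smooth_val(b, _g=g):
            return bound.value(b) - _g @ b

        def smooth_grad(b, _g=g):
            return bound.gradient(b) - _g

        beta_new, _, L = _fista(
            smooth_val, smooth_grad, beta, rho, n_pen,
            config.inner_tol, config.inner_max_iters, L0=L,
        )
        f_new = f_total(beta_new)
        slack = 1e-8 * max(1.0, abs(f_curr))
        if f_new > f_curr + slack:
            raise SolverError(
                f"DC outer iteration {outer} increased the objective "
                f"({f_curr:.6g} -> {f_new:.6g})"
            )
        move = float(np.max(np.abs(beta_new - beta)))
        decrease = f_curr - f_new
        beta, f_curr = beta_new, min(f_new, f_curr)
        if move < config.inner_tol or decrease <= config.outer_tol * max(1.0, abs(f_curr)):
            break
    return beta


def fit_smooth(data, family, support=None, x0=None):
    """Unpenalized convex fit (L-BFGS-B), optionally restricted to a support.

    Returns the full coefficient vector (intercept last when the family has
    one); coordinates outside ``support`` are exactly zero.
    """
    family = get_family(family)
    bound = family.bind(data)
    dim = bound.dim
    p = bound.n_features
    if support is None:
        free = np.arange(dim)
    else:
        support = np.asarray(sorted(support), dtype=int)
        free = np.concatenate([support, [p]]).astype(int) if bound.has_intercept else support
    x_full = np.zeros(dim)
    if x0 is not None:
        x_full[:] = np.asarray(x0, dtype=float)
        mask = np.zeros(dim, dtype=bool)
        mask[free] = True
        x_full[~mask] = 0.0

    def fun(z):
        x = x_full.copy()
        x[free] = z
        return bound.value(x), bound.gradient(x)[free]

    res = _scipy_minimize(
        fun, x_full[free], jac=True, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-9},
    )
    out = x_full.copy()
    out[free] = res.x
    return out


def solve_penalized(data, family, K, beta0, config: SolverConfig, groups=None) -> FitResult:
    """Escalate rho on the geometric grid until the solution has at most K
    active features (kits), always restarting from the original beta0.

    After a feasible solve the active support is refit without penalty (the
    exact local optimum of the penalized problem restricted to that support),
    which also yields the reported model loss.  Returns the last solve with
    ``converged=False`` when no grid value produces a feasible support.
    """
    family = get_family(family)
    bound = family.bind(data)
    n_pen = bound.n_features
    beta0 = np.asarray(beta0, dtype=float)
    if beta0.size == n_pen and bound.has_intercept:
        beta0 = np.concatenate([beta0, [0.0]])
    last = None
    for rho in config.rho_grid():
        beta = minimize_dc(bound, K, rho, beta0, config, groups=groups)
        coefs = beta[:n_pen]
        nnz = _nnz_of(coefs, config.zero_tol, groups)
        feasible = nnz <= K
        if feasible:
            support = np.flatnonzero(np.abs(coefs) > config.zero_tol)
            polished = fit_smooth(data, family, support=support, x0=beta)
            pol_coefs = polished[:n_pen]
            if bound.value(polished) <= bound.value(beta):
                beta, coefs = polished, pol_coefs
                nnz = _nnz_of(coefs, config.zero_tol, groups)
        spec = PenaltySpec(min(K, n_pen), 1.0, groups)
        residual = dc_penalty_value(coefs, spec)
        result = FitResult(
            coefficients=coefs.copy(),
            objective=bound.value(beta),
            penalty_residual=residual,
            nnz=nnz,
            converged=feasible,
            rho_used=rho,
            intercept=float(beta[n_pen]) if bound.has_intercept else None,
        )
        logger.debug(
            "solve_penalized K=%d rho=%.3g nnz=%d objective=%.6g feasible=%s",
            K, rho, nnz, result.objective, feasible,
        )
        if feasible:
            return result
        last = result
    return last
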