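"""L0 machinery: largest-k norm, exact DC penalty, kit-grouped variants.

The cardinality constraint ``||beta||_0 <= K`` is equivalent to
``||beta||_1 - |||beta|||_[K] = 0`` where ``|||.|||_[K]`` is the largest-k
norm (sum of the K largest absolute values).  The penalized objective adds
``rho * (||beta||_1 - |||beta|||_[K])`` to the model loss; it decomposes as a
difference of the convex functions ``f1 = loss + rho*||.||_1`` and
``f2 = rho*|||.|||_[K]``.

Kit grouping generalizes the construction to groups of features measured
together: the within-kit L1 magnitudes ``v_g = sum_{j in g} |beta_j|`` play
the role of the per-feature absolute values, so the kit penalty is zero
exactly when at most K kits contain an active feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KitStructure",
    "PenaltySpec",
    "l0_pseudonorm",
    "largest_k_norm",
    "dc_penalty_value",
    "f2_subgradient",
    "kit_l0",
    "kit_magnitudes",
    "kit_penalty_value",
    "group_indices",
]


@dataclass(frozen=True)
class KitStructure:
    """Total single-valued assignment of features to named kits with costs."""

    kit_of: dict
    kit_cost: dict

    def __post_init__(self):
        if not self.kit_cost:
            raise ValueError("kit structure must define at least one kit")
        for kit, cost in self.kit_cost.items():
            if cost < 0:
                raise ValueError(f"kit {kit!r} has negative cost {cost}")
        missing = {k for k in self.kit_of.values() if k not in self.kit_cost}
        if missing:
            raise ValueError(f"kits without a cost: {sorted(missing)}")

    @property
    def kit_names(self) -> tuple:
        return tuple(sorted(self.kit_cost))

    @property
    def n_kits(self) -> int:
        return len(self.kit_cost)

    def kit_for(self, feature: str) -> str:
        return self.kit_of[feature]

    def completed(self, feature_names) -> "KitStructure":
        """Assign any unmapped feature to a singleton zero-cost kit."""
        kit_of = dict(self.kit_of)
        kit_cost = dict(self.kit_cost)
        for name in feature_names:
            if name not in kit_of:
                kit_of[name] = name
                kit_cost.setdefault(name, 0.0)
        return KitStructure(kit_of, kit_cost)

    @staticmethod
    def singletons(feature_names, cost: float = 0.0) -> "KitStructure":
        return KitStructure(
            {f: f for f in feature_names}, {f: cost for f in feature_names}
        )


def group_indices(kits: KitStructure, feature_names) -> list[np.ndarray]:
    """Feature-index lists per kit, ordered by kit name; unmapped features
    become singleton groups.  Empty kits are dropped."""
    full = kits.completed(feature_names)
    by_kit: dict[str, list[int]] = {}
    for j, name in enumerate(feature_names):
        by_kit.setdefault(full.kit_of[name], []).append(j)
    return [np.asarray(by_kit[k], dtype=int) for k in sorted(by_kit)]


@dataclass(frozen=True)
class PenaltySpec:
    """Cardinality bound K, penalty parameter rho, optional kit grouping.

    ``groups`` is the per-kit index partition over the penalized coordinates;
    when absent the cardinality is counted per feature.
    """

    K: int
    rho: float
    groups: tuple | None = None

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be a positive integer")
        if self.rho < 0:
            raise ValueError("rho must be nonnegative")
        if self.groups is not None:
            object.__setattr__(
                self, "groups", tuple(np.asarray(g, dtype=int) for g in self.groups)
            )
            if self.K > len(self.groups):
                raise ValueError("K exceeds the number of kits")

    @classmethod
    def for_features(cls, K, rho, kits=None, feature_names=None):
        groups = None
        if kits is not None:
            if feature_names is None:
                raise ValueError("feature_names required with a kit structure")
            groups = group_indices(kits, feature_names)
        return cls(K, rho, groups)


def l0_pseudonorm(beta, zero_tol: float = 0.0) -> int:
    """Number of components with |beta_j| > zero_tol."""
    if zero_tol < 0:
        raise ValueError("zero_tol must be nonnegative")
    return int(np.count_nonzero(np.abs(np.asarray(beta, dtype=float)) > zero_tol))


def largest_k_norm(beta, k: int) -> float:
    """Sum of the k largest absolute values."""
    a = np.abs(np.asarray(beta, dtype=float).ravel())
    if not 1 <= k <= a.size:
        raise ValueError(f"k={k} out of range [1, {a.size}]")
    if k == a.size:
        return float(a.sum())
    return float(np.partition(a, a.size - k)[a.size - k :].sum())


def kit_magnitudes(beta, groups) -> np.ndarray:
    """Within-kit L1 magnitudes v_g = sum_{j in g} |beta_j|."""
    a = np.abs(np.asarray(beta, dtype=float))
    return np.array([a[g].sum() for g in groups])


def kit_l0(beta, groups, zero_tol: float = 0.0) -> int:
    """Number of kits containing at least one feature above zero_tol."""
    a = np.abs(np.asarray(beta, dtype=float))
    p = a.size
    covered = np.concatenate(groups) if groups else np.array([], dtype=int)
    if len(np.unique(covered)) != p or (covered.size and covered.max() >= p):
        raise ValueError("groups must partition all feature indices")
    return int(sum(1 for g in groups if np.any(a[g] > zero_tol)))


def _bottom_sum(abs_values: np.ndarray, k: int) -> float:
    """Sum of all but the k largest entries; exactly zero when they are zero."""
    if k >= abs_values.size:
        return 0.0
    return float(np.partition(abs_values, abs_values.size - k)[: abs_values.size - k].sum())


def kit_penalty_value(beta, K_kits: int, rho: float, groups) -> float:
    """rho * (sum of kit magnitudes - largest-K_kits sum of kit magnitudes)."""
    v = kit_magnitudes(beta, groups)
    if not 1 <= K_kits <= v.size:
        raise ValueError(f"K_kits={K_kits} out of range [1, {v.size}]")
    return rho * _bottom_sum(v, K_kits)


def dc_penalty_value(beta, spec: PenaltySpec) -> float:
    """The exact DC penalty rho*(||beta||_1 - |||beta|||_[K]); zero iff the
    (kit-)cardinality constraint holds at zero tolerance."""
    beta = np.asarray(beta, dtype=float)
    if spec.groups is not None:
        return kit_penalty_value(beta, spec.K, spec.rho, spec.groups)
    if spec.K >= beta.size:
        return 0.0
    return spec.rho * _bottom_sum(np.abs(beta.ravel()), spec.K)


def _top_k_stable(values: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest values; ties broken toward the lowest index."""
    order = np.argsort(-values, kind="stable")
    return order[:k]


def f2_subgradient(beta, K: int, rho: float, groups=None) -> np.ndarray:
    """One subgradient of f2 = rho * |||.|||_[K] (kit variant when grouped).

    rho*sign(beta_j) on a deterministically chosen set of K top-magnitude
    coordinates (or all coordinates of the K top-magnitude kits); zero
    elsewhere and at exactly-zero coefficients.
    """
    beta = np.asarray(beta, dtype=float)
    g = np.zeros_like(beta)
    if groups is not None:
        v = kit_magnitudes(beta, groups)
        for gi in _top_k_stable(v, min(K, v.size)):
            idx = groups[gi]
            g[idx] = rho * np.sign(beta[idx])
        return g
    top = _top_k_stable(np.abs(beta), min(K, beta.size))
    g[top] = rho * np.sign(beta[top])
    return g
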