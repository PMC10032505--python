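"""Synthetic data with known ground truth, plus dataset/kit file readers.

Survival data follow a sparse linear risk model: features are standard
normal with exchangeable pairwise correlation, event times are exponential
with rate ``baseline * exp(x' beta_true)``, and independent exponential
censoring times are calibrated by bisection so the realized censoring
fraction lands near the requested target.  All randomness flows from the
seed carried by the simulation spec.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dc_penalty import KitStructure
from .likelihoods import RegressionDataset, SurvivalDataset

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "simulate_cox_data",
    "simulate_binary_data",
    "read_dataset",
    "write_dataset",
    "read_kits",
    "write_kits",
    "clinical_kits",
]


@dataclass(frozen=True)
class SimulationSpec:
    n: int = 200
    p: int = 10
    true_support: tuple = (0, 1, 2)
    true_effects: tuple = (1.0, 1.0, 1.0)
    feature_correlation: float = 0.0
    censoring_fraction: float = 0.3
    baseline: float = 1.0
    intercept: float = 0.0  # logistic simulations only
    kit_layout: tuple | None = None  # (n_kits, features_per_kit, max_cost)
    seed: int = 0

    def __post_init__(self):
        if self.n < 10:
            raise ValueError("n must be at least 10")
        if len(self.true_support) != len(self.true_effects):
            raise ValueError("true_support and true_effects lengths differ")
        if len(self.true_support) > self.p:
            raise ValueError("true support larger than p")
        if any(not 0 <= j < self.p for j in self.true_support):
            raise ValueError("true_support indices out of range")
        if not 0.0 <= self.feature_correlation < 1.0:
            raise ValueError("feature_correlation must lie in [0, 1)")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValueError("censoring_fraction must lie in [0, 1)")
        if self.baseline <= 0:
            raise ValueError("baseline rate must be positive")

    @property
    def beta_true(self) -> np.ndarray:
        beta = np.zeros(self.p)
        for j, b in zip(self.true_support, self.true_effects):
            beta[j] = b
        return beta


@dataclass(frozen=True)
class GroundTruth:
    beta_true: np.ndarray
    censoring_realized: float
    censoring_rate: float


def _draw_features(spec: SimulationSpec, rng) -> np.ndarray:
    z = rng.standard_normal((spec.n, spec.p))
    r = spec.feature_correlation
    if r == 0:
        return z
    shared = rng.standard_normal((spec.n, 1))
    return np.sqrt(r) * shared + np.sqrt(1.0 - r) * z


def simulate_cox_data(spec: SimulationSpec):
    """Generate censored survival data; returns (dataset, ground truth)."""
    rng = np.random.default_rng(spec.seed)
    X = _draw_features(spec, rng)
    beta = spec.beta_true
    rate = spec.baseline * np.exp(X @ beta)
    T = rng.exponential(1.0 / rate)
    names = tuple(f"x{j}" for j in range(spec.p))
    if spec.censoring_fraction == 0:
        data = SurvivalDataset(X, T, np.ones(spec.n, dtype=int), names)
        return data, GroundTruth(beta, 0.0, 0.0)

    u = rng.uniform(size=spec.n)  # fixed draws; censor times are -log(u)/c

    def censored_fraction(c):
        return float(np.mean(-np.log(u) / c < T))

    lo, hi = 1e-12, 1.0
    for _ in range(200):
        if censored_fraction(hi) >= spec.censoring_fraction:
            break
        hi *= 4.0
        if hi > 1e14:
            raise RuntimeError("censoring calibration failed: cannot bracket the rate")
    else:
        raise RuntimeError("censoring calibration failed: cannot bracket the rate")
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if censored_fraction(mid) < spec.censoring_fraction:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1.0 + 1e-10:
            break
    c = hi
    C = -np.log(u) / c
    events = (T <= C).astype(int)
    times = np.minimum(T, C)
    if events.sum() == 0:
        raise RuntimeError("censoring calibration produced no events")
    realized = 1.0 - events.mean()
    data = SurvivalDataset(X, times, events, names)
    return data, GroundTruth(beta, realized, c)


def simulate_binary_data(spec: SimulationSpec, max_retries: int = 10):
    """Generate a binary-outcome dataset from a logistic model."""
    rng = np.random.default_rng(spec.seed)
    names = tuple(f"x{j}" for j in range(spec.p))
    for attempt in range(max_retries):
        X = _draw_features(spec, rng)
        z = spec.intercept + X @ spec.beta_true
        y = (rng.uniform(size=spec.n) < 1.0 / (1.0 + np.exp(-z))).astype(int)
        if len(np.unique(y)) == 2:
            return RegressionDataset(X, y, names), GroundTruth(spec.beta_true, 0.0, 0.0)
        warnings.warn(f"single-class draw on attempt {attempt + 1}; redrawing")
    raise RuntimeError(f"single-class outcome after {max_retries} draws")


def _numeric_or_raise(df: pd.DataFrame) -> np.ndarray:
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"non-numeric feature value at row {row}, column {col!r}")
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna())[0])
            raise ValueError(f"missing value at row {row}, column {col!r}")
        df[col] = converted
    return df.to_numpy(dtype=float)


def read_dataset(path, time_col: str = "time", event_col: str = "event",
                 outcome_col: str = "outcome", sep: str = ","):
    """Read a delimited dataset.

    A file with ``time`` and ``event`` columns yields a SurvivalDataset; one
    with an ``outcome`` column yields a RegressionDataset.  All remaining
    columns are numeric features.
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if time_col in df.columns and event_col in df.columns:
        times = pd.to_numeric(df[time_col], errors="raise").to_numpy(dtype=float)
        events = df[event_col].to_numpy()
        feats = df.drop(columns=[time_col, event_col])
        X = _numeric_or_raise(feats)
        return SurvivalDataset(X, times, events, tuple(feats.columns))
    if outcome_col in df.columns:
        y = pd.to_numeric(df[outcome_col], errors="raise").to_numpy(dtype=float)
        feats = df.drop(columns=[outcome_col])
        X = _numeric_or_raise(feats)
        return RegressionDataset(X, y, tuple(feats.columns))
    raise ValueError(
        f"no ({time_col!r}, {event_col!r}) or {outcome_col!r} columns in {path}"
    )


def write_dataset(data, path, sep: str = ","):
    """Write a dataset as delimited text; read_dataset inverts it losslessly
    up to 17-significant-digit float formatting."""
    cols = {}
    if isinstance(data, SurvivalDataset):
        cols["time"] = data.times
        cols["event"] = data.events
    else:
        cols["outcome"] = data.outcome
    for j, name in enumerate(data.feature_names):
        cols[name] = data.features[:, j]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_kits(path, sep: str = ",") -> KitStructure:
    """Read a kit-definition table with columns feature, kit, cost."""
    # keep_default_na: feature codes like "NA" (sodium) are real names
    df = pd.read_csv(path, sep=sep, keep_default_na=False)
    required = {"feature", "kit", "cost"}
    if not required.issubset(df.columns):
        raise ValueError(f"kit file must have columns {sorted(required)}")
    df = df.drop_duplicates()
    kit_of: dict[str, str] = {}
    kit_cost: dict[str, float] = {}
    for _, row in df.iterrows():
        feature, kit, cost = str(row["feature"]), str(row["kit"]), float(row["cost"])
        if feature in kit_of and kit_of[feature] != kit:
            raise ValueError(f"feature {feature!r} mapped to multiple kits")
        if kit in kit_cost and kit_cost[kit] != cost:
            raise ValueError(f"conflicting costs for kit {kit!r}")
        kit_of[feature] = kit
        kit_cost[kit] = cost
    if not kit_cost:
        return KitStructure({}, {"__empty__": 0.0})
    return KitStructure(kit_of, kit_cost)


def write_kits(kits: KitStructure, path, sep: str = ","):
    rows = [
        {"feature": f, "kit": k, "cost": kits.kit_cost[k]}
        for f, k in sorted(kits.kit_of.items())
    ]
    pd.DataFrame(rows, columns=["feature", "kit", "cost"]).to_csv(path, sep=sep, index=False)


def clinical_kits() -> KitStructure:
    """The packaged clinical laboratory kit table (PSA kit = 100 reference)."""
    ref = importlib.resources.files("cardreg").joinpath("data/clinical_kits.csv")
    with importlib.resources.as_file(ref) as path:
        return read_kits(path)


def random_kits(feature_names, n_kits: int, max_cost: float = 100.0, seed: int = 0) -> KitStructure:
    """Random kit assignment for simulation studies."""
    rng = np.random.default_rng(seed)
    names = list(feature_names)
    if not 1 <= n_kits <= len(names):
        raise ValueError("n_kits out of range")
    kit_names = [f"kit{i}" for i in range(n_kits)]
    assignment = rng.integers(0, n_kits, size=len(names))
    # guarantee every kit is nonempty
    for i in range(n_kits):
        if not np.any(assignment == i):
            assignment[rng.integers(0, len(names))] = i
    kit_of = {names[j]: kit_names[assignment[j]] for j in range(len(names))}
    kit_cost = {k: float(c) for k, c in zip(kit_names, rng.uniform(0, max_cost, n_kits))}
    return KitStructure(kit_of, kit_cost)
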