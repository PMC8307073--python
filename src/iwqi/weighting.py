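"""Subjective (entropy), objective (stochastic-simulation) and integrated
parameter weights.

The subjective weights come from Shannon entropy of the measured matrix; the
objective weights from a Monte-Carlo ensemble of weight vectors drawn around
the per-parameter mean/SD of a literature weight database; the two are fused
through a preference coefficient into a single convex combination.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from typing import Literal

import numpy as np
import pandas as pd

from .core import SampleTable

__all__ = [
    "WeightVector",
    "LiteratureWeightDB",
    "LiteratureStats",
    "SSAConfig",
    "SimulationSummary",
    "IntegrationResult",
    "DegenerateEntropyError",
    "entropy_weights",
    "literature_stats",
    "simulate_objective_weights",
    "combined_product_weights",
    "preference_coefficient",
    "integrated_weights",
    "weight_pipeline",
]

_SUM_TOL = 1e-9

Role = Literal["subjective", "objective", "product", "integrated"]


class DegenerateEntropyError(ValueError):
    """Every column carries zero information (all entropies equal 1)."""


@dataclass(frozen=True)
class WeightVector:
    """Normalized nonnegative per-parameter weights with a role tag."""

    parameters: tuple[str, ...]
    weights: np.ndarray
    role: Role

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (len(self.parameters),):
            raise ValueError("weights length must match parameters")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.parameters), name=self.role)

    def __getitem__(self, parameter: str) -> float:
        return float(self.weights[self.parameters.index(parameter)])


@dataclass
class LiteratureWeightDB:
    """Studies x parameters weight matrix with missing cells (NaN)."""

    table: pd.DataFrame  # index: study id, columns: parameters
    provenance: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.table.to_numpy(dtype=float)
        if (vals[~np.isnan(vals)] < 0).any():
            raise ValueError("literature weights must be nonnegative")

    @property
    def n_studies(self) -> int:
        return len(self.table)

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(self.table.columns)

    def subset(self, parameters) -> "LiteratureWeightDB":
        return LiteratureWeightDB(self.table[list(parameters)], self.provenance)

    @classmethod
    def packaged(cls) -> "LiteratureWeightDB":
        """The literature database shipped with the package (22 studies)."""
        ref = resources.files("iwqi.data") / "literature_weights.csv"
        with resources.as_file(ref) as path:
            frame = pd.read_csv(path, index_col=0)
        return cls(frame)


@dataclass(frozen=True)
class LiteratureStats:
    """Per-parameter mean/SD over the present (non-missing) cells."""

    parameters: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    n_studies: np.ndarray
    degenerate: tuple[str, ...]  # parameters with < 2 contributing studies

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.mean, "sd": self.sd, "n_studies": self.n_studies},
            index=list(self.parameters),
        )

    def subset(self, parameters) -> "LiteratureStats":
        idx = [self.parameters.index(p) for p in parameters]
        return LiteratureStats(
            parameters=tuple(parameters),
            mean=self.mean[idx],
            sd=self.sd[idx],
            n_studies=self.n_studies[idx],
            degenerate=tuple(p for p in self.degenerate if p in parameters),
        )


@dataclass(frozen=True)
class SSAConfig:
    n_simulations: int = 2000
    seed: int = 0
    negative_policy: Literal["clip", "resample"] = "clip"
    normalize_each_draw: bool = True
    max_resample_rounds: int = 100

    def __post_init__(self) -> None:
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")


@dataclass(frozen=True)
class SimulationSummary:
    config: SSAConfig
    ensemble_mean: np.ndarray  # before final renormalization
    ensemble_sd: np.ndarray
    n_clipped: int


@dataclass(frozen=True)
class IntegrationResult:
    product: WeightVector
    g_raw: float
    g: float
    integrated: WeightVector


def entropy_weights(
    table: SampleTable | pd.DataFrame | np.ndarray,
    parameters: tuple[str, ...] | None = None,
    equal_weight_fallback: bool = False,
) -> tuple[WeightVector, np.ndarray]:
    """Entropy (subjective) weights of a measurement matrix.

    P_ij = r_ij / sum_i r_ij; e_j = -(1/ln m) * sum_i P_ij ln P_ij with
    0*ln 0 = 0; W_sj = (1 - e_j) / sum_j (1 - e_j).

    Returns the weight vector and the per-parameter entropy e_j.
    """
    if isinstance(table, SampleTable):
        r = table.values
        parameters = tuple(table.catalog.parameters)
    elif isinstance(table, pd.DataFrame):
        r = table.to_numpy(dtype=float)
        parameters = parameters or tuple(table.columns)
    else:
        r = np.asarray(table, dtype=float)
        parameters = parameters or tuple(f"p{j}" for j in range(r.shape[1]))

    m, n = r.shape
    if m < 2:
        raise ValueError("entropy weights need at least 2 samples")
    if (r < 0).any():
        raise ValueError("entropy weights need nonnegative values")
    col_sums = r.sum(axis=0)
    zero_cols = np.flatnonzero(col_sums == 0)
    if zero_cols.size:
        raise ValueError(
            f"column(s) sum to zero: {[parameters[j] for j in zero_cols]}"
        )

    p = r / col_sums
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    e = -plogp.sum(axis=0) / np.log(m)
    d = 1.0 - e
    # fp noise can push e marginally past 1 for constant columns
    d = np.where(np.abs(d) < 1e-12, 0.0, d)
    total = d.sum()
    if total <= 0:
        if equal_weight_fallback:
            w = np.full(n, 1.0 / n)
            return WeightVector(parameters, w, "subjective"), e
        raise DegenerateEntropyError(
            "all columns are constant: entropy weights are undefined "
            "(pass equal_weight_fallback=True to use uniform weights)"
        )
    w = d / total
    return WeightVector(parameters, w, "subjective"), e


def literature_stats(db: LiteratureWeightDB) -> LiteratureStats:
    """Per-parameter mean and SD over non-missing literature weights.

    Parameters with a single contributing study get sd = 0 and are flagged
    as degenerate.
    """
    if db.n_studies == 0:
        raise ValueError("literature weight database is empty")
    frame = db.table
    counts = frame.notna().sum(axis=0).to_numpy()
    if (counts == 0).any():
        empty = [p for p, c in zip(frame.columns, counts) if c == 0]
        raise ValueError(f"no literature entries for parameter(s): {empty}")
    mean = frame.mean(axis=0, skipna=True).to_numpy()
    sd = frame.std(axis=0, ddof=1, skipna=True).to_numpy()
    degenerate = tuple(p for p, c in zip(frame.columns, counts) if c < 2)
    sd = np.where(counts < 2, 0.0, sd)
    return LiteratureStats(
        parameters=tuple(frame.columns),
        mean=mean,
        sd=sd,
        n_studies=counts,
        degenerate=degenerate,
    )


def _param_rng(seed: int, param_index: int) -> np.random.Generator:
    # parameter-major streams: draws for one parameter are unaffected by
    # adding/removing other parameters
    return np.random.default_rng([seed, param_index])


def simulate_objective_weights(
    stats: LiteratureStats, config: SSAConfig = SSAConfig()
) -> tuple[WeightVector, SimulationSummary]:
    """Objective weights from a Monte-Carlo ensemble of weight vectors.

    Each of K simulated vectors draws component j from Normal(mean_j, sd_j)
    (the inverse-normal-CDF of a uniform draw). Negative draws are clipped to
    zero or resampled per config; each draw is normalized to sum 1; the
    objective weight vector is the renormalized ensemble mean.
    """
    mean = np.asarray(stats.mean, dtype=float)
    sd = np.asarray(stats.sd, dtype=float)
    n = mean.size
    k = config.n_simulations

    if (sd == 0).all():
        # degenerate variance: every draw is the mean vector, so the
        # ensemble mean is exactly the normalized means for any seed
        w = mean / mean.sum()
        vec = WeightVector(stats.parameters, w, "objective")
        return vec, SimulationSummary(config, w.copy(), np.zeros(n), 0)

    draws = np.empty((k, n))
    n_clipped = 0
    for j in range(n):
        rng = _param_rng(config.seed, j)
        col = rng.normal(mean[j], sd[j], size=k)
        if config.negative_policy == "clip":
            n_clipped += int((col < 0).sum())
            col = np.clip(col, 0.0, None)
        elif config.negative_policy == "resample":
            for _ in range(config.max_resample_rounds):
                neg = col < 0
                if not neg.any():
                    break
                col[neg] = rng.normal(mean[j], sd[j], size=int(neg.sum()))
            else:
                raise RuntimeError(
                    f"could not draw nonnegative weights for {stats.parameters[j]!r}"
                )
            col = np.clip(col, 0.0, None)  # guard fp zeros
        else:
            raise ValueError(f"unknown negative policy {config.negative_policy!r}")
        draws[:, j] = col

    row_sums = draws.sum(axis=1)
    if (row_sums == 0).any():
        raise RuntimeError("simulation produced an all-zero weight vector")
    if config.normalize_each_draw:
        normalized = draws / row_sums[:, None]
    else:
        normalized = draws
    ens_mean = normalized.mean(axis=0)
    ens_sd = normalized.std(axis=0, ddof=1) if k > 1 else np.zeros(n)
    w = ens_mean / ens_mean.sum()
    vec = WeightVector(stats.parameters, w, "objective")
    return vec, SimulationSummary(config, ens_mean, ens_sd, n_clipped)


def combined_product_weights(ws: WeightVector, wo: WeightVector) -> WeightVector:
    """Normalized elementwise product of subjective and objective weights."""
    if ws.parameters != wo.parameters:
        raise ValueError("weight vectors are over different parameters")
    prod = ws.weights * wo.weights
    total = prod.sum()
    if total == 0:
        raise ValueError("subjective and objective weights have disjoint support")
    return WeightVector(ws.parameters, prod / total, "product")


def preference_coefficient(
    w: WeightVector, ws: WeightVector, wo: WeightVector
) -> tuple[float, float]:
    """Preference coefficient: sum of squared deviations of the product
    weights from both parents, clamped into [0, 1].

    Returns (raw, clamped); the raw value can exceed 1, the clamped value is
    the one used downstream.
    """
    g_raw = float(((w.weights - ws.weights) ** 2 + (w.weights - wo.weights) ** 2).sum())
    return g_raw, min(max(g_raw, 0.0), 1.0)


def integrated_weights(g: float, ws: WeightVector, wo: WeightVector) -> WeightVector:
    """Convex combination W = G*W_s + (1-G)*W_o."""
    if not 0.0 <= g <= 1.0:
        raise ValueError("G must lie in [0, 1]")
    if ws.parameters != wo.parameters:
        raise ValueError("weight vectors are over different parameters")
    w = g * ws.weights + (1.0 - g) * wo.weights
    return WeightVector(ws.parameters, w / w.sum(), "integrated")


def integrate(ws: WeightVector, wo: WeightVector) -> IntegrationResult:
    """Full integration step: product weights, G, and the integrated vector."""
    w = combined_product_weights(ws, wo)
    g_raw, g = preference_coefficient(w, ws, wo)
    return IntegrationResult(w, g_raw, g, integrated_weights(g, ws, wo))


@dataclass(frozen=True)
class WeightReport:
    """All weight vectors and diagnostics for one table."""

    parameters: tuple[str, ...]
    entropy: np.ndarray
    subjective: WeightVector
    stats: LiteratureStats
    objective: WeightVector
    integration: IntegrationResult

    @property
    def integrated(self) -> WeightVector:
        return self.integration.integrated

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "e": self.entropy,
                "W_s": self.subjective.weights,
                "lit_mean": self.stats.mean,
                "lit_sd": self.stats.sd,
                "W_o": self.objective.weights,
                "w": self.integration.product.weights,
                "W": self.integrated.weights,
            },
            index=list(self.parameters),
        ).rename_axis("parameter")


def weight_pipeline(
    table: SampleTable,
    db: LiteratureWeightDB,
    config: SSAConfig = SSAConfig(),
) -> WeightReport:
    """Entropy -> SSA -> integration over the table's parameter set."""
    params = tuple(table.catalog.parameters)
    ws, e = entropy_weights(table)
    stats = literature_stats(db.subset(params))
    wo, _ = simulate_objective_weights(stats, config)
    integration = integrate(ws, wo)
    return WeightReport(params, e, ws, stats, wo, integration)
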