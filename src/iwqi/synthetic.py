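"""Synthetic sample tables with prescribed marginal structure.

The published assessment reports only per-parameter min/max/mean/SD for its
two 28-well campaigns; raw samples are unavailable. This module generates
stand-in tables whose marginals match those summaries (truncated-normal
draws), plus a noise-controlled cation-exchange fixture for the ion-ratio
diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .core import DEFAULT_CATALOG, ParameterCatalog, SampleTable, validate_sample_table

__all__ = [
    "MarginalSpec",
    "GeneratorConfig",
    "table3_marginals",
    "generate",
    "make_exchange_fixture",
]


@dataclass(frozen=True)
class MarginalSpec:
    """Per-parameter (min, max, mean, sd) marginals for one season."""

    season: str
    table: pd.DataFrame  # index: parameter; columns: min, max, mean, sd

    def __post_init__(self) -> None:
        t = self.table
        bad = t.index[(t["mean"] < t["min"]) | (t["mean"] > t["max"])].tolist()
        if bad:
            raise ValueError(f"mean outside [min, max] for: {bad}")
        if (t["sd"] < 0).any():
            raise ValueError("sd must be nonnegative")

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    def row(self, parameter: str) -> tuple[float, float, float, float]:
        r = self.table.loc[parameter]
        return float(r["min"]), float(r["max"]), float(r["mean"]), float(r["sd"])


#: default plausibility coupling for demos (synthetic, not fitted)
_PRESET_COUPLED = ("TDS", "TH", "Ca", "Mg", "HCO3")


@dataclass(frozen=True)
class GeneratorConfig:
    n_samples: int = 28
    seed: int = 0
    dependence: str = "independent"  # or "rank-correlated"
    correlation: np.ndarray | None = None
    consistency: str = "free"  # or "tied" (TH/TDS recomputed from ions)
    catalog: ParameterCatalog = field(default=DEFAULT_CATALOG)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.dependence not in ("independent", "rank-correlated"):
            raise ValueError(f"unknown dependence mode {self.dependence!r}")
        if self.consistency not in ("free", "tied"):
            raise ValueError(f"unknown consistency mode {self.consistency!r}")
        if self.dependence == "rank-correlated" and self.correlation is not None:
            c = np.asarray(self.correlation, float)
            if c.shape[0] != c.shape[1] or not np.allclose(c, c.T):
                raise ValueError("correlation matrix must be square and symmetric")
            if not np.allclose(np.diag(c), 1.0):
                raise ValueError("correlation matrix needs a unit diagonal")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ValueError("correlation matrix must be positive semidefinite")


def table3_marginals() -> tuple[MarginalSpec, MarginalSpec]:
    """The packaged dry- and wet-season marginal summaries (verbatim)."""
    ref = resources.files("iwqi.data") / "table3_marginals.csv"
    with resources.as_file(ref) as path:
        frame = pd.read_csv(path)
    out = []
    for season in ("dry", "wet"):
        sub = (
            frame[frame["season"] == season]
            .set_index("parameter")[["min", "max", "mean", "sd"]]
        )
        sub = sub.loc[list(DEFAULT_CATALOG.parameters)]
        out.append(MarginalSpec(season, sub))
    return out[0], out[1]


def _feasibility_warned(spec: MarginalSpec) -> None:
    t = spec.table
    with np.errstate(divide="ignore", invalid="ignore"):
        z_hi = (t["max"] - t["mean"]) / t["sd"]
        z_lo = (t["mean"] - t["min"]) / t["sd"]
    suspect = t.index[(z_hi > 10) | (z_lo > 10)].tolist()
    if suspect:
        warnings.warn(
            "marginal summary looks moment-infeasible (printed extreme is "
            f">10 SD from the mean) for: {suspect}",
            stacklevel=3,
        )


def truncated_moments(lo: float, hi: float, mean: float, sd: float) -> tuple[float, float]:
    """Mean/SD of Normal(mean, sd) truncated to [lo, hi] (generation target)."""
    if sd == 0:
        return mean, 0.0
    a, b = (lo - mean) / sd, (hi - mean) / sd
    dist = truncnorm(a, b, loc=mean, scale=sd)
    return float(dist.mean()), float(dist.std())


def _correlation_for(config: GeneratorConfig, params: tuple[str, ...]) -> np.ndarray:
    if config.correlation is not None:
        c = np.asarray(config.correlation, float)
        if c.shape != (len(params), len(params)):
            raise ValueError("correlation matrix size must match parameter count")
        return c
    # plausibility preset: positive coupling among the mineralization block
    c = np.eye(len(params))
    idx = [i for i, p in enumerate(params) if p in _PRESET_COUPLED]
    for i in idx:
        for j in idx:
            if i != j:
                c[i, j] = 0.7
    return c


def generate(spec: MarginalSpec, config: GeneratorConfig = GeneratorConfig()) -> SampleTable:
    """Draw a sample table whose marginals follow the spec.

    Each parameter is Normal(mean, sd) truncated to [min, max] (constant when
    sd = 0). ``rank-correlated`` mode couples columns through a latent
    jointly-normal driver mapped through each marginal's quantile function, so
    marginals are preserved. ``tied`` consistency recomputes TH as
    2.497*Ca + 4.118*Mg and TDS as the ion-mass sum minus half the
    bicarbonate, both clipped back into the spec's range — crude mass-balance
    approximations, flagged in the column provenance.
    """
    _feasibility_warned(spec)
    params = [p for p in config.catalog.parameters if p in spec.parameters]
    if set(spec.parameters) - set(params):
        raise ValueError("spec contains parameters outside the catalog")
    n = config.n_samples
    rng = np.random.default_rng(config.seed)

    if config.dependence == "rank-correlated":
        corr = _correlation_for(config, tuple(params))
        latent = rng.multivariate_normal(
            np.zeros(len(params)), corr, size=n, method="cholesky"
        )
        from scipy.stats import norm

        u = norm.cdf(latent)
    else:
        u = rng.uniform(size=(n, len(params)))

    cols = {}
    for j, p in enumerate(params):
        lo, hi, mean, sd = spec.row(p)
        if sd == 0:
            cols[p] = np.full(n, mean)
            continue
        a, b = (lo - mean) / sd, (hi - mean) / sd
        cols[p] = truncnorm.ppf(u[:, j], a, b, loc=mean, scale=sd)
    data = pd.DataFrame(cols, index=[f"S{i + 1:02d}" for i in range(n)])

    if config.consistency == "tied":
        th = 2.497 * data["Ca"] + 4.118 * data["Mg"]
        lo, hi, *_ = spec.row("TH")
        data["TH"] = th.clip(lo, hi)
        ion_cols = [p for p in params if p not in ("pH", "TDS", "TH")]
        mass = data[ion_cols].copy()
        for nspec, factor in (("NO3_N", 62.0 / 14.0), ("NO2_N", 46.0 / 14.0)):
            if nspec in mass:
                mass[nspec] = mass[nspec] * factor
        tds = mass.sum(axis=1) - 0.5 * data["HCO3"]
        lo, hi, *_ = spec.row("TDS")
        data["TDS"] = tds.clip(lo, hi)

    table = SampleTable(
        data=data,
        seasons=pd.Series(spec.season, index=data.index, name="season"),
        catalog=config.catalog.subset(params),
    )
    return validate_sample_table(table)


def make_exchange_fixture(n: int = 100, seed: int = 0, noise: float = 0.02) -> SampleTable:
    """Waters on a cation-exchange trajectory.

    Constructed in meq/L so that (Ca+Mg) - (HCO3+SO4) = -(Na - Cl) + noise:
    the exchange-panel slope is exactly -1 at noise 0 and the waters stay
    charge-balanced (|CBE| < 5%) and positive.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    d = np.linspace(-1.2, 1.2, n)  # exchange extent, meq/L
    eps = rng.normal(0.0, noise, size=n)

    hco3 = 4.0 + 0.3 * rng.uniform(-1, 1, size=n)
    so4 = 1.0 + 0.1 * rng.uniform(-1, 1, size=n)
    cl = 2.0 + 0.2 * rng.uniform(-1, 1, size=n)
    na = cl + d
    camg = hco3 + so4 - d + eps
    ca, mg = 0.7 * camg, 0.3 * camg

    data = pd.DataFrame(
        {
            "pH": np.full(n, 7.5),
            "Ca": ca * 20.04,
            "Na": na * 22.99,
            "Mg": mg * 12.15,
            "K": np.zeros(n),
            "Fe": np.zeros(n),
            "HCO3": hco3 * 61.02,
            "SO4": so4 * 48.03,
            "Cl": cl * 35.45,
            "NO3_N": np.zeros(n),
            "F": np.zeros(n),
            "NO2_N": np.zeros(n),
        },
        index=[f"X{i + 1:03d}" for i in range(n)],
    )
    data["TH"] = 50.045 * (ca + mg)  # mg/L as CaCO3
    ion_mass = data[["Ca", "Na", "Mg", "HCO3", "SO4", "Cl"]].sum(axis=1)
    data["TDS"] = ion_mass - 0.5 * data["HCO3"]
    data = data[list(DEFAULT_CATALOG.parameters)]
    table = SampleTable(
        data=data,
        seasons=pd.Series("unlabeled", index=data.index, name="season"),
    )
    return validate_sample_table(table)
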