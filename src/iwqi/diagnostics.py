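"""Hydrochemical diagnostics: meq conversion, descriptive statistics with
exceedance rates, Piper trilinear coordinates and facies naming, Gibbs
ratios and ion-ratio panels with fitted slopes.

All ratio/trilinear computations are on a meq/L basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DEFAULT_CATALOG, ParameterCatalog, SampleTable, StandardsTable

__all__ = [
    "MeqTable",
    "PiperCoordinates",
    "WaterType",
    "RatioDiagnostics",
    "to_meq",
    "descriptive_stats",
    "piper_coordinates",
    "classify_water_type",
    "gibbs_ratios",
    "ion_ratio_panel",
]


@dataclass
class MeqTable:
    """Per-sample ionic concentrations in meq/L plus group sums."""

    data: pd.DataFrame  # samples x ionic parameters, meq/L
    cation_sum: pd.Series
    anion_sum: pd.Series
    catalog: ParameterCatalog = DEFAULT_CATALOG


@dataclass
class PiperCoordinates:
    """Trilinear fractions (percent of group meq) and diamond coordinates.

    Cation triangle: Ca, Mg, Na+K. Anion triangle: HCO3(+CO3), SO4, Cl.
    The diamond abscissa/ordinate are the standard projections
    (Na+K)% + ... following the (SO4+Cl)% vs (Ca+Mg)% construction.
    """

    cation_pct: pd.DataFrame  # columns Ca, Mg, NaK
    anion_pct: pd.DataFrame  # columns HCO3, SO4, Cl
    diamond: pd.DataFrame  # columns NaK_pct (=100-Ca-Mg), SO4Cl_pct
    flagged: tuple[str, ...] = ()


@dataclass(frozen=True)
class WaterType:
    """Dominance-ordered facies label such as 'HCO3-Ca' or 'HCO3-Ca-Mg'."""

    anions: tuple[str, ...]
    cations: tuple[str, ...]

    @property
    def label(self) -> str:
        return "-".join(self.anions + self.cations)


@dataclass
class RatioDiagnostics:
    """Gibbs ratios, the six ion-ratio scatter pairs and fitted slope."""

    gibbs: pd.DataFrame | None = None  # na_ratio, cl_ratio, TDS, zone
    panels: dict[str, pd.DataFrame] | None = None
    exchange_slope: float | None = None
    exchange_intercept: float | None = None
    above_below: dict[str, tuple[float, float]] | None = None


def to_meq(table: SampleTable, catalog: ParameterCatalog | None = None) -> MeqTable:
    """Convert ionic parameters to meq/L (N species to ion mass first)."""
    catalog = catalog or table.catalog
    cols = {}
    for p in catalog.ionic_parameters:
        cols[p] = catalog.ion_spec(p).to_meq(table.data[p].astype(float))
    meq = pd.DataFrame(cols, index=table.data.index)
    cation_sum = meq[[p for p in catalog.cations if p in meq]].sum(axis=1)
    anion_sum = meq[[p for p in catalog.anions if p in meq]].sum(axis=1)
    return MeqTable(meq, cation_sum, anion_sum, catalog)


def descriptive_stats(
    table: SampleTable, standards: StandardsTable | None = None
) -> pd.DataFrame:
    """Per-parameter, per-season min/max/mean/SD and %SES.

    SD is the sample standard deviation (ddof=1); a single-sample group gets
    SD 0 with ``sd_flag``. %SES is the percentage of samples strictly
    exceeding the configured limit, 2 decimals; parameters without a limit
    get NaN.
    """
    frames = []
    seasons = table.seasons.unique().tolist()
    for season in seasons:
        sub = table.season_subset(season)
        if sub.n_samples == 0:
            continue
        data = sub.data
        one = data.shape[0] == 1
        for p in table.catalog.parameters:
            col = data[p].astype(float)
            limit = None
            if standards is not None and p in standards:
                limit = standards[p].limit
            ses = (
                round(100.0 * float((col > limit).sum()) / len(col), 2)
                if limit is not None
                else np.nan
            )
            frames.append(
                {
                    "parameter": p,
                    "season": season,
                    "min": col.min(),
                    "max": col.max(),
                    "mean": col.mean(),
                    "sd": 0.0 if one else col.std(ddof=1),
                    "sd_flag": "single-sample" if one else "",
                    "pct_ses": ses,
                    "n": len(col),
                }
            )
    return pd.DataFrame(frames).set_index(["parameter", "season"])


_CAT_GROUPS = {"Ca": ["Ca"], "Mg": ["Mg"], "NaK": ["Na", "K"]}
_AN_GROUPS = {"HCO3": ["HCO3"], "SO4": ["SO4"], "Cl": ["Cl"]}


def _triangle(
    meq: pd.DataFrame, groups: dict[str, list[str]]
) -> tuple[pd.DataFrame, pd.Series]:
    parts = pd.DataFrame(
        {
            name: meq[[m for m in members if m in meq]].sum(axis=1)
            for name, members in groups.items()
        }
    )
    total = parts.sum(axis=1)
    return parts.div(total, axis=0) * 100.0, total


def piper_coordinates(meq: MeqTable) -> PiperCoordinates:
    """Trilinear fractions of the three major cations/anions per sample."""
    cation_pct, cat_total = _triangle(meq.data, _CAT_GROUPS)
    anion_pct, an_total = _triangle(meq.data, _AN_GROUPS)
    flagged = tuple(
        str(s) for s in meq.data.index[(cat_total == 0) | (an_total == 0)]
    )
    diamond = pd.DataFrame(
        {
            "NaK_pct": cation_pct["NaK"],
            "SO4Cl_pct": anion_pct["SO4"] + anion_pct["Cl"],
        }
    )
    return PiperCoordinates(cation_pct, anion_pct, diamond, flagged)


def classify_water_type(
    coords: PiperCoordinates, sample_id, threshold: float = 25.0
) -> WaterType:
    """Facies label from dominant ions (>= threshold meq%), anions first,
    each group in decreasing abundance."""

    def dominant(row: pd.Series, names: dict[str, str]) -> tuple[str, ...]:
        pairs = [(names.get(k, k), v) for k, v in row.items() if v >= threshold]
        pairs.sort(key=lambda kv: -kv[1])
        return tuple(k for k, _ in pairs)

    an = dominant(coords.anion_pct.loc[sample_id], {})
    cat = dominant(coords.cation_pct.loc[sample_id], {"NaK": "Na+K"})
    return WaterType(anions=an, cations=cat)


def water_types(coords: PiperCoordinates, threshold: float = 25.0) -> pd.Series:
    return pd.Series(
        {
            sid: classify_water_type(coords, sid, threshold).label
            for sid in coords.cation_pct.index
        },
        name="water_type",
    )


# Heuristic rectangles in (ratio, TDS mg/L) space; the published construction
# reads zones off a plotted envelope, so these are coarse by design.
_GIBBS_TDS_LOW = 100.0
_GIBBS_TDS_HIGH = 1000.0


def _gibbs_zone(ratio: float, tds: float) -> str:
    if tds <= _GIBBS_TDS_LOW and ratio >= 0.5:
        return "precipitation"
    if tds >= _GIBBS_TDS_HIGH and ratio >= 0.5:
        return "evaporation"
    return "rock-weathering"


def gibbs_ratios(table: SampleTable, meq: MeqTable) -> RatioDiagnostics:
    """Na/(Na+Ca) and Cl/(Cl+HCO3) (meq basis) with TDS and a coarse
    provenance-zone heuristic per sample."""
    na, ca = meq.data["Na"], meq.data["Ca"]
    cl, hco3 = meq.data["Cl"], meq.data["HCO3"]
    na_den = na + ca
    cl_den = cl + hco3
    flagged = tuple(
        str(s) for s in meq.data.index[(na_den == 0) | (cl_den == 0)]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        na_ratio = na / na_den
        cl_ratio = cl / cl_den
    tds = table.data["TDS"].astype(float)
    zone = [
        _gibbs_zone(r, t) if np.isfinite(r) else "undefined"
        for r, t in zip(cl_ratio, tds)
    ]
    frame = pd.DataFrame(
        {"na_ratio": na_ratio, "cl_ratio": cl_ratio, "TDS": tds, "zone": zone}
    )
    return RatioDiagnostics(gibbs=frame)


_PANELS = {
    "Na_vs_Cl": (lambda m: m["Cl"], lambda m: m["Na"]),
    "CaMg_vs_HCO3SO4": (
        lambda m: m["HCO3"] + m["SO4"],
        lambda m: m["Ca"] + m["Mg"],
    ),
    "Ca_vs_HCO3": (lambda m: m["HCO3"], lambda m: m["Ca"]),
    "Ca_vs_SO4": (lambda m: m["SO4"], lambda m: m["Ca"]),
    "Ca_vs_Mg": (lambda m: m["Mg"], lambda m: m["Ca"]),
    "exchange": (
        lambda m: m["Na"] - m["Cl"],
        lambda m: m["Ca"] + m["Mg"] - m["HCO3"] - m["SO4"],
    ),
}


def ion_ratio_panel(meq: MeqTable) -> RatioDiagnostics:
    """The six source-attribution scatter pairs plus the ordinary
    least-squares slope of the cation-exchange panel."""
    if len(meq.data) < 2:
        raise ValueError("slope fitting needs at least 2 samples")
    panels: dict[str, pd.DataFrame] = {}
    above_below: dict[str, tuple[float, float]] = {}
    for name, (fx, fy) in _PANELS.items():
        x, y = fx(meq.data), fy(meq.data)
        panels[name] = pd.DataFrame({"x": x, "y": y})
        m = len(x)
        above_below[name] = (
            float((y > x).sum()) / m,
            float((y < x).sum()) / m,
        )
    ex = panels["exchange"]
    if float(np.var(ex["x"])) == 0.0:
        slope, intercept = np.nan, np.nan
    else:
        fit = sps.linregress(ex["x"], ex["y"])
        slope, intercept = float(fit.slope), float(fit.intercept)
    return RatioDiagnostics(
        panels=panels,
        exchange_slope=slope,
        exchange_intercept=intercept,
        above_below=above_below,
    )
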