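"""Domain types, parameter catalog, standards, validation and the
charge-balance quality gate.

The canonical parameter order defined by :data:`DEFAULT_CATALOG` fixes column
order everywhere downstream; every table is reordered to it during
validation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "IonSpec",
    "ParameterCatalog",
    "DEFAULT_CATALOG",
    "SampleTable",
    "StandardsTable",
    "ClassificationScheme",
    "ValidationIssue",
    "SchemaError",
    "ValidationError",
    "validate_sample_table",
    "charge_balance_error",
    "filter_by_cbe",
]


class SchemaError(ValueError):
    """Input table does not match the expected schema (unknown/missing columns)."""


class ValidationError(ValueError):
    """Input table has invalid values (negative concentrations, bad pH...)."""


@dataclass(frozen=True)
class IonSpec:
    """Charge metadata for an ionic parameter.

    ``mass_factor`` converts the reported mass to the mass of the charged
    species (used for the N-reported species NO3-N and NO2-N); ``eq_mass`` is
    the equivalent mass of the ion in g/eq.
    """

    charge: int
    eq_mass: float
    mass_factor: float = 1.0

    def to_meq(self, conc_mg_l: float | np.ndarray) -> float | np.ndarray:
        return conc_mg_l * self.mass_factor / self.eq_mass


#: NO3-N / NO2-N are reported as nitrogen mass; convert to ion mass first.
_NO3_FACTOR = 62.0 / 14.0
_NO2_FACTOR = 46.0 / 14.0


@dataclass(frozen=True)
class ParameterCatalog:
    """Ordered catalog of measured parameters with unit and ion metadata."""

    parameters: tuple[str, ...]
    units: dict[str, str]
    cations: dict[str, IonSpec]
    anions: dict[str, IonSpec]

    def __post_init__(self) -> None:
        if len(set(self.parameters)) != len(self.parameters):
            raise SchemaError("parameter identifiers must be unique")
        for name, spec in {**self.cations, **self.anions}.items():
            if spec.eq_mass <= 0:
                raise SchemaError(f"ion {name!r} has non-positive equivalent mass")

    @property
    def n_parameters(self) -> int:
        return len(self.parameters)

    @property
    def ionic_parameters(self) -> tuple[str, ...]:
        return tuple(p for p in self.parameters if p in self.cations or p in self.anions)

    def ion_spec(self, name: str) -> IonSpec:
        if name in self.cations:
            return self.cations[name]
        if name in self.anions:
            return self.anions[name]
        raise KeyError(f"{name!r} is not an ionic parameter")

    def subset(self, parameters: Sequence[str]) -> "ParameterCatalog":
        """Catalog restricted to ``parameters`` (catalog order preserved)."""
        keep = [p for p in self.parameters if p in set(parameters)]
        missing = set(parameters) - set(keep)
        if missing:
            raise SchemaError(f"unknown parameters: {sorted(missing)}")
        return ParameterCatalog(
            parameters=tuple(keep),
            units={p: self.units[p] for p in keep},
            cations={p: s for p, s in self.cations.items() if p in keep},
            anions={p: s for p, s in self.anions.items() if p in keep},
        )


# Equivalent masses in g/eq (Fe as Fe3+).
DEFAULT_CATALOG = ParameterCatalog(
    parameters=(
        "pH", "TDS", "TH", "Ca", "Na", "Mg", "K", "Fe",
        "HCO3", "SO4", "Cl", "NO3_N", "F", "NO2_N",
    ),
    units={p: ("unitless" if p == "pH" else "mg/L") for p in (
        "pH", "TDS", "TH", "Ca", "Na", "Mg", "K", "Fe",
        "HCO3", "SO4", "Cl", "NO3_N", "F", "NO2_N",
    )},
    cations={
        "Ca": IonSpec(+2, 20.04),
        "Mg": IonSpec(+2, 12.15),
        "Na": IonSpec(+1, 22.99),
        "K": IonSpec(+1, 39.10),
        "Fe": IonSpec(+3, 18.62),
    },
    anions={
        "HCO3": IonSpec(-1, 61.02),
        "SO4": IonSpec(-2, 48.03),
        "Cl": IonSpec(-1, 35.45),
        "NO3_N": IonSpec(-1, 62.00, mass_factor=_NO3_FACTOR),
        "F": IonSpec(-1, 19.00),
        "NO2_N": IonSpec(-1, 46.01, mass_factor=_NO2_FACTOR),
    },
)

SEASONS = ("dry", "wet", "unlabeled")


@dataclass(frozen=True)
class ValidationIssue:
    sample_id: str | None
    parameter: str | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = "/".join(x for x in (self.sample_id, self.parameter) if x)
        return f"[{loc}] {self.message}" if loc else self.message


@dataclass
class SampleTable:
    """m water samples x n physicochemical parameters.

    ``data`` is indexed by sample id with one column per catalog parameter,
    in catalog order after validation. ``seasons`` aligns with the index.
    """

    data: pd.DataFrame
    seasons: pd.Series
    catalog: ParameterCatalog = DEFAULT_CATALOG
    coordinates: pd.DataFrame | None = None
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def season_subset(self, season: str) -> "SampleTable":
        mask = self.seasons == season
        return dataclasses.replace(
            self,
            data=self.data.loc[mask],
            seasons=self.seasons.loc[mask],
            coordinates=None if self.coordinates is None else self.coordinates.loc[mask],
        )

    def drop_parameter(self, parameter: str) -> "SampleTable":
        keep = [p for p in self.catalog.parameters if p != parameter]
        return dataclasses.replace(
            self,
            data=self.data[keep],
            catalog=self.catalog.subset(keep),
        )

    def to_frame(self) -> pd.DataFrame:
        """Round-trippable frame: sample_id, season, then parameter columns."""
        out = self.data.copy()
        out.insert(0, "season", self.seasons)
        out.index.name = "sample_id"
        if self.coordinates is not None:
            for c in self.coordinates.columns:
                out[c] = self.coordinates[c]
        return out.reset_index()


@dataclass(frozen=True)
class ParameterStandard:
    T: float
    C_ideal: float
    limit: float | None = None


class StandardsTable:
    """Per-parameter standard value T, ideal value C_ideal and %SES limit."""

    def __init__(self, entries: dict[str, ParameterStandard]):
        for name, st in entries.items():
            if st.T == st.C_ideal:
                raise ValueError(f"standard for {name!r} has T == C_ideal")
            if name != "pH" and st.T <= 0:
                raise ValueError(f"standard for {name!r} must be positive")
        self._entries = dict(entries)

    def __getitem__(self, name: str) -> ParameterStandard:
        return self._entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(self._entries)

    def to_dict(self) -> dict[str, dict[str, float | None]]:
        return {
            p: {"T": s.T, "C_ideal": s.C_ideal, "limit": s.limit}
            for p, s in self._entries.items()
        }

    @classmethod
    def from_mapping(cls, mapping: dict) -> "StandardsTable":
        entries = {}
        for name, row in mapping.items():
            entries[name] = ParameterStandard(
                T=float(row["T"]),
                C_ideal=float(row.get("C_ideal", 0.0)),
                limit=None if row.get("limit") is None else float(row["limit"]),
            )
        return cls(entries)

    @classmethod
    def from_yaml(cls, path) -> "StandardsTable":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "StandardsTable":
        ref = resources.files("iwqi.data") / "default_standards.yaml"
        return cls.from_mapping(yaml.safe_load(ref.read_text()))


@dataclass(frozen=True)
class ClassificationScheme:
    """Five quality classes over ordered score boundaries.

    With the default convention, intervals are left-closed/right-open except
    that the top boundary (100) belongs to the fourth class, so "extremely
    poor" is strictly > 100.
    """

    boundaries: tuple[float, ...] = (25.0, 50.0, 75.0, 100.0)
    labels: tuple[str, ...] = (
        "Excellent (I)", "Good (II)", "Medium (III)", "Poor (IV)", "Extremely Poor (V)",
    )
    top_boundary_inclusive: bool = True

    def __post_init__(self) -> None:
        if list(self.boundaries) != sorted(set(self.boundaries)):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.labels) != len(self.boundaries) + 1:
            raise ValueError("need exactly one label per interval")


def _require_columns(frame: pd.DataFrame, catalog: ParameterCatalog) -> None:
    cols = set(frame.columns)
    wanted = set(catalog.parameters)
    unknown = cols - wanted
    if unknown:
        raise SchemaError(f"unknown parameter column(s): {sorted(unknown)}")
    missing = wanted - cols
    if missing:
        raise SchemaError(f"missing parameter column(s): {sorted(missing)}")


def validate_sample_table(
    table: SampleTable,
    catalog: ParameterCatalog | None = None,
    missing_policy: str = "reject",
) -> SampleTable:
    """Validate and canonicalize a sample table.

    Columns are reordered to catalog order; negative concentrations, pH
    outside (0, 14) and missing cells are rejected (``missing_policy='drop-row'``
    drops incomplete rows instead, recording an issue per row).
    """
    catalog = catalog or table.catalog
    if missing_policy not in ("reject", "drop-row"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    _require_columns(table.data, catalog)
    data = table.data[list(catalog.parameters)].astype(float)
    seasons = table.seasons.copy()
    coords = table.coordinates

    issues: list[ValidationIssue] = []
    if data.index.has_duplicates:
        dups = data.index[data.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample_id(s): {dups}")

    na_mask = data.isna()
    if na_mask.to_numpy().any():
        bad_rows = data.index[na_mask.any(axis=1)].tolist()
        if missing_policy == "reject":
            raise ValidationError(f"missing cells in sample(s): {bad_rows}")
        for sid in bad_rows:
            issues.append(ValidationIssue(str(sid), None, "dropped: missing cells"))
        keep = ~na_mask.any(axis=1)
        data, seasons = data.loc[keep], seasons.loc[keep]
        coords = None if coords is None else coords.loc[keep]

    bad_cells = []
    for p in catalog.parameters:
        col = data[p]
        if p == "pH":
            bad = (col <= 0) | (col >= 14)
        else:
            bad = col < 0
        for sid in data.index[bad]:
            bad_cells.append((str(sid), p, float(col.loc[sid])))
    if bad_cells:
        detail = ", ".join(f"{sid}/{p}={v}" for sid, p, v in bad_cells)
        raise ValidationError(f"invalid value(s): {detail}")

    bad_season = ~seasons.isin(SEASONS)
    if bad_season.any():
        raise ValidationError(
            f"unknown season label(s): {sorted(seasons[bad_season].unique())}"
        )

    data.index.name = "sample_id"
    return SampleTable(
        data=data, seasons=seasons, catalog=catalog, coordinates=coords, issues=issues
    )


def sample_meq_sums(
    values: pd.Series | dict, catalog: ParameterCatalog = DEFAULT_CATALOG
) -> tuple[float, float]:
    """(cation, anion) meq/L sums for one sample."""
    cat = sum(spec.to_meq(float(values[p])) for p, spec in catalog.cations.items())
    ani = sum(spec.to_meq(float(values[p])) for p, spec in catalog.anions.items())
    return float(cat), float(ani)


def charge_balance_error(
    sample: pd.Series | dict, catalog: ParameterCatalog = DEFAULT_CATALOG
) -> float:
    """Charge balance error in percent: 100*(cat - an)/(cat + an), meq basis."""
    cat, ani = sample_meq_sums(sample, catalog)
    total = cat + ani
    if total == 0:
        raise ValidationError("charge balance undefined: all ion concentrations zero")
    return 100.0 * (cat - ani) / total


def filter_by_cbe(
    table: SampleTable, threshold: float = 5.0
) -> tuple[SampleTable, pd.DataFrame]:
    """Keep samples with |CBE| < threshold; report the rejected ones.

    Returns the filtered table and a report frame (sample_id, cbe_percent)
    for rejected samples.
    """
    cbe = pd.Series(
        [charge_balance_error(row, table.catalog) for _, row in table.data.iterrows()],
        index=table.data.index,
        name="cbe_percent",
    )
    keep = cbe.abs() < threshold
    rejected = cbe[~keep].rename_axis("sample_id").reset_index()
    filtered = dataclasses.replace(
        table,
        data=table.data.loc[keep],
        seasons=table.seasons.loc[keep],
        coordinates=None if table.coordinates is None else table.coordinates.loc[keep],
    )
    return filtered, rejected
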