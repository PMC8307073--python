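"""Quality rating, IWQI aggregation, five-class classification, baseline
WQI and index-removal sensitivity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ClassificationScheme, SampleTable, StandardsTable
from .weighting import (
    LiteratureWeightDB,
    SSAConfig,
    WeightVector,
    weight_pipeline,
)

__all__ = [
    "IWQIResult",
    "SensitivityResult",
    "quality_rating",
    "iwqi_score",
    "classify",
    "class_distribution",
    "baseline_wqi",
    "sensitivity",
    "score_table",
]


@dataclass
class IWQIResult:
    """Scores, class labels and the ingredients used to produce them."""

    scores: pd.Series  # per sample
    labels: pd.Series
    weights: WeightVector
    q_matrix: pd.DataFrame  # samples x parameters
    seasons: pd.Series
    scheme: ClassificationScheme

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"season": self.seasons, "IWQI": self.scores, "class": self.labels}
        ).rename_axis("sample_id")


@dataclass
class SensitivityResult:
    """Per-sample, per-removed-parameter sensitivity (percent)."""

    s_matrix: pd.DataFrame  # samples x removed parameter
    mean_per_parameter: pd.Series
    season: str
    denominator: str
    flagged: tuple[str, ...] = ()


def quality_rating(
    table: SampleTable | pd.DataFrame,
    standards: StandardsTable,
    ph_mode: str = "signed",
) -> pd.DataFrame:
    """Per-sample, per-parameter rating Q = 100*(C - C_ideal)/(T - C_ideal).

    For pH (C_ideal 7, T 8.5 by default) this is 100*(pH - 7)/1.5, which is
    negative below 7 in the default ``signed`` mode; ``symmetric`` rates the
    deviation |pH - 7| instead.
    """
    if ph_mode not in ("signed", "symmetric"):
        raise ValueError(f"unknown ph_mode {ph_mode!r}")
    data = table.data if isinstance(table, SampleTable) else table
    q = pd.DataFrame(index=data.index, columns=data.columns, dtype=float)
    for p in data.columns:
        if p not in standards:
            raise KeyError(f"no standard defined for parameter {p!r}")
        st = standards[p]
        c = data[p].astype(float)
        if p == "pH" and ph_mode == "symmetric":
            c = st.C_ideal + (c - st.C_ideal).abs()
        q[p] = 100.0 * (c - st.C_ideal) / (st.T - st.C_ideal)
    return q


def iwqi_score(q_matrix: pd.DataFrame, weights: WeightVector) -> pd.Series:
    """Weighted aggregation: score_i = sum_j W_j * Q_ij."""
    if tuple(q_matrix.columns) != weights.parameters:
        raise ValueError("Q matrix columns do not match weight vector parameters")
    scores = q_matrix.to_numpy(dtype=float) @ weights.weights
    return pd.Series(scores, index=q_matrix.index, name="IWQI")


def classify(score: float, scheme: ClassificationScheme = ClassificationScheme()) -> str:
    """Class label for one score (left-closed right-open bands; the top
    boundary belongs to the band below it by default)."""
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    b = scheme.boundaries
    top = b[-1]
    if scheme.top_boundary_inclusive and score == top:
        return scheme.labels[-2]
    for bound, label in zip(b, scheme.labels):
        if score < bound:
            return label
    return scheme.labels[-1]


def classify_series(
    scores: pd.Series, scheme: ClassificationScheme = ClassificationScheme()
) -> pd.Series:
    return pd.Series(
        [classify(s, scheme) for s in scores], index=scores.index, name="class"
    )


def class_distribution(
    labels, scheme: ClassificationScheme = ClassificationScheme()
) -> pd.DataFrame:
    """Counts and percentages per class, in scheme order.

    ``labels`` may be a sequence of class labels or of :class:`IWQIResult`
    (whose per-sample labels are pooled). Percentages are 100*count/m rounded
    to 2 decimals.
    """
    flat: list[str] = []
    for item in labels:
        if isinstance(item, IWQIResult):
            flat.extend(item.labels.tolist())
        else:
            flat.append(item)
    if not flat:
        raise ValueError("no classified samples")
    unknown = set(flat) - set(scheme.labels)
    if unknown:
        raise ValueError(f"labels not in scheme: {sorted(unknown)}")
    m = len(flat)
    counts = [flat.count(label) for label in scheme.labels]
    return pd.DataFrame(
        {
            "count": counts,
            "percent": [round(100.0 * c / m, 2) for c in counts],
        },
        index=list(scheme.labels),
    ).rename_axis("class")


def baseline_wqi(q_matrix: pd.DataFrame, weights: WeightVector) -> pd.Series:
    """Conventional WQI: same aggregation, externally supplied weights."""
    return iwqi_score(q_matrix, weights).rename("WQI")


def score_table(
    table: SampleTable,
    standards: StandardsTable,
    db: LiteratureWeightDB,
    config: SSAConfig = SSAConfig(),
    scheme: ClassificationScheme = ClassificationScheme(),
    ph_mode: str = "signed",
) -> IWQIResult:
    """Full scoring pass: weight pipeline + rating + aggregation + classes."""
    report = weight_pipeline(table, db, config)
    q = quality_rating(table, standards, ph_mode=ph_mode)
    scores = iwqi_score(q, report.integrated)
    labels = classify_series(scores, scheme)
    season = table.seasons.iloc[0] if table.seasons.nunique() == 1 else "mixed"
    return IWQIResult(scores, labels, report.integrated, q, table.seasons, scheme)


def sensitivity(
    table: SampleTable,
    standards: StandardsTable,
    db: LiteratureWeightDB,
    config: SSAConfig = SSAConfig(),
    denominator: str = "V",
    ph_mode: str = "signed",
) -> SensitivityResult:
    """Index-removal sensitivity.

    For each parameter i the FULL weighting pipeline (entropy -> simulation
    -> integration) is recomputed on the remaining n-1 parameters and the
    table rescored; per sample,

        S_i = |V/N - v/n| / D * 100

    with V the full-index score over N parameters, v the reduced score over
    n = N-1, and D the full score V (``denominator='V'``, default) or the
    reduced score v (``denominator='v'``).
    """
    if denominator not in ("V", "v"):
        raise ValueError(f"unknown denominator {denominator!r}")
    params = tuple(table.catalog.parameters)
    if len(params) < 2:
        raise ValueError("sensitivity needs at least 2 parameters")

    full = score_table(table, standards, db, config, ph_mode=ph_mode)
    big_n = len(params)
    s = pd.DataFrame(index=table.data.index, columns=list(params), dtype=float)
    flagged: list[str] = []
    for p in params:
        reduced_table = table.drop_parameter(p)
        try:
            if reduced_table.catalog.n_parameters == 1:
                # single remaining parameter: weights are trivially (1,)
                q = quality_rating(reduced_table, standards, ph_mode=ph_mode)
                v = pd.Series(q.iloc[:, 0], index=q.index)
            else:
                reduced = score_table(reduced_table, standards, db, config, ph_mode=ph_mode)
                v = reduced.scores
        except ValueError:
            flagged.append(p)
            s[p] = np.nan
            continue
        d = full.scores if denominator == "V" else v
        s[p] = (full.scores / big_n - v / (big_n - 1)).abs() / d.abs() * 100.0

    season = table.seasons.iloc[0] if table.seasons.nunique() == 1 else "mixed"
    return SensitivityResult(
        s_matrix=s,
        mean_per_parameter=s.mean(axis=0).rename("mean_S_percent"),
        season=season,
        denominator=denominator,
        flagged=tuple(flagged),
    )
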