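"""End-to-end pipeline runner: validate -> CBE filter -> weights -> scores
-> classes -> sensitivity -> diagnostics, with a provenance manifest."""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core import ClassificationScheme, SampleTable, StandardsTable, filter_by_cbe
from .diagnostics import (
    descriptive_stats,
    gibbs_ratios,
    ion_ratio_panel,
    piper_coordinates,
    to_meq,
    water_types,
)
from .io import config_hash, read_samples, read_standards, read_weight_db, write_report
from .scoring import baseline_wqi, class_distribution, score_table, sensitivity
from .weighting import LiteratureWeightDB, SSAConfig, WeightVector, weight_pipeline

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    samples: Path
    out_dir: Path
    weights_db: Path | None = None  # None -> packaged literature database
    standards: Path | None = None  # None -> packaged defaults
    seed: int = 0
    n_simulations: int = 2000
    negative_policy: str = "clip"
    season: str = "all"  # dry | wet | all
    cbe_threshold: float = 5.0
    sensitivity_denominator: str = "V"
    ph_mode: str = "signed"
    scheme: ClassificationScheme = field(default_factory=ClassificationScheme)
    run_baseline: bool = True

    def ssa_config(self) -> SSAConfig:
        return SSAConfig(
            n_simulations=self.n_simulations,
            seed=self.seed,
            negative_policy=self.negative_policy,  # type: ignore[arg-type]
        )

    def provenance(self) -> dict:
        payload = {
            "iwqi_version": __version__,
            "seed": self.seed,
            "n_simulations": self.n_simulations,
            "negative_policy": self.negative_policy,
            "season": self.season,
            "cbe_threshold": self.cbe_threshold,
            "sensitivity_denominator": self.sensitivity_denominator,
            "ph_mode": self.ph_mode,
            "samples": str(self.samples),
            "weights_db": str(self.weights_db) if self.weights_db else "<packaged>",
            "standards": str(self.standards) if self.standards else "<packaged>",
        }
        payload["config_hash"] = config_hash(payload)
        return payload


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _season_tables(table: SampleTable, season: str) -> dict[str, SampleTable]:
    if season != "all":
        return {season: table.season_subset(season)}
    present = [s for s in ("dry", "wet", "unlabeled") if (table.seasons == s).any()]
    return {s: table.season_subset(s) for s in present}


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and write the report bundle to ``config.out_dir``.

    Returns a mapping of report name to written path. On any stage failure
    partial outputs are removed and :class:`PipelineError` is raised.
    """
    out = Path(config.out_dir)
    fresh = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()
    written: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame, index: bool = True) -> None:
        path = out / f"{name}.csv"
        write_report(frame, path, prov, index=index)
        written[name] = path

    try:
        if config.standards is not None:
            standards = _stage("read-standards")(read_standards)(config.standards)
        else:
            standards = StandardsTable.default()
        if config.weights_db is not None:
            db = _stage("read-weight-db")(read_weight_db)(config.weights_db)
        else:
            db = LiteratureWeightDB.packaged()
        table = _stage("read-samples")(read_samples)(config.samples)

        filtered, rejected = _stage("cbe-filter")(filter_by_cbe)(
            table, config.cbe_threshold
        )
        emit("cbe_rejections", rejected, index=False)

        score_rows, sens_rows, weight_rows, dist_rows = [], [], [], []
        diag_piper, diag_gibbs, slope_rows = [], [], []
        for season, sub in _season_tables(filtered, config.season).items():
            if sub.n_samples == 0:
                continue
            ssa = config.ssa_config()
            report = _stage("weights")(weight_pipeline)(sub, db, ssa)
            wf = report.as_frame()
            wf.insert(0, "season", season)
            wf["G_raw"] = report.integration.g_raw
            wf["G"] = report.integration.g
            weight_rows.append(wf)

            result = _stage("score")(score_table)(
                sub, standards, db, ssa, config.scheme, config.ph_mode
            )
            frame = result.as_frame()
            frame["CBE_percent"] = [_cbe(sub, sid) for sid in frame.index]
            if config.run_baseline:
                lit_mean = report.stats.mean / report.stats.mean.sum()
                wqi_w = WeightVector(report.parameters, lit_mean, "objective")
                frame["WQI_baseline"] = baseline_wqi(result.q_matrix, wqi_w)
            score_rows.append(frame)

            dist = class_distribution([result], config.scheme)
            dist.insert(0, "season", season)
            dist_rows.append(dist)

            sens = _stage("sensitivity")(sensitivity)(
                sub,
                standards,
                db,
                ssa,
                config.sensitivity_denominator,
                config.ph_mode,
            )
            sf = pd.DataFrame(
                {
                    "season": season,
                    "mean_S_percent": sens.mean_per_parameter,
                    "min_S_percent": sens.s_matrix.min(axis=0),
                    "max_S_percent": sens.s_matrix.max(axis=0),
                }
            ).rename_axis("parameter")
            sens_rows.append(sf)

            meq = _stage("diagnostics")(to_meq)(sub)
            coords = piper_coordinates(meq)
            pf = pd.concat(
                [
                    coords.cation_pct.add_prefix("cat_"),
                    coords.anion_pct.add_prefix("an_"),
                    coords.diamond,
                ],
                axis=1,
            )
            pf["water_type"] = water_types(coords)
            pf.insert(0, "season", season)
            diag_piper.append(pf)
            gf = gibbs_ratios(sub, meq).gibbs
            gf.insert(0, "season", season)
            diag_gibbs.append(gf)
            panel = ion_ratio_panel(meq)
            slope_rows.append(
                pd.DataFrame(
                    {
                        "season": [season],
                        "exchange_slope": [panel.exchange_slope],
                        "exchange_intercept": [panel.exchange_intercept],
                    }
                )
            )

        if not score_rows:
            raise PipelineError("stage 'score' failed: no samples in requested season")

        emit("weights", pd.concat(weight_rows).rename_axis("parameter"))
        emit("scores", pd.concat(score_rows).rename_axis("sample_id"))
        emit("class_distribution", pd.concat(dist_rows))
        emit("sensitivity", pd.concat(sens_rows))
        emit("piper", pd.concat(diag_piper).rename_axis("sample_id"))
        emit("gibbs", pd.concat(diag_gibbs).rename_axis("sample_id"))
        emit("exchange_slope", pd.concat(slope_rows), index=False)
        emit("descriptive_stats", descriptive_stats(filtered, standards))

        manifest = dict(prov)
        manifest["standards_used"] = standards.to_dict()
        manifest["n_samples_input"] = table.n_samples
        manifest["n_samples_scored"] = filtered.n_samples
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written["manifest"] = manifest_path
    except Exception:
        if fresh:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for path in written.values():
                path.unlink(missing_ok=True)
        raise
    return written


def _cbe(table: SampleTable, sample_id) -> float:
    from .core import charge_balance_error

    return charge_balance_error(table.data.loc[sample_id], table.catalog)
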