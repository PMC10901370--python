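"""Pipeline orchestration: generate -> anomalies -> extremes -> drivers
-> surrogate -> cleans, with CSV outputs, a JSON manifest and logging.

Every stage reads the tables written by its predecessors (or takes
them in memory), so stages can be run individually from the CLI or all
at once with :func:`run_pipeline`.  Identical configurations produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .anomaly import compute_anomalies
from .config import RunConfig
from .drivers import build_driver_table, correlate_drivers
from .extremes import (
    area_weighted_mean,
    cumulative_curve,
    ewy_share_of_total,
    exclude_smallest_fpus,
    extreme_summaries,
    interval_table,
)
from .policy import EmulatorPredictor, constraint_sweep
from .surrogate import fit_crop_surrogates, partial_dependence, prepare_features
from .synthetic import (
    generate_world,
    simulate_records,
    world_to_frame,
    _emulator_seed,
)

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("cleans")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


SCHEMA_NOTE = """\
# Column units for the pipeline CSV outputs.
world.csv:
  cropland_area: ha
  mean_precip: mm/yr
  sd_precip: mm/yr
  mean_temp: degC
  BD: g/cm^3
  CF: "%"
  SDC: "%"
  STC: "%"
  baseline_nin: kg N/ha/yr
records.csv:
  aPr: mm
  gsPr: mm
  ferPr: mm
  aT: degC
  gsT: degC
  nin: kg N/ha
  nw: kg N/ha (= nws + nwr + nwl)
  nws: kg N/ha (erosion)
  nwr: kg N/ha (surface runoff)
  nwl: kg N/ha (leaching)
  uptake: kg N/ha
  residual_n: kg N/ha
  gaseous_n: kg N/ha
  yield: t/ha
anomalies.csv:
  sa: baseline-SD units
  diffpr: dimensionless
  baseline_mean: mm
  baseline_sd: mm
extremes.csv:
  longterm_mean_nw: kg N/ha/yr
  ewy_mean_nw: kg N/ha/yr
  extreme_nw_pct: "%"
  ci_low: "%"
  ci_high: "%"
intervals.csv:
  mean_change_pct: "%"
cleans.csv:
  d_extreme_nw: "%"
  d_nin: "%"
  d_yield: "%"
"""


STAGE_ORDER = ["generate", "anomalies", "extremes", "drivers", "surrogate", "cleans"]


def run_pipeline(config: RunConfig, outdir=None, through: str | None = None) -> Path:
    """Execute stages in order and write outputs under the run directory.

    ``through`` stops the run after the named stage (default: run all).
    Returns the run directory.  Any stage failure is re-raised as
    :class:`PipelineError` naming the stage.
    """
    if through is not None and through not in STAGE_ORDER:
        raise ValueError(f"unknown stage {through!r}")
    config.validate()
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_digest": config.digest(),
        "version": __version__,
        "stages": {},
    }

    def stage(name, fn):
        log.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:  # pragma: no cover - error path
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # -- generate ------------------------------------------------------
    def _generate():
        profiles = generate_world(config.world.n_fpus, config.seeds.world, config.world)
        profiles = exclude_smallest_fpus(profiles, config.exclude_area_fraction)
        records, climates = simulate_records(
            profiles,
            config.n_years,
            config.crops,
            config.emulator,
            config.seeds.climate,
            config.seeds.emulator,
            config.climate,
            burn_in=config.burn_in,
            start_year=config.start_year,
        )
        return profiles, records, climates

    profiles, records, climates = stage("generate", _generate)
    world = world_to_frame(profiles)
    _write(world, out / "world.csv")
    _write(records, out / "records.csv")
    manifest["stages"]["generate"] = {"fpus": len(profiles), "records": len(records)}
    if through == "generate":
        return _finish(out, manifest, config)

    # -- anomalies -----------------------------------------------------
    anomalies = stage("anomalies", lambda: compute_anomalies(records, config.anomaly))
    _write(anomalies, out / "anomalies.csv")
    manifest["stages"]["anomalies"] = {
        "rows": len(anomalies),
        "ewy_frequency_pct": float(100.0 * anomalies["ewy"].mean()),
    }
    if through == "anomalies":
        return _finish(out, manifest, config)

    # -- extremes ------------------------------------------------------
    def _extremes():
        summaries = extreme_summaries(
            records, anomalies, seed=config.seeds.bootstrap
        )
        summaries = summaries.merge(
            world[["fpu_id", "cropland_area"]], on="fpu_id", how="left"
        )
        intervals = interval_table(records, anomalies, seed=config.seeds.bootstrap)
        return summaries, intervals

    summaries, intervals = stage("extremes", _extremes)
    _write(summaries, out / "extremes.csv")
    _write(intervals, out / "intervals.csv")
    with_ewy = summaries[summaries["n_ewy"] > 0]
    manifest["stages"]["extremes"] = {
        "units": len(summaries),
        "units_with_ewy": len(with_ewy),
        "area_weighted_extreme_nw_pct": (
            area_weighted_mean(summaries["extreme_nw_pct"], summaries["cropland_area"])
            if len(summaries)
            else None
        ),
        "ewy_share_of_total_pct": ewy_share_of_total(records, anomalies),
    }
    curve = cumulative_curve(summaries, weighted=True)
    _write(
        curve[["fpu_id", "crop", "irrigated", "excess", "cumulative_pct"]],
        out / "cumulative_curve.csv",
    )
    if through == "extremes":
        return _finish(out, manifest, config)

    # -- drivers -------------------------------------------------------
    def _drivers():
        table = build_driver_table(summaries, records, world)
        corr = correlate_drivers(table)
        return table, corr

    driver_table, driver_corr = stage("drivers", _drivers)
    _write(driver_table, out / "drivers.csv")
    _write(driver_corr, out / "driver_correlations.csv")
    manifest["stages"]["drivers"] = {"rows": len(driver_table)}
    if through == "drivers":
        return _finish(out, manifest, config)

    # -- surrogate -----------------------------------------------------
    def _surrogate():
        matrix = prepare_features(records, anomalies, world, config.surrogate)
        return matrix, *fit_crop_surrogates(
            matrix,
            config.crops,
            config.surrogate,
            split_seed=config.seeds.split,
            cv_seed=config.seeds.cv,
        )

    matrix, models, metrics = stage("surrogate", _surrogate)
    _write(metrics, out / "surrogate_eval.csv")
    for crop in config.crops:
        pdp = partial_dependence(models[(crop, "nw")], "diffPr")
        _write(pdp, out / f"pdp_diffPr_{crop}.csv")
    manifest["stages"]["surrogate"] = {
        "rows": len(matrix),
        "models": [f"{c}:{r}" for (c, r) in models],
    }
    if through == "surrogate":
        return _finish(out, manifest, config)

    # -- cleans --------------------------------------------------------
    def _cleans():
        units = []
        by_fpu = {p.fpu_id: (i, p) for i, p in enumerate(profiles)}
        adf = anomalies.set_index(["fpu_id", "year"]).sort_index()
        for (fpu_id, crop), grp in records.groupby(["fpu_id", "crop"], sort=True):
            i, profile = by_fpu[fpu_id]
            grp = grp.sort_values("year")
            years = grp["year"].to_numpy()
            sub = adf.loc[fpu_id].reindex(years)
            ci = list(config.crops).index(crop)
            predictor = EmulatorPredictor(
                profile=profile,
                climate=climates[fpu_id],
                params=config.emulator.for_crop(crop),
                seed=_emulator_seed(config.seeds.emulator, i, ci),
                crop=crop,
                burn_in=config.burn_in,
            )
            units.append(
                {
                    "fpu_id": fpu_id,
                    "crop": crop,
                    "irrigated": bool(profile.irrigated),
                    "predictor": predictor,
                    "nin": grp["nin"].to_numpy(),
                    "diffpr": sub["diffpr"].to_numpy(),
                    "ewy": sub["ewy"].to_numpy(dtype=bool),
                }
            )
        caps = [(config.cleans.max_yield_loss, config.cleans.max_nin_reduction)]
        return constraint_sweep(units, caps, config.cleans)

    cleans_df = stage("cleans", _cleans)
    _write(cleans_df, out / "cleans.csv")
    manifest["stages"]["cleans"] = {
        "units": len(cleans_df),
        "feasible": int(cleans_df["feasible"].sum()),
    }

    return _finish(out, manifest, config)


def _finish(out: Path, manifest: dict, config: RunConfig) -> Path:
    (out / "schema.yaml").write_text(SCHEMA_NOTE, encoding="utf-8")
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    config.to_yaml(out / "config.yaml")
    log.info("run complete: %s", out)
    return out
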