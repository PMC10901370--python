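"""Shared synthetic-world fixtures.

Heavy artifacts (the default 200-FPU world and the tuned maize
surrogate) are session-scoped so the full suite builds each once.
"""

from __future__ import annotations

import dataclasses

import pytest

from cleans.anomaly import compute_anomalies
from cleans.config import RunConfig
from cleans.extremes import extreme_summaries
from cleans.surrogate import fit_crop_surrogates, prepare_features
from cleans.synthetic import generate_world, simulate_records, world_to_frame


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def world200(default_config):
    """Default 200-FPU world, 3 crops x 30 years after a 5-year burn-in."""
    cfg = default_config
    profiles = generate_world(cfg.world.n_fpus, cfg.seeds.world, cfg.world)
    records, climates = simulate_records(
        profiles,
        cfg.n_years,
        cfg.crops,
        cfg.emulator,
        cfg.seeds.climate,
        cfg.seeds.emulator,
        cfg.climate,
        burn_in=cfg.burn_in,
        start_year=cfg.start_year,
    )
    anomalies = compute_anomalies(records, cfg.anomaly)
    return {
        "config": cfg,
        "profiles": profiles,
        "world": world_to_frame(profiles),
        "records": records,
        "climates": climates,
        "anomalies": anomalies,
    }


@pytest.fixture(scope="session")
def summaries200(world200):
    summ = extreme_summaries(
        world200["records"], world200["anomalies"], n_boot=200, seed=5
    )
    return summ.merge(
        world200["world"][["fpu_id", "cropland_area"]], on="fpu_id", how="left"
    )


@pytest.fixture(scope="session")
def lownoise_maize(default_config):
    """Low-noise maize world (80 FPUs x 25 years) for surrogate fidelity."""
    cfg = default_config
    params = dataclasses.replace(
        cfg.emulator, noise_sd_nw=0.05, noise_sd_yield=0.05
    )
    profiles = generate_world(80, cfg.seeds.world, cfg.world)
    records, climates = simulate_records(
        profiles,
        25,
        ("maize",),
        params,
        cfg.seeds.climate,
        cfg.seeds.emulator,
        cfg.climate,
        burn_in=cfg.burn_in,
    )
    anomalies = compute_anomalies(records, cfg.anomaly)
    matrix = prepare_features(records, anomalies, world_to_frame(profiles))
    return {
        "config": cfg,
        "params": params,
        "profiles": profiles,
        "records": records,
        "climates": climates,
        "anomalies": anomalies,
        "matrix": matrix,
    }


@pytest.fixture(scope="session")
def maize_surrogate(lownoise_maize):
    """Tuned maize forests (nw and yield) with holdout metrics."""
    cfg = lownoise_maize["config"]
    models, metrics = fit_crop_surrogates(
        lownoise_maize["matrix"],
        ("maize",),
        cfg.surrogate,
        split_seed=cfg.seeds.split,
        cv_seed=cfg.seeds.cv,
    )
    return {"models": models, "metrics": metrics}
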