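"""Synthetic agroecosystem generator.

Produces a world of food production units (FPUs), per-FPU annual
climate series, and an annual soil nitrogen-balance emulation that
yields aquatic nitrogen losses (split into erosion, runoff, and
leaching components), crop uptake, yield, and residual soil N.

The emulator is deliberately simple but carries the one mechanism the
downstream statistics depend on: residual mineral N accumulates in dry
years (low loss fraction, water-stressed uptake) and is flushed out in
a subsequent wet year, so wet-after-dry transitions produce loss
pulses.  All randomness is drawn from explicit seeds; identical inputs
and seeds give byte-identical output tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ClimateConfig, EmulatorParams, WorldConfig

__all__ = [
    "FPUProfile",
    "ClimateSeries",
    "Scenario",
    "generate_world",
    "generate_climate",
    "simulate_agroecosystem",
    "make_future_scenario",
    "simulate_records",
    "world_to_frame",
    "RECORD_COLUMNS",
]


@dataclass
class FPUProfile:
    """One spatial analysis unit: soils, area, baseline N input, climate moments."""

    fpu_id: str
    cropland_area: float  # ha
    mean_precip: float  # mm/yr
    sd_precip: float  # mm/yr
    mean_temp: float  # degC
    bd: float  # bulk density, g/cm^3
    cf: float  # coarse fragment, %
    sdc: float  # sand content, %
    stc: float  # silt content, %
    baseline_nin: float  # kg N/ha/yr
    irrigated: bool

    def __post_init__(self) -> None:
        if self.cropland_area <= 0:
            raise ValueError("cropland_area must be positive")
        if self.mean_precip <= 0:
            raise ValueError("mean_precip must be positive")
        if self.sd_precip < 0:
            raise ValueError("sd_precip must be nonnegative")
        for name in ("cf", "sdc", "stc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100]")
        if self.sdc + self.stc > 100.0:
            raise ValueError("sand + silt content must not exceed 100%")
        if self.baseline_nin < 0:
            raise ValueError("baseline_nin must be nonnegative")


@dataclass
class ClimateSeries:
    """Annual climate variables for one FPU.

    Invariant by construction: ferPr <= gsPr <= aPr for every year.
    """

    years: np.ndarray
    apr: np.ndarray  # annual precipitation, mm
    gspr: np.ndarray  # growing-season precipitation, mm
    ferpr: np.ndarray  # fertilization-window precipitation, mm
    at: np.ndarray  # annual mean temperature, degC
    gst: np.ndarray  # growing-season temperature, degC

    def __post_init__(self) -> None:
        n = len(self.years)
        for name in ("apr", "gspr", "ferpr", "at", "gst"):
            if len(getattr(self, name)) != n:
                raise ValueError("climate series lengths must match")
        if np.any(self.apr < 0):
            raise ValueError("precipitation must be nonnegative")
        if np.any(self.gspr > self.apr + 1e-9) or np.any(self.ferpr > self.gspr + 1e-9):
            raise ValueError("ferPr <= gsPr <= aPr violated")


@dataclass
class Scenario:
    """A labelled future scenario as multiplicative shifts of the generator."""

    label: str
    precip_mean_mult: float = 1.0
    precip_sd_mult: float = 1.0
    nin_mult: float = 1.0

    def __post_init__(self) -> None:
        for name in ("precip_mean_mult", "precip_sd_mult", "nin_mult"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------


def generate_world(
    n_fpus: int, seed: int, config: WorldConfig | None = None
) -> list[FPUProfile]:
    """Sample ``n_fpus`` FPU profiles spanning a dry-to-wet gradient.

    Mean precipitation is uniform over ``config.precip_range``; the
    precipitation CV is tied to aridity when
    ``config.couple_cv_to_aridity`` is set (driest units get the top of
    ``cv_range``, wettest the bottom).  Roughly ``irrigated_frac`` of
    units are irrigated.  Deterministic given ``seed``.
    """
    if n_fpus < 1:
        raise ValueError("n_fpus must be >= 1")
    cfg = config or WorldConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    mean_precip = rng.uniform(*cfg.precip_range, size=n_fpus)
    lo, hi = cfg.precip_range
    if cfg.couple_cv_to_aridity:
        # dry units -> high relative variability, plus a little scatter
        wetness_rank = (mean_precip - lo) / (hi - lo)
        cv = cfg.cv_range[1] - wetness_rank * (cfg.cv_range[1] - cfg.cv_range[0])
        cv = np.clip(cv + rng.normal(0.0, 0.02, size=n_fpus), 0.05, 0.5)
    else:
        cv = rng.uniform(*cfg.cv_range, size=n_fpus)
    sd_precip = cv * mean_precip

    mean_temp = rng.uniform(*cfg.temp_range, size=n_fpus)
    nin = rng.uniform(*cfg.nin_range, size=n_fpus)
    area = 10.0 ** rng.uniform(*cfg.log10_area_range, size=n_fpus)
    bd = rng.uniform(*cfg.bd_range, size=n_fpus)
    cf = rng.uniform(*cfg.cf_range, size=n_fpus)
    sdc = rng.uniform(*cfg.sdc_range, size=n_fpus)
    stc = rng.uniform(*cfg.stc_range, size=n_fpus)
    # keep sand + silt physically valid
    over = sdc + stc > 95.0
    scale = np.where(over, 95.0 / (sdc + stc), 1.0)
    sdc, stc = sdc * scale, stc * scale
    irrigated = rng.random(n_fpus) < cfg.irrigated_frac

    width = len(str(n_fpus))
    return [
        FPUProfile(
            fpu_id=f"FPU{i:0{width}d}",
            cropland_area=float(area[i]),
            mean_precip=float(mean_precip[i]),
            sd_precip=float(sd_precip[i]),
            mean_temp=float(mean_temp[i]),
            bd=float(bd[i]),
            cf=float(cf[i]),
            sdc=float(sdc[i]),
            stc=float(stc[i]),
            baseline_nin=float(nin[i]),
            irrigated=bool(irrigated[i]),
        )
        for i in range(n_fpus)
    ]


def world_to_frame(profiles: Sequence[FPUProfile]) -> pd.DataFrame:
    """Tabulate FPU profiles, one row per unit."""
    return pd.DataFrame(
        {
            "fpu_id": [p.fpu_id for p in profiles],
            "cropland_area": [p.cropland_area for p in profiles],
            "mean_precip": [p.mean_precip for p in profiles],
            "sd_precip": [p.sd_precip for p in profiles],
            "mean_temp": [p.mean_temp for p in profiles],
            "BD": [p.bd for p in profiles],
            "CF": [p.cf for p in profiles],
            "SDC": [p.sdc for p in profiles],
            "STC": [p.stc for p in profiles],
            "baseline_nin": [p.baseline_nin for p in profiles],
            "irrigated": [p.irrigated for p in profiles],
        }
    )


# ---------------------------------------------------------------------------
# Climate generation
# ---------------------------------------------------------------------------


def generate_climate(
    profile: FPUProfile,
    n_years: int,
    seed,
    config: ClimateConfig | None = None,
    start_year: int = 1981,
) -> ClimateSeries:
    """Draw an annual climate series for one FPU.

    Annual precipitation follows a gamma distribution with the
    profile's mean and SD (positive and right-skewed, as annual
    rainfall totals are); a zero SD degenerates to a constant series.
    Growing-season and fertilization-window precipitation are noisy
    fixed fractions, clipped to keep ferPr <= gsPr <= aPr.
    Temperatures are Gaussian about the profile mean.  Deterministic
    given ``seed`` (any value accepted by ``np.random.default_rng``).
    """
    if n_years < 2:
        raise ValueError("n_years must be >= 2 (consecutive-year statistics)")
    cfg = config or ClimateConfig()
    rng = np.random.default_rng(seed)

    mu, sd = profile.mean_precip, profile.sd_precip
    if sd == 0:
        apr = np.full(n_years, mu)
    else:
        shape = (mu / sd) ** 2
        scale = sd * sd / mu
        apr = rng.gamma(shape, scale, size=n_years)

    gs_noise = rng.normal(0.0, cfg.gs_noise_sd, size=n_years)
    gspr = np.clip(cfg.gs_fraction * apr * (1.0 + gs_noise), 0.0, apr)
    fer_noise = rng.normal(0.0, cfg.fer_noise_sd, size=n_years)
    ferpr = np.clip(cfg.fer_fraction * gspr * (1.0 + fer_noise), 0.0, gspr)

    at = rng.normal(profile.mean_temp, cfg.temp_sd, size=n_years)
    gst = at + cfg.gs_temp_offset + rng.normal(0.0, 0.3 * cfg.temp_sd, size=n_years)

    years = np.arange(start_year, start_year + n_years)
    return ClimateSeries(years=years, apr=apr, gspr=gspr, ferpr=ferpr, at=at, gst=gst)


# ---------------------------------------------------------------------------
# Annual nitrogen-balance emulation
# ---------------------------------------------------------------------------

RECORD_COLUMNS = [
    "fpu_id",
    "year",
    "crop",
    "irrigated",
    "aPr",
    "gsPr",
    "ferPr",
    "aT",
    "gsT",
    "nin",
    "nw",
    "nws",
    "nwr",
    "nwl",
    "uptake",
    "residual_n",
    "gaseous_n",
    "yield",
]


def simulate_agroecosystem(
    profile: FPUProfile,
    climate: ClimateSeries,
    nin_series,
    params: EmulatorParams,
    seed,
    crop: str = "maize",
    burn_in: int = 0,
    reference_precip: float | None = None,
) -> pd.DataFrame:
    """Run the annual N balance for one FPU x crop and return records.

    Per year t with available pool ``A_t = residual_{t-1} + nin_t +
    deposition`` and relative wetness ``w_t = aPr_t / reference``:

    * aquatic loss ``nw_t = f(w_t) * A_t * (1 + eps_t)`` with logistic
      ``f`` and Gaussian relative noise, clipped into ``[0, A_t]``,
      then split into leaching / runoff / erosion by fixed fractions;
    * uptake ``= min(uptake_max * s_t, eff * (A_t - nw_t))`` with
      water stress ``s_t`` (1 when irrigated, else
      min(1, gsPr_t / required_gspr)) and single-season extraction
      efficiency ``eff``, so part of the pool always escapes the crop;
    * yield follows a Mitscherlich curve in uptake, scaled by
      ``s_t ** water_stress_exp`` and noised, clipped at 0;
    * residual ``= carryover_retention * (A_t - nw_t - uptake_t)``; the
      rest leaves as gaseous/immobilized N, closing the balance exactly.

    ``burn_in`` initial years are simulated (so the residual pool
    reaches its working regime) but dropped from the returned table.
    ``reference_precip`` defaults to the profile mean; pass the
    historical mean when simulating a future climate so wetness is
    referenced to historical conditions.
    """
    params.validate()
    nin = np.asarray(nin_series, dtype=float)
    n = len(climate.years)
    if len(nin) != n:
        raise ValueError("nin series length must match climate length")
    if np.any(nin < 0):
        raise ValueError("nitrogen input must be nonnegative")
    if burn_in >= n:
        raise ValueError("burn_in must be shorter than the simulated period")

    ref = profile.mean_precip if reference_precip is None else float(reference_precip)
    rng = np.random.default_rng(seed)
    # noise drawn up-front so counterfactual nin reuses identical draws
    eps_nw = rng.normal(0.0, 1.0, size=n) * params.noise_sd_nw
    eps_yield = rng.normal(0.0, 1.0, size=n) * params.noise_sd_yield

    a, b = params.loss_logistic_a, params.loss_logistic_b
    ret = params.carryover_retention

    out = np.empty((n, 9))
    residual = params.initial_residual
    for t in range(n):
        pool = residual + nin[t] + params.deposition
        w = climate.apr[t] / ref
        frac = 1.0 / (1.0 + math.exp(-(a + b * w)))
        nw = frac * pool * (1.0 + eps_nw[t])
        nw = min(max(nw, 0.0), pool)
        if profile.irrigated:
            stress = 1.0
        else:
            stress = min(1.0, climate.gspr[t] / params.required_gspr)
        uptake = min(params.uptake_max * stress, params.uptake_efficiency * (pool - nw))
        yld = (
            params.yield_max
            * (1.0 - math.exp(-params.mitscherlich_k * uptake))
            * stress**params.water_stress_exp
            * (1.0 + eps_yield[t])
        )
        yld = max(yld, 0.0)
        surplus = pool - nw - uptake
        residual_next = ret * surplus
        gaseous = (1.0 - ret) * surplus
        out[t] = (
            nin[t],
            nw,
            (1.0 - params.partition_leach - params.partition_runoff) * nw,
            params.partition_runoff * nw,
            params.partition_leach * nw,
            uptake,
            residual_next,
            gaseous,
            yld,
        )
        residual = residual_next

    df = pd.DataFrame(
        out[burn_in:],
        columns=[
            "nin",
            "nw",
            "nws",
            "nwr",
            "nwl",
            "uptake",
            "residual_n",
            "gaseous_n",
            "yield",
        ],
    )
    df.insert(0, "fpu_id", profile.fpu_id)
    df.insert(1, "year", climate.years[burn_in:])
    df.insert(2, "crop", crop)
    df.insert(3, "irrigated", profile.irrigated)
    attr = {"aPr": "apr", "gsPr": "gspr", "ferPr": "ferpr", "aT": "at", "gsT": "gst"}
    for i, col in enumerate(attr):
        df.insert(4 + i, col, getattr(climate, attr[col])[burn_in:])
    return df[RECORD_COLUMNS]


# ---------------------------------------------------------------------------
# Convenience orchestration
# ---------------------------------------------------------------------------


def _climate_seed(base: int, fpu_index: int):
    return np.random.SeedSequence([base, fpu_index])


def _emulator_seed(base: int, fpu_index: int, crop_index: int):
    return np.random.SeedSequence([base, fpu_index, crop_index])


def simulate_records(
    profiles: Sequence[FPUProfile],
    n_years: int,
    crops: Sequence[str],
    params: EmulatorParams,
    climate_seed: int,
    emulator_seed: int,
    climate_config: ClimateConfig | None = None,
    burn_in: int = 0,
    start_year: int = 1981,
    scenario: Scenario | None = None,
) -> tuple[pd.DataFrame, dict[str, ClimateSeries]]:
    """Simulate every FPU x crop and stack the annual records.

    Returns the combined record table and the per-FPU climate series
    (post burn-in climate is embedded in the records; the full series
    are returned for anomaly baselines).  When ``scenario`` is given,
    climate moments and N input are scaled by its multipliers while
    loss wetness stays referenced to the *historical* profile mean.
    """
    frames = []
    climates: dict[str, ClimateSeries] = {}
    total_years = n_years + burn_in
    for i, profile in enumerate(profiles):
        sim_profile = profile
        if scenario is not None:
            import dataclasses as _dc

            sim_profile = _dc.replace(
                profile,
                mean_precip=profile.mean_precip * scenario.precip_mean_mult,
                sd_precip=profile.sd_precip * scenario.precip_sd_mult,
                baseline_nin=profile.baseline_nin * scenario.nin_mult,
            )
        clim = generate_climate(
            sim_profile,
            total_years,
            _climate_seed(climate_seed, i),
            climate_config,
            start_year=start_year - burn_in,
        )
        climates[profile.fpu_id] = clim
        nin = np.full(total_years, sim_profile.baseline_nin)
        for j, crop in enumerate(crops):
            frames.append(
                simulate_agroecosystem(
                    sim_profile,
                    clim,
                    nin,
                    params.for_crop(crop),
                    _emulator_seed(emulator_seed, i, j),
                    crop=crop,
                    burn_in=burn_in,
                    reference_precip=profile.mean_precip,
                )
            )
    return pd.concat(frames, ignore_index=True), climates


def make_future_scenario(
    profiles: Sequence[FPUProfile],
    n_years: int,
    crops: Sequence[str],
    params: EmulatorParams,
    scenario: Scenario,
    climate_seed: int,
    emulator_seed: int,
    climate_config: ClimateConfig | None = None,
    burn_in: int = 0,
    start_year: int = 2036,
) -> tuple[pd.DataFrame, dict[str, ClimateSeries]]:
    """Generate a future record set under scaled climate/N-input moments.

    The historical profiles are left untouched; a scenario with all
    multipliers equal to 1 and the same seeds reproduces the historical
    generator exactly (up to the start-year labels).
    """
    return simulate_records(
        profiles,
        n_years,
        crops,
        params,
        climate_seed,
        emulator_seed,
        climate_config,
        burn_in=burn_in,
        start_year=start_year,
        scenario=scenario,
    )
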