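"""Run configuration for the extreme nitrogen-loss pipeline.

Every stochastic stage of the pipeline (world generation, climate
sampling, emulator noise, train/test splitting, bootstrap resampling,
cross-validation folds) carries its own explicit seed so that a run is
reproducible from the configuration alone.  The configuration
round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "ConfigError",
    "Seeds",
    "WorldConfig",
    "ClimateConfig",
    "EmulatorParams",
    "CropParams",
    "AnomalyConfig",
    "SurrogateConfig",
    "CleansConfig",
    "RunConfig",
    "CROP_PARAMS",
]


class ConfigError(ValueError):
    """A configuration value violates its documented constraints."""


@dataclass
class Seeds:
    """One integer seed per stochastic pipeline stage."""

    world: int = 1
    climate: int = 2
    emulator: int = 3
    split: int = 4
    bootstrap: int = 5
    cv: int = 6


@dataclass
class WorldConfig:
    """Settings for sampling a synthetic world of food production units.

    Mean annual precipitation spans a dry-to-wet gradient
    (``precip_range``, mm/yr).  The coefficient of variation of annual
    precipitation is drawn from ``cv_range``; with
    ``couple_cv_to_aridity`` the CV decreases linearly with mean
    precipitation, reproducing the observation that dry regions have
    relatively more variable rainfall.  Cropland areas are sampled
    log-uniformly over ``log10_area_range`` (hectares).
    """

    n_fpus: int = 200
    precip_range: tuple[float, float] = (200.0, 2000.0)
    cv_range: tuple[float, float] = (0.15, 0.35)
    couple_cv_to_aridity: bool = True
    temp_range: tuple[float, float] = (5.0, 28.0)
    nin_range: tuple[float, float] = (50.0, 250.0)
    irrigated_frac: float = 0.5
    log10_area_range: tuple[float, float] = (3.0, 6.0)
    bd_range: tuple[float, float] = (1.1, 1.6)
    cf_range: tuple[float, float] = (0.0, 30.0)
    sdc_range: tuple[float, float] = (10.0, 70.0)
    stc_range: tuple[float, float] = (10.0, 60.0)


@dataclass
class ClimateConfig:
    """Settings for per-FPU annual climate series.

    Growing-season precipitation is a fixed fraction of annual
    precipitation in expectation (``gs_fraction``), and the
    fertilization-window precipitation a sub-fraction of that
    (``fer_fraction``); both carry multiplicative noise but are clipped
    to preserve ferPr <= gsPr <= aPr.
    """

    gs_fraction: float = 0.6
    fer_fraction: float = 0.5
    gs_noise_sd: float = 0.10
    fer_noise_sd: float = 0.10
    temp_sd: float = 0.7
    gs_temp_offset: float = 3.0


@dataclass
class CropParams:
    """Crop-specific response parameters (no phenology)."""

    uptake_max: float  # kg N/ha
    yield_max: float  # t/ha
    mitscherlich_k: float  # (kg N/ha)^-1


#: Default crop parameter sets.  Crops differ only through these.
CROP_PARAMS: dict[str, CropParams] = {
    "maize": CropParams(uptake_max=170.0, yield_max=12.0, mitscherlich_k=0.018),
    "rice": CropParams(uptake_max=140.0, yield_max=9.0, mitscherlich_k=0.022),
    "wheat": CropParams(uptake_max=120.0, yield_max=8.0, mitscherlich_k=0.025),
}


@dataclass
class EmulatorParams:
    """Parameters of the annual soil nitrogen-balance emulator.

    The emulator tracks a single mineral-N pool per unit.  Each year the
    available pool (previous residual + input + deposition) loses a
    wetness-dependent fraction to aquatic systems, crops take up N under
    water stress, a retention fraction of the post-season surplus
    carries over as residual soil N, and the remainder closes the
    balance as gaseous/immobilized loss.

    Attributes
    ----------
    carryover_retention : float
        Fraction of post-season surplus kept as residual N, in [0, 1].
    loss_logistic_a, loss_logistic_b : float
        Intercept and slope of the logistic loss fraction
        f(w) = 1/(1 + exp(-(a + b*w))) in relative wetness
        w = aPr / mean aPr; b > 0 so wetter years lose more.
    partition_leach, partition_runoff : float
        Fractions of the aquatic loss routed to leaching and surface
        runoff; erosion takes the remainder.  Sum must be <= 1.
    uptake_max : float
        Potential crop N uptake, kg N/ha (overridden per crop).
    uptake_efficiency : float
        Fraction of the post-loss mineral pool extractable in one
        season, in [0, 1]; keeps fertilizer-N recovery below 100% so a
        residual pool can build up.
    yield_max : float
        Yield plateau, t/ha (overridden per crop).
    mitscherlich_k : float
        Curvature of the diminishing-returns yield response, (kg N/ha)^-1.
    water_stress_exp : float
        Exponent applied to the water-stress scalar in the yield term.
    required_gspr : float
        Growing-season precipitation (mm) at which rainfed crops are
        unstressed; stress = min(1, gsPr / required_gspr).
    deposition : float
        Atmospheric N deposition, kg N/ha/yr.
    noise_sd_nw, noise_sd_yield : float
        Relative SD of the multiplicative Gaussian noise on the aquatic
        loss and on yield.
    initial_residual : float
        Residual-N pool at the start of the burn-in, kg N/ha.
    """

    carryover_retention: float = 0.6
    loss_logistic_a: float = -4.0
    loss_logistic_b: float = 2.5
    partition_leach: float = 0.5
    partition_runoff: float = 0.3
    uptake_max: float = 150.0
    uptake_efficiency: float = 0.7
    yield_max: float = 10.0
    mitscherlich_k: float = 0.02
    water_stress_exp: float = 0.5
    required_gspr: float = 500.0
    deposition: float = 5.0
    noise_sd_nw: float = 0.10
    noise_sd_yield: float = 0.05
    initial_residual: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.carryover_retention <= 1.0:
            raise ConfigError("carryover_retention must lie in [0, 1]")
        if self.loss_logistic_b <= 0:
            raise ConfigError("loss_logistic_b must be positive")
        if self.partition_leach < 0 or self.partition_runoff < 0:
            raise ConfigError("loss partitions must be nonnegative")
        if self.partition_leach + self.partition_runoff > 1.0 + 1e-12:
            raise ConfigError("partition_leach + partition_runoff must be <= 1")
        for name in ("noise_sd_nw", "noise_sd_yield", "water_stress_exp"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.uptake_max < 0 or self.yield_max < 0 or self.mitscherlich_k < 0:
            raise ConfigError("crop response parameters must be nonnegative")
        if not 0.0 <= self.uptake_efficiency <= 1.0:
            raise ConfigError("uptake_efficiency must lie in [0, 1]")

    def for_crop(self, crop: str) -> "EmulatorParams":
        """Return a copy with the crop's uptake/yield parameters applied."""
        try:
            cp = CROP_PARAMS[crop]
        except KeyError:
            raise ConfigError(f"unknown crop {crop!r}") from None
        return dataclasses.replace(
            self,
            uptake_max=cp.uptake_max,
            yield_max=cp.yield_max,
            mitscherlich_k=cp.mitscherlich_k,
        )


@dataclass
class AnomalyConfig:
    """Standardized-anomaly settings.

    ``sd_ddof`` selects the SD divisor convention for the baseline
    (0 = population SD, the default; 1 = sample SD).  Years with
    anomaly strictly above ``ewy_threshold`` (in baseline-SD units)
    are extremely wet years.  Interval bins run from ``bin_lo`` to
    ``bin_hi`` in steps of ``bin_width``, half-open on the right, with
    open tails beyond the stated range.
    """

    ewy_threshold: float = 2.0
    bin_lo: float = -2.5
    bin_hi: float = 3.5
    bin_width: float = 0.5
    sd_ddof: int = 0


@dataclass
class SurrogateConfig:
    """Random-forest surrogate training protocol."""

    mtry_grid: tuple[int, ...] = (2, 3, 5, 8)
    ntree_grid: tuple[int, ...] = (200, 500)
    k_folds: int = 10
    train_frac: float = 0.8
    outlier_alpha: float = 0.001
    #: Drop growing-season precipitation/temperature from predictors
    #: (they are nearly collinear with their annual counterparts).
    exclude_growing_season: bool = True


def _frange(lo: float, hi: float, step: float) -> tuple[float, ...]:
    n = int(round((hi - lo) / step)) + 1
    return tuple(round(lo + i * step, 10) for i in range(n))


@dataclass
class CleansConfig:
    """Grid and constraints for adaptive nitrogen-input scaling."""

    thresholds: tuple[float, ...] = field(
        default_factory=lambda: _frange(0.0, 1.5, 0.1)
    )
    ratios: tuple[float, ...] = field(default_factory=lambda: _frange(0.1, 1.0, 0.1))
    max_yield_loss: float = 3.0  # %, strict
    max_nin_reduction: float = 15.0  # %, strict
    #: SD of Gaussian error added to diffPr before thresholding, to
    #: emulate imperfect seasonal forecasts.  0 disables the hook.
    forecast_noise_sd: float = 0.0


@dataclass
class RunConfig:
    """Top-level configuration of a pipeline run."""

    n_years: int = 30
    burn_in: int = 5
    start_year: int = 1981
    crops: tuple[str, ...] = ("maize", "rice", "wheat")
    seeds: Seeds = field(default_factory=Seeds)
    world: WorldConfig = field(default_factory=WorldConfig)
    climate: ClimateConfig = field(default_factory=ClimateConfig)
    emulator: EmulatorParams = field(default_factory=EmulatorParams)
    anomaly: AnomalyConfig = field(default_factory=AnomalyConfig)
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    cleans: CleansConfig = field(default_factory=CleansConfig)
    exclude_area_fraction: float = 0.0005
    outdir: str = "run"

    def validate(self) -> None:
        if self.world.n_fpus < 1:
            raise ConfigError("n_fpus must be >= 1")
        if self.n_years < 2:
            raise ConfigError("n_years must be >= 2")
        if self.burn_in < 0:
            raise ConfigError("burn_in must be >= 0")
        for crop in self.crops:
            if crop not in CROP_PARAMS:
                raise ConfigError(f"unknown crop {crop!r}")
        self.emulator.validate()

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)

        def build(klass, key):
            if key in d:
                d[key] = klass(**_tuplify(d[key]))

        build(Seeds, "seeds")
        build(WorldConfig, "world")
        build(ClimateConfig, "climate")
        build(EmulatorParams, "emulator")
        build(AnomalyConfig, "anomaly")
        build(SurrogateConfig, "surrogate")
        build(CleansConfig, "cleans")
        if "crops" in d:
            d["crops"] = tuple(d["crops"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(_listify(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        """Stable hash of the configuration, for the run manifest."""
        blob = yaml.safe_dump(_listify(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _tuplify(d: dict[str, Any]) -> dict[str, Any]:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def _listify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj
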