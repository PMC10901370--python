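"""Standardized precipitation anomalies, EWY classification, diffPr.

The standardized anomaly of annual precipitation,
``SA_t = (aPr_t - mean) / sd``, is computed against a multiyear
baseline — either the series' own moments (historical mode) or an
externally supplied historical baseline (future mode).  Years with
SA strictly above a threshold (default 2 baseline-SD units) are
classified as extremely wet years (EWYs).  The consecutive-year
precipitation difference relative to the baseline mean,
``diffPr_t = (aPr_t - aPr_{t-1}) / mean``, flags wet-after-dry
transitions; it is undefined for the first year of a series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnomalyConfig

__all__ = [
    "DegenerateBaselineError",
    "AnomalyProfile",
    "standardized_anomaly",
    "classify_intervals",
    "interval_edges",
    "interval_label",
    "diffpr",
    "compute_anomalies",
]


class DegenerateBaselineError(ValueError):
    """The baseline SD is zero, so anomalies are undefined."""


@dataclass
class AnomalyProfile:
    """Per-FPU anomaly series: baseline moments, SA, bins, EWY flags, diffPr."""

    fpu_id: str
    baseline_mean: float
    baseline_sd: float
    years: np.ndarray
    sa: np.ndarray
    interval: np.ndarray  # string bin labels
    ewy: np.ndarray  # boolean
    diffpr: np.ndarray  # NaN for the first year

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fpu_id": self.fpu_id,
                "year": self.years,
                "sa": self.sa,
                "interval": self.interval,
                "ewy": self.ewy,
                "diffpr": self.diffpr,
                "baseline_mean": self.baseline_mean,
                "baseline_sd": self.baseline_sd,
            }
        )


def standardized_anomaly(
    apr, baseline: tuple[float, float] | None = None, ddof: int = 0
) -> tuple[np.ndarray, tuple[float, float]]:
    """Standardize an annual precipitation series.

    Parameters
    ----------
    apr : array-like
        Annual precipitation, mm.
    baseline : (mean, sd), optional
        External baseline moments.  When omitted the series' own mean
        and SD are used (requires length >= 2); supplying the
        historical moments here is how future series are referenced to
        historical climate.
    ddof : int
        SD divisor convention when the baseline is self-computed
        (0 = population SD, the default).

    Returns
    -------
    (sa, (mean, sd))
        The anomaly series and the baseline actually used.
    """
    x = np.asarray(apr, dtype=float)
    if baseline is None:
        if x.size < 2:
            raise ValueError("need >= 2 years to self-compute a baseline")
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=ddof))
    else:
        mean, sd = float(baseline[0]), float(baseline[1])
    if sd <= 0:
        raise DegenerateBaselineError("baseline SD must be positive")
    return (x - mean) / sd, (mean, sd)


def interval_edges(config: AnomalyConfig | None = None) -> np.ndarray:
    """Interior bin edges in SD units (default -2.5 .. +3.5 step 0.5)."""
    cfg = config or AnomalyConfig()
    n = int(round((cfg.bin_hi - cfg.bin_lo) / cfg.bin_width))
    edges = cfg.bin_lo + cfg.bin_width * np.arange(n + 1)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    return edges


def interval_label(sa: float, edges: np.ndarray) -> str:
    """Half-open bin label for one SA value, with open tail bins."""
    if sa < edges[0]:
        return f"<{edges[0]:g}"
    if sa >= edges[-1]:
        return f">={edges[-1]:g}"
    i = int(np.searchsorted(edges, sa, side="right")) - 1
    return f"[{edges[i]:g},{edges[i + 1]:g})"


def classify_intervals(
    sa, config: AnomalyConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Assign interval labels and EWY flags to an SA series.

    A year is an EWY iff its SA strictly exceeds the threshold (ties at
    the threshold are not extreme).  Bins are half-open ``[lo, hi)``;
    values beyond the configured range fall into open tail bins.
    """
    cfg = config or AnomalyConfig()
    x = np.asarray(sa, dtype=float)
    edges = interval_edges(cfg)
    labels = np.array([interval_label(v, edges) for v in x], dtype=object)
    return labels, x > cfg.ewy_threshold


def diffpr(apr, baseline_mean: float) -> np.ndarray:
    """Consecutive-year precipitation difference over the baseline mean.

    ``diffPr_t = (aPr_t - aPr_{t-1}) / baseline_mean`` for t >= 2; the
    first element is NaN (undefined) and must be excluded from policy
    triggers and regressions downstream.
    """
    x = np.asarray(apr, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 years for consecutive differences")
    if baseline_mean <= 0:
        raise ValueError("baseline_mean must be positive")
    out = np.empty_like(x)
    out[0] = np.nan
    out[1:] = np.diff(x) / baseline_mean
    return out


def compute_anomalies(
    records_or_climate: pd.DataFrame,
    config: AnomalyConfig | None = None,
    baselines: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-FPU anomaly table from a record or climate table.

    Expects columns ``fpu_id``, ``year``, ``aPr`` (duplicate rows per
    crop are collapsed to unique FPU-years first).  ``baselines`` maps
    fpu_id to externally supplied (mean, sd) — pass the historical
    baselines when standardizing a future period.

    Returns one row per FPU-year with columns ``sa``, ``interval``,
    ``ewy``, ``diffpr``, ``baseline_mean``, ``baseline_sd``.
    """
    cfg = config or AnomalyConfig()
    cols = {"fpu_id", "year", "aPr"}
    if not cols.issubset(records_or_climate.columns):
        raise ValueError(f"input must contain columns {sorted(cols)}")
    uniq = (
        records_or_climate[["fpu_id", "year", "aPr"]]
        .drop_duplicates(["fpu_id", "year"])
        .sort_values(["fpu_id", "year"], kind="mergesort")
    )
    frames = []
    for fpu_id, grp in uniq.groupby("fpu_id", sort=True):
        apr = grp["aPr"].to_numpy()
        base = None if baselines is None else baselines.get(fpu_id)
        sa, (mean, sd) = standardized_anomaly(apr, baseline=base, ddof=cfg.sd_ddof)
        labels, ewy = classify_intervals(sa, cfg)
        prof = AnomalyProfile(
            fpu_id=str(fpu_id),
            baseline_mean=mean,
            baseline_sd=sd,
            years=grp["year"].to_numpy(),
            sa=sa,
            interval=labels,
            ewy=ewy,
            diffpr=diffpr(apr, mean),
        )
        frames.append(prof.to_frame())
    return pd.concat(frames, ignore_index=True)
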