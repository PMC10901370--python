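"""Extreme nitrogen-loss statistics.

Summaries of aquatic N loss (nw, kg N/ha/yr) conditioned on
precipitation-anomaly intervals: interval-wise relative changes, the
extreme-loss statistic (mean relative change during extremely wet
years), percentile-bootstrap confidence intervals, cumulative excess
curves across spatial units, the EWY share of total loss, and
cropland-area-weighted aggregation with a smallest-units exclusion
rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "UndefinedRatioError",
    "ExtremeSummary",
    "interval_relative_changes",
    "extreme_nw",
    "extreme_summaries",
    "bootstrap_ci",
    "interval_table",
    "cumulative_curve",
    "area_weighted_mean",
    "ewy_share_of_total",
    "exclude_smallest_fpus",
]

UNIT_KEYS = ["fpu_id", "crop", "irrigated"]


class UndefinedRatioError(ValueError):
    """A relative change is requested against a zero long-term mean."""


@dataclass
class ExtremeSummary:
    """Extreme-loss summary for one FPU x crop x irrigation unit.

    ``extreme_nw_pct`` is the relative change (%) of the mean loss over
    EWY years versus the unit's long-term mean loss; it is 0 exactly
    when the unit has no EWYs.  ``ewy_mean_nw`` is NaN in that case.
    """

    fpu_id: str
    crop: str
    irrigated: bool
    longterm_mean_nw: float
    n_ewy: int
    extreme_nw_pct: float
    ewy_mean_nw: float
    ci_low: float
    ci_high: float
    mean_diffpr_ewy: float


def _merged(records: pd.DataFrame, anomalies: pd.DataFrame) -> pd.DataFrame:
    keep = ["fpu_id", "year", "sa", "interval", "ewy", "diffpr"]
    return records.merge(anomalies[keep], on=["fpu_id", "year"], how="left")


def interval_relative_changes(
    records: pd.DataFrame, anomalies: pd.DataFrame
) -> pd.Series:
    """Mean relative nw change (%) per precipitation-anomaly interval.

    Each FPU-year's nw is first expressed relative to its own unit's
    long-term mean, ``100 * (nw - mean) / mean``, then averaged within
    each occupied interval (pooled across units).  Bins with no years
    are absent from the result.
    """
    m = _merged(records, anomalies)
    means = m.groupby(UNIT_KEYS)["nw"].transform("mean")
    if (means <= 0).any():
        raise UndefinedRatioError("a unit has zero long-term mean nw")
    rel = 100.0 * (m["nw"] - means) / means
    return rel.groupby(m["interval"]).mean()


def _unit_extreme(nw: np.ndarray, ewy: np.ndarray) -> tuple[float, int, float, float]:
    """(extreme_pct, n_ewy, longterm_mean, ewy_mean) for one unit."""
    longterm = float(np.mean(nw))
    n_ewy = int(np.sum(ewy))
    if n_ewy == 0:
        return 0.0, 0, longterm, float("nan")
    if longterm <= 0:
        raise UndefinedRatioError("zero long-term mean nw")
    ewy_mean = float(np.mean(nw[ewy]))
    return 100.0 * (ewy_mean - longterm) / longterm, n_ewy, longterm, ewy_mean


def extreme_nw(
    records: pd.DataFrame,
    anomalies: pd.DataFrame,
    n_boot: int = 1000,
    level: float = 95.0,
    seed=0,
) -> ExtremeSummary:
    """Extreme-loss summary for a single-unit record table.

    The unit's nw over its EWY years is averaged and expressed as a
    relative change from the long-term mean; units without EWYs get 0
    by convention.  The bootstrap CI resamples the per-EWY-year
    relative changes; with no EWYs the interval is (0, 0).
    """
    units = records[UNIT_KEYS].drop_duplicates()
    if len(units) != 1:
        raise ValueError("extreme_nw expects records for exactly one unit")
    m = _merged(records, anomalies).sort_values("year")
    nw = m["nw"].to_numpy(dtype=float)
    ewy = m["ewy"].to_numpy(dtype=bool)
    pct, n_ewy, longterm, ewy_mean = _unit_extreme(nw, ewy)
    dpr = m["diffpr"].to_numpy(dtype=float)
    if n_ewy:
        rel = 100.0 * (nw[ewy] - longterm) / longterm
        lo, hi = bootstrap_ci(rel, n_boot=n_boot, level=level, seed=seed)
        mean_dpr = float(np.nanmean(dpr[ewy])) if np.any(~np.isnan(dpr[ewy])) else float("nan")
    else:
        lo = hi = 0.0
        mean_dpr = float("nan")
    row = units.iloc[0]
    return ExtremeSummary(
        fpu_id=str(row["fpu_id"]),
        crop=str(row["crop"]),
        irrigated=bool(row["irrigated"]),
        longterm_mean_nw=longterm,
        n_ewy=n_ewy,
        extreme_nw_pct=pct,
        ewy_mean_nw=ewy_mean,
        ci_low=lo,
        ci_high=hi,
        mean_diffpr_ewy=mean_dpr,
    )


def extreme_summaries(
    records: pd.DataFrame,
    anomalies: pd.DataFrame,
    n_boot: int = 1000,
    level: float = 95.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Extreme-loss summaries for every FPU x crop x irrigation unit."""
    rows = []
    for i, (key, grp) in enumerate(records.groupby(UNIT_KEYS, sort=True)):
        s = extreme_nw(
            grp,
            anomalies,
            n_boot=n_boot,
            level=level,
            seed=np.random.SeedSequence([int(seed), i]),
        )
        rows.append(vars(s))
    return pd.DataFrame(rows)


def bootstrap_ci(
    values, n_boot: int = 1000, level: float = 95.0, seed=0
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean.

    Resamples ``values`` with replacement ``n_boot`` times and returns
    the central ``level``% percentile interval of the resampled means.
    Deterministic given ``seed``; a single value yields (v, v).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("bootstrap_ci needs at least one value")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(int(n_boot), x.size))
    means = x[idx].mean(axis=1)
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(means, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def interval_table(
    records: pd.DataFrame,
    anomalies: pd.DataFrame,
    n_boot: int = 1000,
    level: float = 95.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Pooled per-interval relative changes with bootstrap CIs.

    One row per occupied interval: the mean relative nw change across
    all FPU-year combinations in the bin, its bootstrap CI, and the
    number of FPU-years (pooling mirrors how interval bar charts are
    built from many units).
    """
    m = _merged(records, anomalies)
    means = m.groupby(UNIT_KEYS)["nw"].transform("mean")
    if (means <= 0).any():
        raise UndefinedRatioError("a unit has zero long-term mean nw")
    rel = 100.0 * (m["nw"] - means) / means
    rows = []
    for i, (label, vals) in enumerate(rel.groupby(m["interval"])):
        lo, hi = bootstrap_ci(
            vals.to_numpy(), n_boot=n_boot, level=level,
            seed=np.random.SeedSequence([int(seed), i]),
        )
        rows.append(
            {
                "interval": label,
                "mean_change_pct": float(vals.mean()),
                "ci_low": lo,
                "ci_high": hi,
                "n": int(len(vals)),
            }
        )
    out = pd.DataFrame(rows)
    # order bins by their lower edge (tails first/last)
    def _key(lbl: str) -> float:
        if lbl.startswith("<"):
            return -np.inf
        if lbl.startswith(">="):
            return np.inf
        return float(lbl[1:].split(",")[0])

    return out.sort_values("interval", key=lambda s: s.map(_key)).reset_index(drop=True)


def cumulative_curve(
    summaries: pd.DataFrame, weighted: bool = True
) -> pd.DataFrame:
    """Cumulative extreme-loss excess across units, ascending.

    Units are sorted by their absolute EWY excess (mean EWY nw minus
    long-term mean nw, kg N/ha; 0 for units without EWYs).  The curve
    value at position k is the running area-weighted excess as a
    percentage of the running area-weighted long-term mean:

        100 * sum_k area*excess / sum_k area*longterm_mean

    With ``weighted=False`` all areas are treated as equal.  The
    endpoint is the overall excess of extreme over average loss.
    """
    if len(summaries) == 0:
        raise ValueError("need at least one unit")
    df = summaries.copy()
    excess = np.where(
        df["n_ewy"].to_numpy() > 0,
        df["ewy_mean_nw"].to_numpy() - df["longterm_mean_nw"].to_numpy(),
        0.0,
    )
    df["excess"] = excess
    df = df.sort_values("excess", kind="mergesort").reset_index(drop=True)
    if weighted and "cropland_area" not in df.columns:
        raise ValueError("weighted curve needs a cropland_area column")
    w = df["cropland_area"].to_numpy(dtype=float) if weighted else np.ones(len(df))
    num = np.cumsum(w * df["excess"].to_numpy())
    den = np.cumsum(w * df["longterm_mean_nw"].to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        df["cumulative_pct"] = 100.0 * num / den
    return df


def area_weighted_mean(values, areas) -> float:
    """Cropland-area-weighted mean: sum(v*a) / sum(a)."""
    v = np.asarray(values, dtype=float)
    a = np.asarray(areas, dtype=float)
    if v.shape != a.shape:
        raise ValueError("values and areas must have equal length")
    if np.any(a < 0):
        raise ValueError("areas must be nonnegative")
    total = a.sum()
    if total == 0:
        raise ValueError("areas must not all be zero")
    return float((v * a).sum() / total)


def ewy_share_of_total(records: pd.DataFrame, anomalies: pd.DataFrame) -> float:
    """Percentage of cumulative nw that falls in EWY years."""
    m = _merged(records, anomalies)
    total = m["nw"].sum()
    if total <= 0:
        raise UndefinedRatioError("total nw must be positive")
    return float(100.0 * m.loc[m["ewy"].astype(bool), "nw"].sum() / total)


def exclude_smallest_fpus(profiles, fraction: float = 0.0005):
    """Drop the smallest-area FPUs up to a cumulative area fraction.

    Units are considered smallest-first; a unit is dropped while the
    cumulative area of dropped units stays <= ``fraction`` of the total.
    Row order of the input does not affect the retained set.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    if fraction == 0.0:
        return list(profiles)
    prof = list(profiles)
    areas = np.array([p.cropland_area for p in prof])
    order = np.argsort(areas, kind="mergesort")
    budget = fraction * areas.sum()
    dropped: set[int] = set()
    cum = 0.0
    for i in order:
        if cum + areas[i] > budget:
            break
        cum += areas[i]
        dropped.add(int(i))
    return [p for i, p in enumerate(prof) if i not in dropped]
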