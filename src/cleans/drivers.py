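"""Cross-unit screening of extreme-loss drivers.

Assembles one row per FPU x crop x irrigation unit (units without any
extremely wet year are excluded — their extreme-loss statistic is 0 by
convention and carries no driver signal) with twelve candidate
drivers: long-term mean climate (aPr, gsPr, ferPr, aT, gsT), the
consecutive-year precipitation difference diffPr averaged over EWY
years, management (N_in), soils (BD, CF, SDC, STC), and long-term mean
yield.  Screening is by per-driver correlation with the extreme-loss
percentage and by ordinary least squares across units.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DataError",
    "CollinearityError",
    "DRIVER_COLUMNS",
    "build_driver_table",
    "correlate_drivers",
    "regress_drivers",
    "diffpr_anomaly_relation",
]


class DataError(ValueError):
    """Required columns or join keys are missing."""


class CollinearityError(ValueError):
    """The regression design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"collinear or constant columns: {self.columns}")


DRIVER_COLUMNS = [
    "aPr",
    "N_in",
    "BD",
    "diffPr",
    "gsPr",
    "ferPr",
    "aT",
    "gsT",
    "yield",
    "CF",
    "SDC",
    "STC",
]

RESPONSE = "extreme_nw_pct"


def build_driver_table(
    summaries: pd.DataFrame,
    records: pd.DataFrame,
    profiles_frame: pd.DataFrame,
) -> pd.DataFrame:
    """One row per unit with the extreme-loss response and 12 drivers.

    Climate, N input and yield enter as long-term unit means; diffPr as
    its mean over the unit's EWY years (taken from the summaries); soil
    properties are copied from the FPU profile.  Units with no EWYs are
    dropped.
    """
    need = {"fpu_id", "crop", "irrigated", RESPONSE, "n_ewy", "mean_diffpr_ewy"}
    if not need.issubset(summaries.columns):
        raise DataError(f"summaries missing {sorted(need - set(summaries.columns))}")
    keys = ["fpu_id", "crop", "irrigated"]
    longterm = (
        records.groupby(keys)[["aPr", "gsPr", "ferPr", "aT", "gsT", "nin", "yield"]]
        .mean()
        .rename(columns={"nin": "N_in"})
        .reset_index()
    )
    soil_cols = ["fpu_id", "BD", "CF", "SDC", "STC"]
    if not set(soil_cols).issubset(profiles_frame.columns):
        raise DataError("profiles frame missing soil columns")
    tab = (
        summaries.loc[summaries["n_ewy"] > 0, keys + [RESPONSE, "mean_diffpr_ewy"]]
        .rename(columns={"mean_diffpr_ewy": "diffPr"})
        .merge(longterm, on=keys, how="left", validate="one_to_one")
        .merge(profiles_frame[soil_cols], on="fpu_id", how="left")
    )
    if tab[["aPr", "BD"]].isna().any().any():
        raise DataError("join keys missing between summaries, records and profiles")
    # a unit whose only EWY is the first recorded year has no defined
    # diffPr there; such units carry no diffPr signal and are dropped
    tab = tab[tab["diffPr"].notna()].reset_index(drop=True)
    return tab[keys + [RESPONSE] + DRIVER_COLUMNS]


def correlate_drivers(
    table: pd.DataFrame,
    alpha: float = 0.05,
    drivers=None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-driver correlation with the extreme-loss percentage.

    Returns a frame with columns ``driver``, ``r``, ``p``,
    ``significant`` (p < alpha).  Constant drivers give NaN r/p and are
    never significant.  ``method`` is "pearson" (default) or
    "spearman".
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows to correlate")
    drivers = list(drivers) if drivers is not None else DRIVER_COLUMNS
    y = table[RESPONSE].to_numpy(dtype=float)
    rows = []
    for d in drivers:
        x = table[d].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        xv, yv = x[ok], y[ok]
        if xv.size < 3 or np.std(xv) == 0 or np.std(yv) == 0:
            r, p = np.nan, np.nan
        elif method == "pearson":
            r, p = stats.pearsonr(xv, yv)
        elif method == "spearman":
            r, p = stats.spearmanr(xv, yv)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(
            {
                "driver": d,
                "r": float(r),
                "p": float(p),
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(rows)


def regress_drivers(table: pd.DataFrame, drivers=None):
    """OLS of the extreme-loss percentage on a driver subset.

    Fits with an intercept and returns the statsmodels results object
    (coefficients, standard errors, R-squared).  A rank-deficient
    design raises :class:`CollinearityError` naming the offending
    columns.
    """
    drivers = list(drivers) if drivers is not None else DRIVER_COLUMNS
    if len(table) <= len(drivers) + 1:
        raise ValueError("need more rows than predictors + 1")
    X = table[drivers].to_numpy(dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        # name columns whose removal restores full rank
        bad = []
        for j, name in enumerate(drivers):
            others = np.delete(Xc, j + 1, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(Xc):
                bad.append(name)
        raise CollinearityError(bad or drivers)
    model = sm.OLS(table[RESPONSE].to_numpy(dtype=float), Xc)
    res = model.fit()
    res.driver_names = ["const"] + drivers
    return res


def diffpr_anomaly_relation(anomalies: pd.DataFrame) -> tuple[float, float]:
    """Correlations of diffPr with current- and previous-year anomalies.

    Pools all FPU-years with a defined diffPr and returns
    ``(corr(diffPr_t, SA_t), corr(diffPr_t, SA_{t-1}))``.  For
    independent annual precipitation both approach +/- 1/sqrt(2): a wet
    current year raises diffPr, a wet previous year lowers it.
    """
    need = {"fpu_id", "year", "sa", "diffpr"}
    if not need.issubset(anomalies.columns):
        raise DataError(f"anomalies missing {sorted(need - set(anomalies.columns))}")
    df = anomalies.sort_values(["fpu_id", "year"]).copy()
    df["sa_prev"] = df.groupby("fpu_id")["sa"].shift(1)
    ok = df["diffpr"].notna() & df["sa_prev"].notna()
    d = df.loc[ok]
    if len(d) < 3:
        raise ValueError("need at least 3 defined diffPr years")
    r_cur, _ = stats.pearsonr(d["diffpr"], d["sa"])
    r_prev, _ = stats.pearsonr(d["diffpr"], d["sa_prev"])
    return float(r_cur), float(r_prev)
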