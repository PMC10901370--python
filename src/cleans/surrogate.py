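"""Random-forest surrogate of the agroecosystem emulator.

One forest per crop per response (aquatic N loss and yield), trained
on FPU-crop-year rows following a fixed protocol: feature assembly
(growing-season precipitation/temperature excluded as near-duplicates
of their annual counterparts; binary indicators for irrigation and for
extremely wet years), univariate chi-square outlier removal on the
standardized response, a seeded 80/20 split, 10-fold cross-validated
grid search over ``mtry`` (features per split) and ``ntree`` (forest
size) minimizing RMSE, and holdout evaluation.  The fitted surrogate
predicts loss and yield for counterfactual nitrogen inputs inside the
policy optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .config import SurrogateConfig

__all__ = [
    "PREDICTORS",
    "RESPONSES",
    "FeatureMatrix",
    "SurrogateModel",
    "prepare_features",
    "remove_outliers",
    "split_data",
    "tune_and_fit",
    "evaluate",
    "partial_dependence",
    "fit_crop_surrogates",
]

PREDICTORS = [
    "aPr",
    "ferPr",
    "aT",
    "diffPr",
    "N_in",
    "BD",
    "CF",
    "SDC",
    "STC",
    "IRRF",
    "Extreme",
]
RESPONSES = ["nw", "yield"]
KEY_COLUMNS = ["fpu_id", "year", "crop"]


@dataclass
class FeatureMatrix:
    """Feature rows (FPU-crop-year) with predictors and responses."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(PREDICTORS + RESPONSES) - set(self.data.columns)
        if missing:
            raise ValueError(f"feature matrix missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def predictors(self) -> list[str]:
        """Active predictor columns (growing-season ones when present)."""
        extra = [c for c in ("gsPr", "gsT") if c in self.data.columns]
        return PREDICTORS + extra

    def for_crop(self, crop: str) -> "FeatureMatrix":
        return FeatureMatrix(self.data[self.data["crop"] == crop].reset_index(drop=True))


@dataclass
class SurrogateModel:
    """A tuned forest for one crop and one response, with diagnostics."""

    crop: str
    response: str
    forest: RandomForestRegressor
    mtry: int
    ntree: int
    cv_table: pd.DataFrame  # columns mtry, ntree, cv_rmse
    train_X: np.ndarray = field(repr=False)
    feature_names: list[str] = field(default_factory=lambda: list(PREDICTORS))

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        return self.forest.predict(X)


def prepare_features(
    records: pd.DataFrame,
    anomalies: pd.DataFrame,
    profiles_frame: pd.DataFrame,
    config: SurrogateConfig | None = None,
) -> FeatureMatrix:
    """Assemble the surrogate training matrix from annual records.

    Joins anomaly flags and soil properties onto the records, encodes
    ``IRRF`` (1 irrigated / 0 rainfed) and ``Extreme`` (1 EWY / 0
    other), drops first years (undefined diffPr), and — by default —
    leaves growing-season precipitation and temperature out of the
    predictor set.
    """
    cfg = config or SurrogateConfig()
    m = records.merge(
        anomalies[["fpu_id", "year", "sa", "ewy", "diffpr"]],
        on=["fpu_id", "year"],
        how="left",
    ).merge(profiles_frame[["fpu_id", "BD", "CF", "SDC", "STC"]], on="fpu_id", how="left")
    if m[["sa", "BD"]].isna().all().any():
        raise ValueError("records failed to join anomalies or profiles")
    m = m[m["diffpr"].notna()].reset_index(drop=True)
    m["IRRF"] = m["irrigated"].astype(int)
    m["Extreme"] = m["ewy"].astype(int)
    m = m.rename(columns={"nin": "N_in", "diffpr": "diffPr"})
    cols = KEY_COLUMNS + PREDICTORS + RESPONSES
    if not cfg.exclude_growing_season:
        cols = cols + ["gsPr", "gsT"]
    return FeatureMatrix(m[cols].copy())


def remove_outliers(
    matrix: FeatureMatrix, response: str, alpha: float = 0.001
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Chi-square outlier filter on the standardized response.

    Rows whose squared standardized response exceeds the upper-alpha
    quantile of chi-square(1) are removed.  A zero-variance response
    removes nothing, as does ``alpha = 0``.  Returns the filtered
    matrix and a log of removed rows (keys plus the test statistic).
    """
    if response not in RESPONSES:
        raise ValueError(f"unknown response {response!r}")
    df = matrix.data
    if len(df) < 10:
        raise ValueError("need at least 10 rows for outlier screening")
    y = df[response].to_numpy(dtype=float)
    sd = y.std()
    if alpha <= 0 or sd == 0:
        return matrix, df.iloc[0:0][KEY_COLUMNS].assign(statistic=[])
    z2 = ((y - y.mean()) / sd) ** 2
    cut = stats.chi2.ppf(1.0 - alpha, df=1)
    drop = z2 > cut
    log = df.loc[drop, KEY_COLUMNS].assign(statistic=z2[drop])
    return FeatureMatrix(df.loc[~drop].reset_index(drop=True)), log


def split_data(
    matrix: FeatureMatrix, train_frac: float = 0.8, seed=0
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Seeded random train/test split (disjoint and exhaustive)."""
    df = matrix.data
    if len(df) < 5:
        raise ValueError("need at least 5 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(df))
    n_train = int(round(train_frac * len(df)))
    train = df.iloc[np.sort(perm[:n_train])].reset_index(drop=True)
    test = df.iloc[np.sort(perm[n_train:])].reset_index(drop=True)
    return FeatureMatrix(train), FeatureMatrix(test)


def _make_forest(mtry: int, ntree: int, seed: int, n_features: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=int(ntree),
        max_features=min(int(mtry), n_features),
        random_state=int(seed),
        n_jobs=1,
    )


def tune_and_fit(
    train: FeatureMatrix,
    response: str,
    grid: list[tuple[int, int]] | None = None,
    k: int = 10,
    seed: int = 0,
    crop: str = "",
    config: SurrogateConfig | None = None,
) -> SurrogateModel:
    """Cross-validated grid search over (mtry, ntree), then refit.

    For every grid point the mean RMSE over ``k`` folds is recorded;
    the point with the smallest mean RMSE wins (ties broken toward the
    smaller ntree, then smaller mtry — the cheaper model).  The
    returned model is refit on the full training set.
    """
    cfg = config or SurrogateConfig()
    if grid is None:
        grid = [(m, n) for m in cfg.mtry_grid for n in cfg.ntree_grid]
    if not grid:
        raise ValueError("hyperparameter grid must be nonempty")
    df = train.data
    if len(df) < k:
        raise ValueError("training rows must be >= number of folds")
    features = train.predictors
    X = df[features].to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)

    ss = np.random.SeedSequence([int(seed), 0])
    fold_seed = int(ss.generate_state(1)[0] % (2**31))
    kf = KFold(n_splits=k, shuffle=True, random_state=fold_seed)
    folds = list(kf.split(X))

    rows = []
    for gi, (mtry, ntree) in enumerate(grid):
        errs = []
        for tr, va in folds:
            f = _make_forest(mtry, ntree, seed=fold_seed + gi, n_features=X.shape[1])
            f.fit(X[tr], y[tr])
            pred = f.predict(X[va])
            errs.append(float(np.sqrt(np.mean((pred - y[va]) ** 2))))
        rows.append({"mtry": mtry, "ntree": ntree, "cv_rmse": float(np.mean(errs))})
    cv = pd.DataFrame(rows)
    best = cv.sort_values(["cv_rmse", "ntree", "mtry"], kind="mergesort").iloc[0]
    forest = _make_forest(int(best["mtry"]), int(best["ntree"]), seed=fold_seed, n_features=X.shape[1])
    forest.fit(X, y)
    return SurrogateModel(
        crop=crop,
        response=response,
        forest=forest,
        mtry=int(best["mtry"]),
        ntree=int(best["ntree"]),
        cv_table=cv,
        train_X=X,
        feature_names=list(features),
    )


def evaluate(model: SurrogateModel, test: FeatureMatrix) -> dict[str, float]:
    """Holdout R-squared (1 - SSE/SST) and RMSE for one model."""
    df = test.data
    if len(df) == 0:
        raise ValueError("test set must be nonempty")
    y = df[model.response].to_numpy(dtype=float)
    pred = model.predict(df)
    sse = float(np.sum((y - pred) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = float("nan") if sst == 0 else 1.0 - sse / sst
    rmse = float(np.sqrt(sse / len(y)))
    return {"r2": r2, "rmse": rmse}


def partial_dependence(
    model: SurrogateModel, feature: str, grid_points: int = 20
) -> pd.DataFrame:
    """One-dimensional partial dependence over the training rows.

    The feature is swept over an even grid spanning its observed
    training range; at each value the model predicts for every
    training row with only that feature replaced, and the predictions
    are averaged.
    """
    if feature not in model.feature_names:
        raise ValueError(f"unknown feature {feature!r}")
    j = model.feature_names.index(feature)
    col = model.train_X[:, j]
    grid = np.linspace(col.min(), col.max(), int(grid_points))
    X = model.train_X.copy()
    means = np.empty(grid.size)
    for i, v in enumerate(grid):
        X[:, j] = v
        means[i] = float(model.forest.predict(X).mean())
    return pd.DataFrame({feature: grid, "mean_prediction": means})


def fit_crop_surrogates(
    matrix: FeatureMatrix,
    crops,
    config: SurrogateConfig | None = None,
    split_seed: int = 0,
    cv_seed: int = 0,
) -> tuple[dict[tuple[str, str], SurrogateModel], pd.DataFrame]:
    """Full protocol per crop and response; returns models and metrics.

    For each crop: split 80/20, then per response filter outliers in
    train and test independently, tune, fit, and evaluate on the
    holdout.  Metrics frame has one row per (crop, response).
    """
    cfg = config or SurrogateConfig()
    models: dict[tuple[str, str], SurrogateModel] = {}
    rows = []
    for ci, crop in enumerate(crops):
        sub = matrix.for_crop(crop)
        train, test = split_data(
            sub, cfg.train_frac, seed=np.random.SeedSequence([int(split_seed), ci])
        )
        for response in RESPONSES:
            tr, _ = remove_outliers(train, response, cfg.outlier_alpha)
            te, _ = remove_outliers(test, response, cfg.outlier_alpha)
            model = tune_and_fit(
                tr,
                response,
                k=cfg.k_folds,
                seed=int(np.random.SeedSequence([int(cv_seed), ci]).generate_state(1)[0] % (2**31)),
                crop=crop,
                config=cfg,
            )
            met = evaluate(model, te)
            models[(crop, response)] = model
            rows.append(
                {
                    "crop": crop,
                    "response": response,
                    "mtry": model.mtry,
                    "ntree": model.ntree,
                    "r2": met["r2"],
                    "rmse": met["rmse"],
                    "n_train": len(tr),
                    "n_test": len(te),
                }
            )
    return models, pd.DataFrame(rows)
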