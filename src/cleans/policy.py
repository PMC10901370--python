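"""Adaptive nitrogen-input scaling (the CLEANS strategy).

The policy is a pair (diffPr threshold, N-input scaling ratio): in any
year whose consecutive-year precipitation difference diffPr strictly
exceeds the threshold, nitrogen input is multiplied by the ratio;
other years are untouched.  High-diffPr years are wet years following
drier ones — exactly when the soil still holds residual N from the dry
year, so input can be cut with little yield cost while the loss pulse
shrinks.

Policies are evaluated against a predictor of the counterfactual: the
emulator itself re-run with the modified input series and identical
noise draws (the ground truth here), or a fitted random-forest
surrogate.  The optimizer scans a (threshold x ratio) grid
exhaustively and returns the feasible policy with the largest
extreme-loss reduction, subject to strict caps on long-term yield loss
and N-input reduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

from .config import CleansConfig, EmulatorParams
from .surrogate import SurrogateModel
from .synthetic import ClimateSeries, FPUProfile, simulate_agroecosystem

__all__ = [
    "CleansPolicy",
    "PolicyEvaluation",
    "apply_policy",
    "EmulatorPredictor",
    "SurrogatePredictor",
    "evaluate_policy",
    "optimize_policy",
    "constraint_sweep",
]


@dataclass(frozen=True)
class CleansPolicy:
    """A (diffPr threshold, N-input scaling ratio) pair."""

    threshold: float
    ratio: float

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio <= 1.0:
            raise ValueError("ratio must lie in (0, 1]")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


@dataclass
class PolicyEvaluation:
    """Effects of one policy on one FPU x crop unit.

    Deltas are percentages relative to the unmitigated run:
    ``d_extreme_nw`` on the mean loss over EWY years, ``d_nin`` on the
    long-term mean N input (always <= 0), ``d_yield`` on the long-term
    mean yield.  ``extreme_pct_base``/``extreme_pct_mit`` give the
    extreme-loss statistic (relative change of EWY-mean loss versus the
    unmitigated long-term mean) before and after mitigation.
    """

    policy: CleansPolicy
    d_extreme_nw: float
    d_nin: float
    d_yield: float
    extreme_pct_base: float
    extreme_pct_mit: float
    n_triggered: int
    feasible: bool


def apply_policy(nin, diffpr, policy: CleansPolicy) -> np.ndarray:
    """Scale N input in years with diffPr strictly above the threshold.

    Years with undefined (NaN) diffPr — the first year of a series —
    never trigger.
    """
    nin = np.asarray(nin, dtype=float)
    dpr = np.asarray(diffpr, dtype=float)
    if nin.shape != dpr.shape:
        raise ValueError("nin and diffpr must be aligned")
    trigger = np.zeros(nin.shape, dtype=bool)
    defined = ~np.isnan(dpr)
    trigger[defined] = dpr[defined] > policy.threshold
    out = nin.copy()
    out[trigger] = policy.ratio * out[trigger]
    return out


class Predictor(Protocol):
    """Maps a counterfactual N-input series to per-year (nw, yield)."""

    def __call__(self, nin: np.ndarray) -> tuple[np.ndarray, np.ndarray]: ...


@dataclass
class EmulatorPredictor:
    """Counterfactual prediction by re-running the emulator.

    Re-simulates one FPU x crop with the modified input series under
    the *same* seed, so noise draws match the baseline run and the
    only difference is the policy.  This is the ground-truth oracle.
    """

    profile: FPUProfile
    climate: ClimateSeries
    params: EmulatorParams
    seed: object
    crop: str
    burn_in: int = 0
    reference_precip: float | None = None

    def __call__(self, nin: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        full = np.asarray(nin, dtype=float)
        if self.burn_in:
            # burn-in years keep the baseline input (policy acts on the
            # analysis period only)
            pad = np.full(self.burn_in, full[0])
            full = np.concatenate([pad, full])
        rec = simulate_agroecosystem(
            self.profile,
            self.climate,
            full,
            self.params,
            self.seed,
            crop=self.crop,
            burn_in=self.burn_in,
            reference_precip=self.reference_precip,
        )
        return rec["nw"].to_numpy(), rec["yield"].to_numpy()


@dataclass
class SurrogatePredictor:
    """Counterfactual prediction through fitted random forests.

    ``features`` holds one row per analysis year of the unit, with the
    surrogate's predictor columns; only ``N_in`` is replaced by the
    policy-modified series.
    """

    nw_model: SurrogateModel
    yield_model: SurrogateModel
    features: pd.DataFrame

    def __call__(self, nin: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = self.features.copy()
        if len(X) != len(nin):
            raise ValueError("feature rows must align with the nin series")
        X["N_in"] = np.asarray(nin, dtype=float)
        return self.nw_model.predict(X), self.yield_model.predict(X)


def evaluate_policy(
    policy: CleansPolicy,
    predictor: Callable,
    nin: np.ndarray,
    diffpr: np.ndarray,
    ewy: np.ndarray,
    config: CleansConfig | None = None,
    baseline_nw: np.ndarray | None = None,
    baseline_yield: np.ndarray | None = None,
    forecast_rng=None,
) -> PolicyEvaluation:
    """Evaluate one policy for one unit against a predictor.

    The baseline (unmitigated) nw/yield series are taken from the
    predictor at the unmodified input unless supplied.  The extreme
    statistic is recomputed over the *same* EWY year set, against the
    unmitigated long-term mean, so the delta isolates the policy
    effect.  Feasibility uses strict caps on yield loss and input
    reduction (percent).
    """
    cfg = config or CleansConfig()
    nin = np.asarray(nin, dtype=float)
    dpr = np.asarray(diffpr, dtype=float)
    if cfg.forecast_noise_sd > 0:
        rng = forecast_rng if forecast_rng is not None else np.random.default_rng(0)
        noisy = dpr + rng.normal(0.0, cfg.forecast_noise_sd, size=dpr.shape)
        noisy[np.isnan(dpr)] = np.nan
        dpr_for_trigger = noisy
    else:
        dpr_for_trigger = dpr
    ewy = np.asarray(ewy, dtype=bool)

    if baseline_nw is None or baseline_yield is None:
        baseline_nw, baseline_yield = predictor(nin)
    new_nin = apply_policy(nin, dpr_for_trigger, policy)
    n_triggered = int(np.sum(new_nin != nin))
    if n_triggered == 0:
        base_pct = _extreme_pct(baseline_nw, ewy, float(np.mean(baseline_nw)))
        return PolicyEvaluation(
            policy, 0.0, 0.0, 0.0, base_pct, base_pct, 0, True
        )

    mit_nw, mit_yield = predictor(new_nin)

    base_longterm = float(np.mean(baseline_nw))
    base_pct = _extreme_pct(baseline_nw, ewy, base_longterm)
    mit_pct = _extreme_pct(mit_nw, ewy, base_longterm)

    n_ewy = int(np.sum(ewy))
    if n_ewy > 0 and float(np.mean(baseline_nw[ewy])) > 0:
        d_extreme = 100.0 * (
            float(np.mean(mit_nw[ewy])) - float(np.mean(baseline_nw[ewy]))
        ) / float(np.mean(baseline_nw[ewy]))
    else:
        d_extreme = 0.0
    d_nin = 100.0 * (new_nin.mean() - nin.mean()) / nin.mean() if nin.mean() > 0 else 0.0
    by = float(np.mean(baseline_yield))
    d_yield = 100.0 * (float(np.mean(mit_yield)) - by) / by if by > 0 else 0.0

    feasible = (d_yield > -cfg.max_yield_loss) and (d_nin > -cfg.max_nin_reduction)
    return PolicyEvaluation(
        policy, d_extreme, d_nin, d_yield, base_pct, mit_pct, n_triggered, feasible
    )


def _extreme_pct(nw: np.ndarray, ewy: np.ndarray, longterm: float) -> float:
    if not np.any(ewy) or longterm <= 0:
        return 0.0
    return 100.0 * (float(np.mean(nw[ewy])) - longterm) / longterm


def optimize_policy(
    predictor: Callable,
    nin: np.ndarray,
    diffpr: np.ndarray,
    ewy: np.ndarray,
    config: CleansConfig | None = None,
) -> tuple[PolicyEvaluation | None, list[PolicyEvaluation]]:
    """Exhaustive grid search for the best feasible policy of one unit.

    Every (threshold, ratio) combination in the configured grid is
    evaluated; among feasible ones the policy minimizing
    ``d_extreme_nw`` (the largest extreme-loss reduction) wins, with
    ties broken toward the larger ratio, then the larger threshold
    (the least intervention).  Returns ``(best, all_evaluations)``;
    ``best`` is None when no policy is feasible.
    """
    cfg = config or CleansConfig()
    if cfg.max_yield_loss < 0 or cfg.max_nin_reduction < 0:
        raise ValueError("constraint caps must be nonnegative")
    if not cfg.thresholds or not cfg.ratios:
        raise ValueError("policy grid must be nonempty")
    nin = np.asarray(nin, dtype=float)
    baseline_nw, baseline_yield = predictor(nin)
    evals = []
    for th in cfg.thresholds:
        for ratio in cfg.ratios:
            evals.append(
                evaluate_policy(
                    CleansPolicy(threshold=float(th), ratio=float(ratio)),
                    predictor,
                    nin,
                    diffpr,
                    ewy,
                    cfg,
                    baseline_nw=baseline_nw,
                    baseline_yield=baseline_yield,
                )
            )
    feasible = [e for e in evals if e.feasible]
    if not feasible:
        return None, evals
    best = min(
        feasible,
        key=lambda e: (e.d_extreme_nw, -e.policy.ratio, -e.policy.threshold),
    )
    return best, evals


def constraint_sweep(
    units: Sequence[dict],
    constraint_sets: Sequence[tuple[float, float]],
    config: CleansConfig | None = None,
) -> pd.DataFrame:
    """Optimize every unit under each (yield cap %, N-input cap %) pair.

    ``units`` is a sequence of dicts with keys ``fpu_id``, ``crop``,
    ``irrigated``, ``predictor``, ``nin``, ``diffpr``, ``ewy``.
    Returns one row per unit x constraint set with the best policy (or
    an infeasible flag) and its deltas.
    """
    import dataclasses as _dc

    cfg = config or CleansConfig()
    if not constraint_sets:
        raise ValueError("need at least one constraint set")
    rows = []
    for unit in units:
        for yield_cap, nin_cap in constraint_sets:
            c = _dc.replace(cfg, max_yield_loss=yield_cap, max_nin_reduction=nin_cap)
            best, _ = optimize_policy(
                unit["predictor"], unit["nin"], unit["diffpr"], unit["ewy"], c
            )
            row = {
                "fpu_id": unit["fpu_id"],
                "crop": unit["crop"],
                "irrigated": unit["irrigated"],
                "max_yield_loss": yield_cap,
                "max_nin_reduction": nin_cap,
                "feasible": best is not None,
            }
            if best is not None:
                row.update(
                    threshold=best.policy.threshold,
                    ratio=best.policy.ratio,
                    d_extreme_nw=best.d_extreme_nw,
                    d_nin=best.d_nin,
                    d_yield=best.d_yield,
                    extreme_pct_base=best.extreme_pct_base,
                    extreme_pct_mit=best.extreme_pct_mit,
                    n_triggered=best.n_triggered,
                )
            else:
                row.update(
                    threshold=np.nan,
                    ratio=np.nan,
                    d_extreme_nw=np.nan,
                    d_nin=np.nan,
                    d_yield=np.nan,
                    extreme_pct_base=np.nan,
                    extreme_pct_mit=np.nan,
                    n_triggered=0,
                )
            rows.append(row)
    return pd.DataFrame(rows)
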