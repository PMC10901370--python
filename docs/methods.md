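# Methods

This note documents the models and procedures implemented in `cleans`,
the choices made where the design was genuinely open, and what the
synthetic experiments can and cannot show.

## The synthetic agroecosystem

The generator replaces a process-based crop model with an annual soil
nitrogen-balance emulator per food production unit (FPU) and crop. It
is deliberately minimal: its purpose is to carry, in a controlled and
fully seeded form, the one mechanism the downstream statistics depend
on — residual mineral N accumulates in dry years and is flushed out in
a subsequent wet year.

**World.** `n_fpus` units (default 200) are sampled with mean annual
precipitation uniform over 200–2000 mm/yr, a precipitation coefficient
of variation of 0.15–0.35 that by default *decreases* with mean
precipitation (dry regions have relatively more variable rainfall —
this coupling is what makes low-precipitation units carry the largest
relative loss pulses, and it can be switched off), Gaussian-free
uniform soils (bulk density 1.1–1.6 g/cm³, coarse fragment 0–30 %,
sand 10–70 %, silt 10–60 % with sand+silt capped at 95 %), baseline N
input uniform over 50–250 kg N/ha/yr, log-uniform cropland areas
(10³–10⁶ ha) and a 50 % irrigation probability.

**Climate.** Annual precipitation is gamma-distributed with the unit's
mean and SD (positive, right-skewed; SD = 0 degenerates to a constant
series). Growing-season precipitation is 0.6 of annual and the
fertilization-window share 0.5 of that, each with 10 % multiplicative
noise, clipped so ferPr ≤ gsPr ≤ aPr always holds. Real crop calendars
are out of scope; the two fertilizer applications are not modelled
separately, only their combined window.

**Annual balance.** With residual pool `R_{t-1}`, input `N_t` and
deposition `D` (5 kg N/ha/yr), the available pool is
`A_t = R_{t-1} + N_t + D`. Relative wetness `w_t = aPr_t / mean aPr`
sets the aquatic loss fraction through a logistic
`f(w) = 1/(1+exp(−(a + b·w)))` with `a = −4`, `b = 2.5` — about 6 % of
the pool is lost at half the normal rainfall, 18 % at normal rainfall,
73 % at double. A bounded, monotone logistic was chosen over a power
law so `nw ≤ A` holds without ad-hoc clipping in the typical range.
The loss `nw_t = f(w_t)·A_t·(1+ε)` (multiplicative Gaussian noise,
SD 0.10, clipped to `[0, A_t]`) splits into leaching/runoff/erosion as
0.5/0.3/0.2 — asserted as configuration, not as a fact about any
process model. Crop uptake is
`min(uptake_max·s_t, 0.7·(A_t − nw_t))`: demand-capped
(120–170 kg N/ha by crop) and concentration-capped at a single-season
extraction efficiency of 0.7, which keeps fertilizer-N recovery below
100 % so a residual pool can build up at all. Water stress
`s_t = min(1, gsPr_t/500 mm)` applies to rainfed units only. Yield
follows a Mitscherlich curve in uptake times `s_t^0.5`, with 5 %
multiplicative noise. Of the post-season surplus, 60 %
(`carryover_retention`) becomes next year's residual; the rest leaves
as gaseous/immobilized N, closing the mass balance exactly every year.
Crops differ only by parameter sets (no phenology). A 5-year burn-in
from an empty pool is simulated and discarded so initialization
transients never enter the analysis.

Noise is drawn up-front per run from the seed, so re-simulating with a
modified input series reuses identical noise — counterfactuals isolate
the policy effect exactly.

**Future scenarios** scale the precipitation mean/SD and N-input
moments multiplicatively and regenerate the series; loss wetness stays
referenced to the *historical* mean, and anomalies of future series are
standardized against the historical baseline.

## Anomaly statistics

The standardized anomaly uses the **population SD** (divisor *n*) by
default; the divisor is configurable (`sd_ddof`). The EWY threshold is
a **strict** `SA > 2`. Interval bins are half-open `[lo, lo+0.5)` from
−2.5 to +3.5 SD with open tails; edge handling is this package's
convention. diffPr is undefined for the first year of a series rather
than imputed, and first years are excluded from driver tables, feature
matrices and policy triggers. Under a stationary Gaussian climate the
strict 2σ rule flags ≈ 2.3 % of self-standardized 30-year unit-years —
the rarity that makes EWYs "extreme".

## Extreme-loss summaries

Per unit, "extreme N_w" averages the loss over EWY years first and
applies one relative transform (not a mean of per-year ratios); units
without EWYs are set to 0 by rule. Uncertainty uses the percentile
bootstrap of the mean (1000 resamples, 95 %); BCa was not used because
nothing downstream needs second-order accuracy. The cumulative curve
sorts units by absolute EWY excess (kg N/ha) and reports the running
area-weighted excess as a percentage of the running area-weighted
long-term mean, so its endpoint is the headline "extreme losses exceed
the average by X %" figure; an unweighted mode is provided. The
smallest units totalling ≤ 0.05 % of cropland area are excluded before
aggregation.

## Driver screening

One row per FPU × crop × irrigation with at least one EWY (and a
defined diffPr there), 12 candidate drivers: long-term means of aPr,
gsPr, ferPr, aT, gsT, N input and yield; diffPr averaged over EWY
years; and the four soil properties. Pearson correlation is the
default (Spearman available); per-driver p-values are reported without
multiple-testing correction — the screen is descriptive, and this is
flagged here deliberately. The default response is the relative
extreme-loss statistic; screening against absolute changes is an
option off the default path. OLS via statsmodels, with explicit
collinearity detection naming offending columns.

## Random-forest surrogate

One forest per crop per response (loss and yield) on FPU-crop-year
rows. Predictors: aPr, ferPr, aT, diffPr, N_in, BD, CF, SDC, STC,
IRRF (irrigation indicator), Extreme (EWY indicator). gsPr and gsT are
dropped by default as near-duplicates of their annual counterparts
(config override available). Outlier removal is a univariate
chi-square test on the squared standardized response at α = 0.001
(threshold 10.83), applied independently per response to the training
and testing partitions — an interpretation of a loosely specified
screening step, not a canonical procedure. Split 80/20, then 10-fold
CV over `mtry ∈ {2,3,5,8} × ntree ∈ {200,500}` minimizing mean RMSE
(ties → cheaper model). Partial dependence sweeps one feature over its
observed range, averaging predictions over all training rows.

On low-noise emulator output (noise SD 0.05, 80 FPUs × 24 usable
years, maize) the tuned forests reach holdout R² ≈ 0.86 for losses and
≈ 0.93 for yields — the suite asserts ≥ 0.85 / ≥ 0.92.

**Known limitation — the surrogate is memoryless.** The emulator's
response to an input cut propagates through the residual pool into
later years; the forest sees only current-year features. Under a mild
adaptive cut (ratio 0.9 above threshold 0.1) surrogate and re-simulated
counterfactual losses correlate > 0.9 and per-unit extreme-loss deltas
agree within 10 percentage points at the median, but fidelity degrades
monotonically with intervention severity (the suite asserts the
degradation explicitly). For this reason the pipeline's policy
optimization uses emulator re-simulation as its predictor; the
surrogate is the cheap alternative, not the default oracle.

## CLEANS policy optimization

A policy is a (diffPr threshold, input-scaling ratio) pair applied with
a strict trigger (`diffPr > threshold`); undefined diffPr never
triggers. Evaluation recomputes loss and yield under the modified
input with identical noise, measures the extreme statistic over the
*same* EWY year set against the unmitigated long-term mean, and reports
percentage deltas for extreme loss, mean input (always ≤ 0) and mean
yield. Constraints are strict (`yield loss < 3 %`, `input reduction <
15 %` by default; both swept over {3,5} × {10,15,20} in the constraint
sweep, and a 0 % yield-loss variant is expressible — with strict
comparisons it requires strictly positive yield change, so it is the
most conservative variant). The optimizer is an exhaustive scan of the
grid (thresholds 0–1.5 step 0.1, ratios 0.1–1.0 step 0.1 — anchored to
the order of magnitude practitioners quote for small thresholds and
deep cuts); ties break toward the larger ratio, then larger threshold,
i.e. the least intervention. A Gaussian forecast-noise hook on diffPr
before thresholding is available (off by default) since real deployment
would rely on seasonal forecasts.

On the default world the optimized policies cut the area-weighted
extreme loss by tens of percent while area-weighted yield changes stay
within the 3 % cap (the README's worked example prints −25.7 % /
−1.5 % on one configuration) — the suite asserts the signs and caps,
not the exact figures.

## Numerical and testing choices

* All randomness flows from named per-stage seeds through
  `numpy.random.SeedSequence`; identical configurations give
  byte-identical CSVs.
* Mass-balance closure is exact by construction (asserted at 1e-9
  relative); the loss partition is additive to 1e-12 relative.
* Problem sizes in the test suite (200 FPUs × 30 years for interval and
  driver structure; 80 FPUs × 25 years for surrogate fidelity; 60 FPUs
  for policy optimization; 500 series for null-frequency and bootstrap
  coverage) were chosen as the smallest ensembles at which the
  mechanism signatures are stable sign properties rather than noise.
* The generator emulates annual aggregates only. It has no daily
  hydrology, no N speciation (nitrate vs ammonium), no phenology, no
  spatial autocorrelation between units, and its loss response is a
  single logistic in relative wetness. Passing tests therefore show
  that the statistical machinery recovers a known mechanism of this
  form — not that the mechanism has any particular magnitude in real
  agroecosystems.
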