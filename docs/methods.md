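# Methods

## The problem

Mobile monitoring produces short-term, daytime, **on-road** measurements
at tens of thousands of 50 m road segments; stationary networks produce
**long-term, near-road** means at only tens of sites. A land-use
regression (LUR) trained on the mobile aggregates therefore learns the
wrong target distribution: on-road concentrations are on average a few
percent higher, exaggerate spatial contrasts, and contain persistent
street-level artifacts that a façade monitor does not see. The package
treats this as an instance-transfer problem: keep the mobile data (it
carries the spatial signal), but reweight or re-anchor it with the
little long-term information available.

## Data preparation

Roads are cut into consecutive 50 m pieces (a trailing remainder under
20 % of the target length is merged into its predecessor to avoid
sliver segments). One-second observations are temporally corrected
against a single fixed background reference site — additive
(`value − (ref_hour_mean − ref_campaign_mean)`) by default,
multiplicative (`value · campaign_mean/ref_hour_mean`) as the
conventional choice for particle counts — over a calendar-hour window.
Corrected points snap to the nearest segment (Euclidean, planar meters;
ties to the lexicographically smaller segment id; beyond 25 m
unassigned). Per segment the arithmetic mean, observation count and
drive-pass count (distinct calendar dates) are kept. Long-term sites
match every segment within 30 m; site-level predictions are means over
matched segments.

Defaults the source material does not fix, chosen once: correction
window = hour; snap cutoff 25 m (half a wide carriageway plus GPS
error); no minimum-observation filter on segments.

## Baselines

**SLR.** Forward stepwise OLS from an intercept-only model, adding the
candidate with the largest adjusted-R² gain, accepted only if the gain
exceeds 0.01, every coefficient keeps its a-priori sign (traffic,
population, industry positive; green space negative), and at most one
member of each buffer family enters. Afterwards covariates with
p > 0.10 are dropped iteratively. Thresholds follow common European LUR
practice. Predictions are floored at zero.

**RF_LUR.** scikit-learn random forest; 70/30 split of the mobile
segments, discrete grid over {number of trees, `m_try`, maximum leaf
nodes} scored by 5-fold CV squared Pearson R² on the 70 %, then an
overfit check `train R² − test R² ≤ 0.05` on the 30 %. Grid defaults:
trees {250, 500, 1000}, `m_try` {p/3, √p, p/2}, leaves {∞, 128, 512}.

## Density ratio (RuLSIF)

The α-relative density ratio
r_α(y) = p_t(y) / (α·p_t(y) + (1−α)·p_s(y)) between long-term (target)
and mobile (source) concentrations is fitted directly from samples with
Gaussian-kernel least squares: r̂(y) = Σ_l θ_l K_σ(y, c_l), centers on
≤ 100 target samples, θ = (Ĥ+λI)⁻¹ĥ with
Ĥ = α·E_t[kkᵀ] + (1−α)·E_s[kkᵀ], ĥ = E_t[k]. (σ, λ) are selected by
5-fold CV of the squared-loss criterion J = ½θᵀĤθ − ĥᵀθ; folds are
assigned round-robin over value-sorted samples, which makes the fit
deterministic and invariant to input order. σ grid = median distance ×
{¼, ½, 1, 2, 4}; λ grid = 10⁻³…10¹; α = 0.1 (mild relative smoothing —
bounds the ratio and stabilises the tails). A singular system moves to
the next larger λ. Evaluated ratios are floored at 10⁻³ (no instance is
fully discarded) and normalised to mean 1. The ratio is estimated on
the response axis; passing multivariate arrays gives a covariate-shift
variant.

## Transfer models

**Prior_RF.** The fitted ratio, evaluated at each mobile instance's
concentration, becomes its sample weight in an otherwise unchanged
random forest (same hyperparameters as RF_LUR, so the two differ only
in the weighting). Uniform weights reproduce the unweighted forest
exactly at a fixed seed, and the fit is invariant to rescaling all
weights.

**AdaBoost.R2** (internal). Weighted base learner per iteration
(depth-6 regression tree), adjusted errors e_i = L(|resid|/max|resid|)
with linear/square/exponential loss, weighted error ε = Σw_i e_i, stop
at ε ≥ 0.5, β = ε/(1−ε), update w_i ← w_i·β^{1−e_i} on the unfrozen
instances and renormalise *that block to its previous mass* — frozen
instances are genuinely untouched, and with nothing frozen this is the
standard renormalisation. Prediction is the weighted median of the
learners with weights log(1/β). A perfect first fit short-circuits to a
single-learner ensemble.

**Two-stage TrAdaBoost.R2.** Source (mobile) and target (long-term)
instances merge with equal initial weights. For steps t = 0…S−1 the
target share of total weight follows the schedule
n_t/(n_s+n_t) + t/(S−1)·(1 − n_t/(n_s+n_t)); at each step AdaBoost.R2
runs with all source instances frozen, the step is scored by k-fold CV
mean-squared error on target instances only, and between steps source
weights update as w_i·β_t^{e_i} — instance-dependent, so the source
instances most unlike the target (largest adjusted error under the
step's own ensemble) are de-emphasised hardest — with β_t found by
bisection (tolerance 10⁻⁶ on the fraction, clamped with a log message
when zero-error source instances make the schedule unreachable). The
step with minimal CV error is returned; its ensemble predicts via the
weighted median. Defaults: S = 10, 30 estimators per step, linear loss,
5 CV folds (reduced automatically for tiny target sets). All
randomness derives from one seed.

Design notes. The block-mass renormalisation matters: renormalising
all weights jointly lets the frozen source share grow back every
iteration (well-predicted target weights shrink multiplicatively) and
empirically collapses the target share to zero, silently undoing the
schedule. Likewise a *uniform* stage-one source scaling cannot separate
consistent from inconsistent source instances and erases the transfer
benefit; the per-instance β_t^{e_i} form is essential.

## Validation protocol

Per iteration (default 20): the long-term sites split 50/50 by site
(⌈n/2⌉ train / ⌊n/2⌋ validate — 17 sites split 9/8); TrAdaBoost trains
with the mobile data plus the training half and validates on the other
half; SLR is fit once on the full mobile data (it is deterministic, so
no CI is reported); RF_LUR and Prior_RF refit on a bootstrap resample
of mobile segments and validate on the full site set; the sensitivity
variants RF_LUR_half / Prior_RF_half validate on TrAdaBoost's half.
Metrics: nMAE and nRMSE (normalised by the mean of the validation
observations) and squared Pearson R². Summaries: mean, 2.5/97.5
percentile 95 % CI, median; improvement percentages are
100·(transfer − conventional)/conventional on the **medians**, reported
to one decimal.

## Synthetic study conditions

The generator emulates the structure of a mobile campaign plus sparse
long-term network at desk scale (defaults: 10×10 street grid of 1 km
streets → 400 segments of 50 m; this size keeps a full multi-seed
comparison to minutes while leaving ~5 segments per long-term site).

* **Covariates**: street-level traffic intensity (major/minor roads,
  log-normal) at 50 m and 300 m buffers, population density,
  industrial and green land fractions — spatially correlated fields
  with declared effect directions.
* **Truth** y*: linear in the covariates (NO₂-like scale, mean
  ≈ 26 µg/m³) plus a mild √traffic nonlinearity and spatially
  correlated noise; strictly positive.
* **Mobile campaign**: 1 + Poisson(7) drive-passes per segment on
  distinct weekdays 08:00–22:00; per-pass noise sd 6 µg/m³; a diurnal +
  daily temporal term shared with the background reference series (so
  the reference correction can remove it).
* **Domain shift** (defaults calibrated once to the reported summary
  statistics of real campaigns): traffic-dependent on-road inflation
  1 + 0.28·(traffic/max)² — tens of percent on the busiest roads,
  near zero on quiet streets, campaign-wide mean ≈ +5 %; a flat
  daytime bias of 0.2 µg/m³; gradient amplification 1.2 (on-road
  spatial contrasts exaggerated, widening the mobile distribution
  without moving its mean); and a mean-zero, spatially correlated,
  pass-persistent on-road scatter (sd 3.5 µg/m³) representing
  street-canyon and stop-and-go micro-environments — the reason mobile
  aggregates correlate only moderately with long-term values at the
  same locations.
* **Long-term network**: 82 sites (17 for the UFP-like preset) placed
  7 m off randomly chosen segments; a site's value is the
  inverse-distance-weighted mean of y* over all roads within 40 m
  (a façade monitor integrates every nearby road) plus noise sd
  1 µg/m³. `neutral_shift()` switches every bias, noise and mixing
  term off, making mobile aggregates equal y* exactly.

What the generator does **not** emulate: instrument drift and
calibration error, meteorology-driven regional transport, GPS error and
map-matching ambiguity, seasonal imbalance of the campaign, and
real-data covariate errors. Passing tests therefore demonstrate the
algorithms behave as designed under a controlled, realistic shift — not
that any particular improvement magnitude carries over to a specific
real campaign.

## Numerical choices and edge cases

Zero-length polylines are rejected by id; observations without
reference coverage are dropped and counted; unsnapped points and
unmatched sites are flagged, logged and excluded; all concentration
predictions are floored at zero with a log record. Adjusted-R² ties in
SLR resolve to the smaller column index; rank-deficient candidate
designs are skipped. CV fold assignments are fixed once per tuning run
and shared across the whole grid. A forest's uniform sample weights are
dropped so the unweighted RNG path is reproduced exactly. AdaBoost's
perfect-fit test uses a relative 10⁻¹⁰ threshold on the maximum
residual. The RuLSIF λ path retries larger grid values on singular
systems and errors only when the grid is exhausted.

## Known limitations

TrAdaBoost's step selection rests on small-sample CV over the target
set; with tens of sites the chosen step is noisy and its validated
performance fluctuates more than Prior_RF's (wider CIs), matching the
behaviour reported for the original protocol. The UFP-like preset
(9 training sites) is near the lower limit at which step selection is
meaningful. The density ratio is univariate by default; joint
covariate-response shifts are only partially corrected. Improvement
percentages computed from medians can differ in sign from mean-based
summaries when iteration distributions are skewed.
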