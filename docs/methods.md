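# Methods

## Dose–volume histograms and the MADD

A cumulative DVH tabulates, for each dose level `D_j`, the structure volume
`V_j` receiving at least `D_j`. The mean absolute dose deviation against a
reference dose `A` is computed by rectangular strips: point `j < n`
contributes `δV_j = V_j − V_{j+1}` at dose `D_j`, and the terminal point
carries its remaining volume `V_n` at `D_n` (no extrapolation beyond the
tabulated maximum). The strips are left-anchored, so the discrete sum is
biased by at most one grid width relative to the underlying voxel
distribution; the property suite asserts exactly this bound, and the
default export grid is 0.1% of the prescribed dose, making the bias
negligible at clinical precision (the bin width used by planning systems
varies and is configurable at ingestion).

Normalization rules for real exports: duplicate dose rows are merged
keeping the smaller cumulative volume (a cumulative DVH is a step
function); a truncated export whose first volume is below the structure
volume is anchored by prepending `(0, V₀)`. All pipeline math runs in
percent of the prescribed dose — conversion happens once at ingestion — and
the MADD is invariant to the volume unit (mL or fraction).

Reference doses by role: 0 for organs at risk and for the body contour,
the prescription (100%) for the breast target and the tumor bed. The body
contour receives weight only in the dedicated `body` priority; anywhere
else it would doubly penalize the structures it contains.

## Penalty scores

`score = Σ wᵢ Mᵢ` with `Σ wᵢ = 1` is a convex combination, so it is bounded
by the smallest and largest weighted MADD and shares their unit. The five
built-in weight sets are frozen constants; user sets load from YAML/JSON
and are validated (non-negative, sum 1 within 1e−9). A missing weighted
structure is an error by default; an explicit renormalize option rescales
the remaining weights and logs it, for exports that lost a contour. Scores
are carried at full precision and rounded to two decimals only at report
time.

## Gain analysis

Δ = prone − supine per patient; a gain is strictly Δ < 0, ties counting
conservatively as no gain. The exact binomial interval is Clopper–Pearson
(Beta quantiles, via `scipy.stats.binomtest(...).proportion_ci
(method="exact")`), which collapses to [0, ·] and [·, 1] at the boundaries.
The subgroup contrast (gain rate below vs at/above a supine-penalty
threshold, default 2) uses Fisher's exact test by default — the appropriate
choice at these cell counts — with a chi-square option; this is a
documented interpretation, since two-proportion comparisons are often
reported without naming the method. Degenerate inputs fail loudly: a paired
t-test on zero-variance deltas raises rather than returning p = 1, and an
empty subgroup raises rather than returning an empty summary.

## Predictor screening

One univariable fit per characteristic against Δ, complete cases per
characteristic (no imputation; the available N is reported per row).
The robust fit is Huber M-estimation with tuning constant 1.345, scale
from the median absolute deviation, IRLS converged to 1e−8 on the
coefficients (max 50 iterations), with the coefficient SD from the robust
covariance of the final fit — the standard defaults of the classical
`rlm`-style implementation, here through `statsmodels.RLM`. On outlier-free
noiseless data it coincides with ordinary least squares exactly.

Categoricals are dummy-coded 0 for the reference level, 1 otherwise
(tumor location collapses to lower-inner-quadrant vs not; couch to Varian
vs Bionix; preference to prone vs else). Binary predictors report no
numeric cutoff.

The cutoff where the predicted gain changes sign is
`−intercept/coefficient`; the slope's sign gives the direction
(negative → larger values favor prone). The cutoff is declared not
identifiable when the slope is too flat (|coefficient/SD| < 0.5 — a slope
indistinguishable from zero at even half a standard error cannot place a
sign change) or when it falls outside the observed data range. Cutoffs are
rounded half away from zero at each characteristic's natural precision
(integers for mm/years/kg/cm/mL, one decimal for ratios/L/%dose) only at
report time.

Nonlinearity screening uses a one-term fractional polynomial: the best
power among {−2, −1, −0.5, 0 (log), 0.5, 1, 2, 3} by deviance, then a
closed test — best-FP1 vs null on 2 degrees of freedom (one for the power
selection, one for the slope), then best-FP1 vs the straight line on 1 —
both at the nominal alpha. The 2-df first stage is what keeps the family
type-I error near nominal despite the maximization over eight correlated
transforms; the acceptance suite measures it at about 0.04 over 1000 null
replicates at alpha 0.05. Two degrees of freedom means FP1 only; a
two-term FP2 search is out of scope. Predictors that are not strictly
positive are shifted by the smallest observed spacing before transforming.
"Linearity acceptable" is operationalized as the closed test not rejecting
the straight line — one reasonable quantification of a criterion usually
left informal.

## Synthetic cohort

The generator emulates what the analysis needs from a dual-planning
left-breast cohort, not anatomy or beam physics. Per structure and setup a
two-component mixture drives 10,000 voxels (a trade-off keeping the DVH
grid bias below 0.1% of the prescription at negligible cost): an in-field
fraction on a Gaussian plateau and an exponential out-of-field bath
truncated at six mean-lengths. Default parameters are set analytically from
the mixture mean `f·μ + (1−f)·s` so the cohort-mean MADDs land on the
clinically reported anchors — ipsilateral lung ≈ 7.6% of prescription
supine vs ≈ 1.9% prone, heart ≈ 1.9% supine vs ≈ 3.4% prone, contralateral
breast ≈ 0.8% vs ≈ 1.7% — and so the target structures keep mean doses
within the planning constraint window (95–107% of prescription).

Heterogeneity has two layers of mean-one lognormal jitter: an anatomical
factor shared by a patient's two setups (sd 0.4 on in-field fractions —
this is what spreads supine penalties over roughly 1.3–4.5% of
prescription, matching the clinical range, and what creates the
regression-to-the-mean dependence of Δ on the supine score) and a small
per-setup planning factor (sd 0.15). The pendulousness link is physical:
the prone in-field fractions of the ipsilateral lung and the heart decay
log-linearly in the breast depth ratio, so Δ depends on the ratio through
the full MADD → penalty computation. The manifest records the effective
planted slope as the linear projection of the noise-free expected Δ onto
the sampled ratios. Characteristics are sampled at the reference cohort's
medians and ranges (age 57.5 y, BMI 25, left breast volume 484 mL, heart
volume 461 mL, depth ratio ≈ 1.7) with realistic missingness in BMI,
weight, and preference.

Three outlier patients are planted by default: depth ratio forced below
1.5 and the prone heart dose regenerated with an in-field fraction sized to
raise Δ by about 5% of prescription — low-pendulousness patients whose
prone plan fails badly, off the trend, as observed clinically. A `direct`
mode skips voxels and draws Δ from an explicit linear link (slope −0.8 on
the ratio, supine coefficient −0.5, noise sd 0.35) for studies that need
the exact planted slope, e.g. the replicated recovery calibration.

What passing tests therefore show about real data — and what they do not:
the pipeline arithmetic is verified against independent oracles and the
published numbers that can be replayed from printed inputs (counts,
coefficients, weights); the generator demonstrates that planted signals of
clinical magnitude survive the full chain. It does not reproduce
cohort-level estimates that depend on the non-public raw data (the 62.1%
gain rate, the fitted coefficients themselves), and real DVHs have
features the mixture model lacks (multimodal plateaus, correlated
structure overlap, setup-specific contouring differences).

## Numerical choices and limitations

- Ties (Δ = 0) are no-gain, conservative toward prone; at full floating
  precision they essentially never occur.
- Percent reporting rounds half away from zero to one decimal.
- Gain counting, sorting, and report ordering are deterministic and
  order-invariant; reruns with the same config and seed are bit-identical.
- The replicated calibrations in the acceptance script use 100 cohorts of
  500 patients (robust-fit recovery) and 1000 null replicates of size 116
  (FP1 type-I error) — sizes chosen to estimate a 5% rate to about ±1.5%
  while keeping the whole script under a minute.
- No multivariable model, no weight optimization, no NTCP/dose-response
  modeling behind the weights, and no DICOM RT-DOSE handling: DVHs are the
  input, and the priority weights are declared, not learned.
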