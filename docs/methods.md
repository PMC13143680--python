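# Methods

This note documents the models, defaults and numerical choices behind
`fluxpro`, and what the synthetic study conditions do and do not emulate.

## Synthetic study conditions (`synthdata`)

**Cohort.** Three groups — healthy controls (HC, n = 80), type-2 diabetes
without kidney disease (T2DM-NoDKD, n = 102), established DKD (n = 100) —
with per-group marginals for the clinical and optical variables
(age, BMI, blood pressure, HbA1c, eGFR, UACR, serum creatinine, urine
osmolality, chroma, `b*`, foam half-life, micro-bubble index, surface
tension). Symmetric variables are normal (mean ± SD); right-skewed ones
(UACR, `T½`, creatinine) are log-normal parameterised by their median and
IQR, with the IQR assumed symmetric on the log scale — this preserves
positivity and skew, and makes the configured "location" of a skewed
variable its *median*, which is what location-convergence checks compare.
Surface tension has no tabulated marginal; we use N(68, 4) / N(64, 4) /
N(52, 6) mN/m for HC / T2DM / DKD, inside the physiological urine range and
decreasing with proteinuria.

**Correlation structure.** Cross-variable structure comes from a per-group
Gaussian copula on latent normals. Four targets are configured:
`corr(log UACR, log T½) = 0.78`, `corr(b*, osmolality) = 0.78`,
`corr(log UACR, MBI) = 0.85`, and Spearman
`ρ(γ, T½) = −0.88`, converted to its latent Pearson equivalent via
`r = 2 sin(πρ/6)`. Targets are defined — and reproduced exactly up to
sampling noise — on the latent scale (log scale for log-normal
marginals); raw-scale Pearson correlations of heavily skewed variables are
necessarily attenuated. Unspecified pairs among correlated variables are
completed transitively (`r_ij = r_ik · r_kj` along specified links), a
one-factor-consistent fill that keeps the matrix positive definite; an
eigenvalue-clipping repair is the fallback for user-supplied targets.

**Risk score and strata.** Each subject carries a latent risk score
`σ(α_g + 1.5 z)`, with `z` the severity (UACR) latent and group intercepts
(−4.0, −1.45, 1.5) chosen so that ~17% of the T2DM-NoDKD group crosses the
0.5 high-risk threshold, matching the emulated design's stratum split
(17 / 85).

**Measurement noise.** The optical features are duplicated as `*_meas`
columns with 3% multiplicative Gaussian noise — inside the < 4.5%
replicate-CV precision the imaging protocol claims.

**Metabolite panels.** Ten analytes (indoxyl sulfate, p-cresyl sulfate,
phenylacetylglutamine, C8/C16/C18 acylcarnitines, succinate, citrate,
kynurenine, tryptophan) with log-normal baselines (geometric SD ≈ 1.6) and
DKD-specific log2 fold-changes implementing the serum-retention /
urinary-loss mismatch (e.g. indoxyl sulfate +1.5 serum / −1.0 urine).
Urinary concentrations and creatinine scale with each subject's dilution
state (osmolality / 650); urinary creatinine is 9000 µmol/L at reference
osmolality with 15% log-normal noise. Values below the per-metabolite LOD
(indoxyl sulfate 0.0152 µmol/L, p-cresyl sulfate 0.0224 µmol/L, others
panel-typical) are recorded as censored; an additional fraction (5-8%) is
removed completely at random. Missingness is MCAR by design — the
mechanism is otherwise unconstrained.

**Outcomes.** Event times are exponential within the 3-year horizon:
annual hazards 0 (HC), `−ln(1 − 0.023)/3` (T2DM low-risk stratum) and
`−ln(1 − 0.34)/3` (DKD), with the high-risk stratum hazard multiplied by
12.5. Non-renal death competes as an independent exponential process at
0.01 / year; subjects event-free at 3 years are administratively censored.

**Image phantoms.** `phantom.render_urine_series` draws a flat geometric
scene at 0.05 mm/pixel: a 24-patch reference card, a liquid column at the
prescribed CIELAB colour, and a foam band of height
`h(t) = h₀ · 2^(−t/T½)` (h₀ = 10 mm by default) at t = 0, 30, 60, 120 s.
At t = 30 s the band is populated with non-overlapping bubble disks from a
two-component log-normal mixture (micro: median 0.30 mm, truncated to
[0.18, 0.44]; macro: median 1.1 mm, truncated to [0.60, 2.20]); the
truncation keeps every bubble unambiguously on one side of the 0.5 mm
cutoff given that a rasterized disk's equivalent diameter is only accurate
to about ±1 pixel at this resolution. Disks are rasterized at their exact
float radius, so the summed pixel area tracks the analytic `Σ πr²` to a
fraction of a percent even though individual small disks deviate by a few
percent. A 3×3 colour cast models the acquisition illuminant and is
applied to the whole scene; 8-bit Gaussian noise (σ = 2) is added last.
The phantoms exercise operator *contracts* (parameter recovery,
invariances), not robustness to real photography: no meniscus, glare,
perspective, shading, or bubble coalescence is modelled, so passing tests
demonstrate correctness of the extraction math, not field readiness.

## Physicalomics extraction

* Colour correction is a least-squares affine map (3×3 + offset) from ≥ 4
  observed card patches to their reference RGB; chromaticity is the mean
  corrected liquid-ROI colour converted sRGB → CIELAB under D65 (the
  5500 K acquisition illuminant is treated as removed by card correction).
* Foam masks come from Otsu thresholding inside the foam ROI with
  hole-filling (bubble rims) and small-object removal; uniform ROIs
  (range < 0.15) resolve to all-foam or all-empty by brightness level.
  Foam height is the column-wise **median** of the mask's vertical extent
  (robust to speckle), times the pixel pitch.
* `T½` comes from least squares on `log2 h(t)` over positive heights — an
  exponential-decay fit rather than interpolation, since only four frames
  exist. If the height never falls below `h₀/2` in the window and the
  fitted `T½` exceeds the last frame time, the estimate is flagged
  right-censored ("> 120 s") rather than returned as a bare number, so
  downstream models can cap it.
* Bubbles are detected inside the mask as rim-enclosed regions: rim pixels
  are those darker than `min + 0.35 · (median − min)` of the in-mask
  intensities (the rims are the darkest mode; the bulk is matrix or
  interior); interiors touching the mask exterior (or the image border)
  are interstitial matrix, not bubbles. Merged interiors are split by
  distance-transform watershed seeded at dilated local maxima, and rim
  pixels are assigned to the nearest labelled interior — the "ridge to
  nearer seed" tie-break. Bubble size uses the equivalent-circle diameter
  `d = 2√(area/π)`; MBI's denominator is the **total** foam-mask area,
  interstitial pixels included (the alternative — bubbles-only denominator
  — would inflate MBI in sparse foams).

## Flux-ratio preprocessing (`fluxomics`)

Pipeline order is filter → KNN → LOD/2 → ratio. The missingness filter
drops metabolites with **strictly** more than 20% missing-at-random values
in either fluid (censored ≠ missing; both are tracked separately).
KNN imputation (k = 5) works per fluid on log10, z-scored features,
measuring Euclidean distance over features observed in both subjects and
averaging the k nearest donors' raw values; distance ties break by subject
order for determinism. Censored entries then become LOD/2 exactly, flagged
in the output provenance. The ratio itself is exactly invariant to uniform
dilution of either fluid and to any consistent unit change.

PQN divides each sample by the median of its feature-wise quotients
against the reference (per-feature median spectrum by default).
"Creatinine-adjusted TUS" has no canonical formula; here the per-sample
dilution factor is the **geometric mean** of the total-signal quotient and
the creatinine quotient (each relative to its cohort median), which makes
the normalisation exactly invariant to joint scaling of a sample and its
creatinine — the property a dilution correction must have. This definition
is a documented package choice.

## Multivariate statistics

OPLS-DA follows the NIPALS orthogonal-projections formulation: orthogonal
components `w_o = p − (wᵀp)w` are peeled off before a single predictive
component is fit. One orthogonal component is the default; `n_ortho=None`
grows components greedily while cross-validated Q² improves by > 0.01.
Q² uses 7-fold cross-validation with centring/scaling refit inside each
training fold. VIP on one predictive component reduces to
`√p · |w_j| / ‖w‖`, so mean(VIP²) = 1 identically. Permutation validation
refits under label permutations and passes only if **all** permuted R²Y
and Q² fall below the originals and the intercept of the Q²-vs-|label
correlation| regression (permuted points plus the original at r = 1) is
negative. Differential features need VIP > 1.0 **and** BH-FDR < 0.05 on
Mann-Whitney (two groups) or Kruskal-Wallis (more) p-values.

## Classifier evaluation (`fusionmodel`)

Random forests (500 trees by default, `min_samples_leaf=2`) drive both the
classifier and RFE feature selection; RFE drops 20% of remaining features
per round using permutation importance averaged over stratified inner
folds (5 by default), and is invoked strictly inside each outer training
fold of the repeated stratified k-fold evaluation, so held-out folds never
see the selection. Out-of-fold probabilities are pooled (averaged per
subject across repeats) for the cross-validated AUC and calibration;
apparent performance refits on all data and is reported separately, with
optimism = apparent − cv. AUC inference uses the fast DeLong
midrank estimator, including the correlated-difference test for two
models on the same subjects. Calibration reports Hosmer-Lemeshow deciles
(χ² with g − 2 df; adjacent degenerate groups merged), logistic
recalibration slope/intercept of `y` on logit(p), and the Brier score.
NRI is category-free (no published risk categories to use); NRI/IDI CIs
come from a seeded 1000-replicate subject bootstrap. Decision curves use
`NB(τ) = TP/N − (FP/N)·τ/(1−τ)` against treat-all and treat-none. The
nomogram maps an additive logistic fit to points —
`scale · β_j · (x_j − ref_j)` with the reference at the range minimum
(positive β) or maximum (negative β), the widest `|β|·range` spanning 100
points — and back to probability through the linear predictor, an exact
round trip. Sample-size calculators: EPV = events/predictors; minimum n
for a target shrinkage factor S, `n = p / ((S−1) ln(1 − R²_CS/S))`,
rounded up (461 at p = 15, R²_CS = 0.25, S = 0.9); Hanley-McNeil
`SE(AUC)` with `Q₁ = A/(2−A)`, `Q₂ = 2A²/(1+A)`.

Tests and the acceptance script run the evaluation at reduced problem
sizes chosen for the package's default verification workloads (repeats = 1,
forests of 100-300 trees, inner folds 3-5); the estimators themselves are
size-agnostic and the defaults above remain the analysis settings.

## Prognosis

The MARE composite fires on the earliest of: a **sustained** relative eGFR
decline — threshold met at two consecutive assessments, with the event
timed at the first of the pair (the single-visit alternative would count
transient dips); new-onset macroalbuminuria, a strict `UACR > 300 mg/g`
crossing at any visit; or an ESRD flag. The decline threshold is
configurable and defaults to 30% (a stricter 40% variant is used by some
endpoint definitions; both are supported). Risk strata split at score
≥ 0.5, boundary inclusive.

The Monte-Carlo projection draws one Bernoulli outcome per subject per
iteration (1000 by default) from assigned 3-year probabilities and reports
per-stratum means with 2.5/97.5 percentile intervals; the stratum mean is
an unbiased estimator of the mean assigned probability with
`SE = √(Σp(1−p))/n/√iterations`.

Cox proportional-hazards fits delegate to lifelines (Efron ties, Wald
CIs). The Fine-Gray subdistribution model is implemented directly:
subjects with a competing event at `s` remain in risk sets after `s`
with weight `G(t)/G(s)`, where `G` is the Kaplan-Meier estimate of the
censoring survival (left-continuous); the weighted partial likelihood
(Breslow ties) is maximised by Newton-Raphson (tolerance 1e-10), and the
CI is Wald from the inverse observed information. This model-based
variance is slightly narrower than the robust sandwich used by some
reference implementations; coefficient estimates agree with
`cmprsk::crr` to ~1e-5 on shared data (verified in the test suite). With
no competing events the weights are unity and the estimate coincides with
the Cox fit — a degeneracy the tests check to 1e-6 relative.

## Known limitations

* The phantoms validate extraction math, not real-world imaging; ambient
  light, specular highlights and non-rigid foam geometry are out of scope.
* The Fine-Gray variance is model-based, not robust; for small samples its
  CI can be mildly anticonservative.
* The synthetic cohort induces correlations pairwise on the latent scale;
  higher-order dependence (e.g. heteroscedasticity of UACR noise across
  severity) is not modelled.
* The TUS normalisation formula is a package definition (see above), since
  no canonical one exists.
* With only four frame times, `T½` estimates for fast-decaying foams
  (≈ 4 s) rely on a single sub-resolution height at t = 30 s; recovery is
  within 10% in tests, but the variance there is dominated by the 1-pixel
  height quantisation.
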