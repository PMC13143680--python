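# fluxpro

Digital urine physicalomics and dual-fluid metabolic flux modelling for
early diabetic kidney disease (DKD) stratification.

Screening for DKD leans on two glomerular markers — estimated GFR and the
urine albumin-to-creatinine ratio (UACR) — which miss early *tubular*
dysfunction and non-albuminuric phenotypes. Two orthogonal signal families
can close that gap:

* **Digital urine physicalomics** — computer-vision quantification of
  macroscopic urine traits: CIELAB chromaticity of the liquid column
  (`b*`, chroma `C* = √(a*² + b*²)`, and a dilution-corrected yellowness
  `b*_adj = b* · 650 / osmolality`), the foam half-life
  `T½` from time-lapse frames after standardized agitation
  (`h(t) = h₀ · 2^(−t/T½)`), and the micro-bubble index
  (MBI = % of t = 30 s foam area in bubbles with equivalent diameter
  < 0.5 mm). Foam stability is an optical proxy for surfactant proteins
  (albumin) at the air-liquid interface.
* **Serum-to-urine flux ratios** — for each metabolite in paired serum and
  urine panels (µmol/L),

  ```
  flux = log10( ([S]met/[S]creat) / ([U]met/[U]creat) )
  ```

  a dimensionless, dilution-invariant readout of renal handling. High
  values for protein-bound uremic toxins (indoxyl sulfate, p-cresyl
  sulfate, phenylacetylglutamine) — the "high serum / low urine" mismatch —
  indicate failing proximal-tubular secretion (OAT1/3) before eGFR falls.

The package is a complete, tested re-implementation of the pipeline around
these ideas for methodologists and nephrology data scientists: a
synthetic-data layer that generates cohorts, paired panels, outcome
histories and rendered urine-image phantoms with known ground truth;
feature extraction; flux-ratio preprocessing (missingness filter > 20%,
KNN imputation, LOD/2 censoring imputation, PQN / creatinine-adjusted TUS
normalization); OPLS-DA with VIP scores and 1000-iteration permutation
validation; a three-tier random-forest classifier (clinical base →
metabolomics → fusion) evaluated with nested cross-validation, DeLong AUC
comparison, Hosmer-Lemeshow / calibration-slope / Brier calibration,
continuous NRI/IDI, decision-curve analysis and a logistic nomogram; and
prognosis tooling (MARE endpoint classification, score-threshold risk
strata, Monte-Carlo 3-year projection, Cox and Fine-Gray competing-risk
models, Riley/Hanley-McNeil sample-size calculators).

## Worked example

```python
import numpy as np
from fluxpro import synthdata as sd, fluxomics as fx, fusionmodel as fm
from fluxpro import phantom as ph, physicalomics as po

# 1. render one DKD-like urine sample and extract its optical phenotypes
rng = np.random.default_rng(0)
spec = ph.ImageSpec(lab_color=(78.0, 2.0, 25.0), foam_half_life_s=45.8,
                    bubble_diameters_mm=ph.sample_bubble_diameters(40, 0.6, rng),
                    seed=7)
series = ph.render_urine_series(spec)
feats = po.extract_features(series, osmolality=420.3)
c = feats["chromatic"]
print(f"b* = {c.b_star:.1f}   b*_adj = {c.b_adj:.1f}   "
      f"T1/2 = {feats['t_half'].t_half_s:.1f} s   MBI = {feats['mbi_pct']:.1f} %")

# 2. synthetic cohort -> flux ratios -> tiered classifier
cohort = sd.generate_cohort(sd.default_cohort_config(seed=1))
panel = sd.generate_metabolite_panel(cohort, sd.default_flux_effects(seed=2))
matrix, dropped = fx.flux_pipeline(panel)
groups = cohort.set_index("subject_id")["group"]
print(matrix.values["indoxyl_sulfate"].groupby(groups).mean().round(2))

table = fm.build_feature_table(cohort, matrix.values)
y = table.pop("label").to_numpy()
clin = fm.nested_cv_evaluate(table, y, tier=fm.CLINICAL_TIER, folds=10, repeats=1, seed=3)
fus = fm.nested_cv_evaluate(table, y, tier=fm.FUSION_TIER, folds=10, repeats=1, seed=3)
*_, p = fm.delong_auc(fus.oof_pred, clin.oof_pred, y)
print(f"clinical cv AUC = {clin.cv_auc:.3f}   fusion cv AUC = {fus.cv_auc:.3f}   "
      f"DeLong p = {p:.2e}")
```

which prints

```
b* = 25.0   b*_adj = 38.6   T1/2 = 46.2 s   MBI = 1.9 %
group
DKD           1.64
HC            1.13
T2DM-NoDKD    1.10
Name: indoxyl_sulfate, dtype: float64
clinical cv AUC = 0.763   fusion cv AUC = 0.994   DeLong p = 1.62e-12
```

Reading the output: the phantom was rendered with a generative half-life
of 45.8 s and the extractor recovers 46.2 s (0.9% off); the low `b*` with
a much higher `b*_adj` reflects a dilute urine (420 vs the 650 mOsm/kg
reference). The indoxyl-sulfate flux ratio is ~0.5 log10 units higher in
the DKD group — the serum-retention / urinary-loss mismatch — and adding
the flux and optical features to the clinical covariates raises the
cross-validated AUC for DKD-vs-diabetes discrimination from 0.76 to 0.99
on these synthetic study conditions (the out-of-fold DeLong comparison is
decisive).

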