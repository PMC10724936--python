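# Methods

## Problem

An intermediate coronary stenosis is functionally significant when the
fractional flow reserve (FFR) — the ratio of distal to aortic pressure at
maximal hyperemia — is at most 0.80. Invasive FFR measurement is costly and
uncomfortable; this package implements a classification pipeline that
predicts significance from the lumen geometry of an intravascular OCT
pullback (reduced to a 1-D radius-vs-length signal) together with routine
clinical covariates. Because the kind of registry the pipeline targets
(on the order of 80 patients / 100 lesions, with roughly half the lesions
inside the 0.75–0.85 gray zone) is not publicly available, the package
ships a synthetic cohort generator with the same statistical structure, so
that every stage is testable end to end.

## Ground truth: drift-corrected FFR

At the end of an FFR pullback the wire and catheter transducers may
disagree by a residual drift `D` (mmHg). A drift with `|D| ∈ {2, 3}` is
treated as relevant and corrected as

    corrected_Pd = Pd + D,    corrected_FFR = corrected_Pd / Pa,

while drifts of 0–1 mmHg are left alone and `|D| > 3` raises a
re-equalization warning (the clinical protocol would repeat the
measurement) and is not silently corrected. A lesion is labeled
significant (`y = 1`) when `corrected_FFR ≤ 0.80`; the boundary value
itself is significant. The gray zone is the closed interval
`[0.75, 0.85]`, optionally narrowed to `[0.75, 0.83]` for subgroup
reporting. Negative drifts are corrected with signed addition and flagged,
since protocols rarely state the sign convention.

## Geometric features

Twelve quantities are computed from the radii signal, with inclusive frame
ranges and lengths defined as `(end − start) · frame_spacing` (0-based
indices, 0.2 mm/frame by default): the segment mean/min/max radius, the
stenosis-region mean radius, mean radius per segment length, the maximum
radius rapport `(r_max − r_min)/r_max`, the stenosis length, the
percentage diameter reduction `100·(1 − 2·r_mean/(r_prox + r_dist))`, the
proximal radius rapport `(r_prox − r_dist)/r_prox`, the radius rapport
`((r_prox + r_dist)/2 − r_min)/((r_prox + r_dist)/2)`, and the proximal
and distal boundary areas `π r²`. The proximal/distal reference radii are
taken at the annotated lesion-boundary frames — a single unambiguous rule
that stands in for the expert's annotation. The physician-estimated
minimal lumen diameter (MLD) enters as its own feature, deliberately
distinct from twice the computed minimum radius (it is simulated as
`2·r_min` plus annotation noise).

The full matrix is 26 columns (12 geometric + MLD + 13 clinical). It is
L1-normalized per feature column — each column divided by the sum of its
absolute values. Per-column (not per-row) normalization is the only
choice that does not mix units across features, and it leaves every
univariate model's ranking, and hence all ROC quantities, unchanged.
Feature pairs with `|Pearson r| ≥ 0.999` are pruned by removing the
later-ranked member; the threshold is slightly below 1 purely for floating
point, and the rule is deterministic and idempotent.

## Univariate models and cross-validation

Twelve base learners are registered: SVMs with linear, cubic-polynomial
and RBF("scale") kernels (class probabilities via cross-validated Platt
scaling), a decision tree, 5-nearest neighbors, random forests with
20/40/60/100 trees, AdaBoost, Gaussian naive Bayes, and logistic
regression. The learner families are fixed by the study design; the exact
hyperparameters (kernel degree, k, tree counts beyond 60) are this
package's declared defaults, not inferred choices. Estimators that are
sensitive to feature scale are wrapped in a per-fold standardizer — fit on
the training fold only — because L1 normalization puts columns on a ~1/n
scale that would otherwise interact badly with default regularization; for
a single feature this is a monotone affine map and changes no ranking.

Two protocols share one thresholding rule: the decision threshold is
chosen on the training fold to minimize `|Se − Sp|` over all candidate
thresholds (midpoints of consecutive sorted unique scores plus ±∞
sentinels; ties broken by maximal Se + Sp, then the smallest threshold),
and only then applied to the held-out lesions.

* Feature ranking uses stratified patient-grouped tenfold CV repeated over
  seeds 0–9, re-seeding both the folds and the learner; each seed's
  accuracy pools the out-of-fold predictions. Features are kept when the
  mean accuracy over seeds reaches 60%.
* Ensemble inputs use leave-one-patient-out CV: one fold per patient, all
  lesions of a patient held out together so multi-lesion patients never
  leak across the split. Each lesion receives an out-of-fold class
  probability `O_i` and crisp label `C_i`. A training fold missing a class
  is skipped with a warning, never imputed.

An optional isotonic calibration of the probabilities (fit on the training
fold) exists but is off by default; it is monotone, so AUCs are unchanged.

## ROC analysis and ensemble voting

ROC curves are built exactly over the same candidate-threshold set, with
the positive call `score ≥ threshold`. AUC is the Mann–Whitney statistic
(concordant pairs plus half the ties). The operating point is the curve
point closest in Euclidean distance to the perfect corner (FPR, TPR) =
(0, 1) — not the Youden index; ties prefer higher sensitivity, then the
smaller threshold.

Each univariate model contributes one binary vote per lesion under one of
three strategies: M1 thresholds every model's probability at the *mean* of
all models' optimal cutoffs; M2 thresholds each at its *own* cutoff; M3
votes the crisp labels directly (its "ROC of the crisp votes" cutoff is
computed on the mean vote and reported, though it is degenerate by
construction — the prose behind M3 admits more than one reading, and this
concretization is declared, not attributed). Votes combine by simple
majority or by weighted voting with log-odds weights
`w_i = ln(acc_i/(1 − acc_i))`, accuracies clipped to `[ε, 1 − ε]`
(ε = 10⁻⁶) so the weights stay finite. The weighted score is normalized by
`Σ w_i`, which makes the 0.5 comparison invariant to the logarithm base
and to positive rescaling — the base left unstated in the weight formula
is therefore immaterial. A score of exactly 0.5 is called positive,
erring toward detecting significant lesions. If all models are at or below
chance the weight sum is non-positive and weighted voting refuses with an
error rather than inverting votes.

## Reporting

Confusion-matrix metrics (accuracy, Se, Sp, PPV, NPV) are percentages with
two decimals; a zero-denominator metric is reported as undefined, never
NaN. Proportion CIs are Wilson score intervals (z = 1.96) — the method
reproduces published interval bounds for this study design exactly at two
decimals. AUC CIs use the Hanley–McNeil closed-form standard error by
default, with a stratified-bootstrap alternative behind a flag since
closed-form and resampling intervals can differ in the third decimal.
Subgroup reports slice accuracy by FFR zone (inside/outside a configurable
gray zone) and by vessel, proximal-LAD, sex, hypertension and diabetes,
always with per-cell counts. A multivariate random-forest baseline on the
top-k features runs under the same leave-one-patient-out protocol for
comparison with the voting ensemble.

## Synthetic cohort generator

The generator works backwards from physiology so that geometry, pressures
and labels stay mutually consistent:

1. **Target FFR** is drawn from a three-zone mixture with masses
   25/102 (below 0.75), 47/102 (gray), 30/102 (above 0.85); within-zone
   laws are a truncated normal (0.71, 0.05) below, uniform inside the gray
   zone, and a truncated normal (0.875, 0.035) above. These were fixed
   once, from the registry's published marginals alone, to reproduce mean
   0.80, sd 0.08, and ~48/102 lesions at FFR ≤ 0.80.
2. **Geometry**: each lesion gets a baseline radius ~N(1.6, 0.08) mm
   (clipped to 1.3–1.9), an analyzed segment of 15–30 mm (within the 75 mm
   pullback limit), a raised-cosine stenosis occupying 55–65% of the
   segment at a uniformly drawn center, and a mild linear taper (0–2%).
   The stenosis severity is solved by root-finding so that the noiseless
   profile reproduces the target FFR through the pressure-drop surrogate
   below. Sampling FFR first and inverting to severity (rather than
   calibrating a severity distribution) hits the zone masses exactly by
   construction while keeping the geometric features causally linked to
   the label. Per-frame Gaussian radius noise (default 0.05 mm) is added
   and floored at 0.1 mm.
3. **Pressure-drop surrogate**: `ΔP = Kv·lengthS·(1/r_min⁴ − 1/r_ref⁴)·Q +
   Kt·(A_prox/A_min − 1)²·Q²` with defaults Q = 2 mL/s, Kv = 0.3,
   Kt = 0.7, and FFR = clamp((Pa − ΔP)/Pa, 0.01, 1). The viscous term uses
   the *excess* resistance over the healthy proximal-boundary radius so
   that an unnarrowed vessel has ΔP = 0 and FFR exactly 1; the term is
   otherwise Poiseuille-like (halving `r_min` scales it by ~16 in the
   wide-reference limit). The coefficients weight the scale-free turbulent
   term so the dimensionless narrowing ratios carry most of the signal —
   with zero noise, a univariate model on percentage diameter reduction
   reaches out-of-fold AUC > 0.85. This is a monotone plumbing surrogate,
   not a hemodynamic model; no published coupling constrains it.
4. **Pressures**: Pa ~ N(100, 5) mmHg rounded to the 1 mmHg instrument
   resolution; `corrected_Pd = round(FFR·Pa)`; the recorded Pd is
   `corrected_Pd − D`, so drift correction recovers the true FFR up to
   rounding (exactly, on a 0.01 grid with zero pressure noise). Drift is
   assigned to exactly 12 lesions at 2 mmHg and 3 at 3 mmHg by default.
5. **Clinical covariates** follow the registry's patient-level marginals
   (82% male, age 60.5 ± 11.2 y, BMI 27.7 ± 2.5 with weight derived from a
   sex-specific height, hypertension 75%, dyslipidemia 77.5%, diabetes
   33.75%, smoking history 52.5%, EF 48.28 ± 6.31%); covariates without a
   published marginal (height, IVS, Hb, Ht, diastolic grade) use
   population-typical laws. Weight and hematocrit optionally carry a weak
   severity signal (default +2 kg and +1% per standardized unit of lesion
   burden); zeroing the couplings makes the clinical block independent of
   FFR. All lesions of a patient share one clinical record.

The whole cohort is a deterministic function of its config (including the
seed): regeneration is bit-identical.

### What the generator does not emulate

No 2-D/3-D imaging, no segmentation artifacts, no serial/bifurcation
lesions, no vessel-specific FFR differences (LAD vs RCA), no hemodynamic
realism beyond monotonicity, and no culprit-lesion timelines. Passing
tests on synthetic cohorts therefore demonstrate that the pipeline's
machinery is correct and well-calibrated under its stated assumptions —
not that its accuracy transfers to clinical data.

## Problem sizes and numerical choices

Unit tests run on the default 80-patient/102-lesion cohort and a
240-patient/300-lesion noise-free cohort. The end-to-end behavioral suite
uses 20 seeds of 400-patient/500-lesion cohorts with eight univariate
naive-Bayes models (six geometric/MLD features plus weight and
hematocrit), combined by per-model-cutoff (M2) weighted voting — the
configuration found most robust on synthetic data. Generator calibration
is checked on a 50,000-lesion cohort; the reproduction script
(`scripts/acceptance.py`) regenerates that cohort from a command-line
seed and reports its mean corrected FFR. Root-finding uses Brent's method
on severity ∈ [0, 0.95] with `xtol = 1e-10`; when even a zero-severity
segment cannot reach a near-1 target FFR (taper alone causes a tiny drop),
severity 0 is used and the achieved value is stored as the truth.
Equal-score candidates, ROC ties and vote ties all have stated
deterministic tie-breaks (documented beside each function).

## Known limitations

* The severity→FFR link is a two-term surrogate; rankings among geometric
  features on synthetic data need not match clinical rankings.
* Univariate SVM probabilities come from Platt scaling on small folds and
  can be poorly calibrated; only their ranks and the per-fold balanced
  thresholds are consumed downstream, with isotonic calibration available
  but off by default.
* Wilson intervals are exact for the reported binomial proportions but the
  Hanley–McNeil AUC interval is an approximation that assumes the
  Mann–Whitney variance model.
* With 1 mmHg pressure rounding, labels for lesions within half a unit of
  the 0.80 cutoff can differ from the latent truth; this mirrors the
  instrument granularity rather than a defect.
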