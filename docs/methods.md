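# Methods

## The quantity being measured

Emphysema destroys lung parenchyma, which lowers its CT attenuation
toward that of air (≈ −1000 HU). The standard burden metric is %LAA: the
percentage of lung voxels at or below −950 HU. This package quantifies
%LAA *per lobe* and condenses the upper-vs-lower spatial distribution
into a signed heterogeneity index

    HI = 100 · (V_upper − V_lower) / (V_upper + V_lower)   [percent]

where V_upper and V_lower are LAA **volumes** (ml, not lobe-normalised
percentages). The right middle lobe is counted with the upper zone, so
the zones per scope are: left lung LUL vs LLL; right lung RUL+RML vs
RLL; whole lung LUL+RUL+RML vs LLL+RLL. HI = +100 means all emphysema is
upper-zone, −100 all lower-zone. Two rules force HI to zero: upper and
lower volumes exactly equal (including both zero), and whole-lung %LAA
below 1% — too little disease to localise meaningfully. The <1% gate
uses the whole-lung extent for every scope (a flag switches to per-scope
gating). A subject is "upper dominant" iff HI > 0; HI = 0 is grouped
with lower dominance.

## Densitometry chain and its numerical conventions

1. **Threshold.** A voxel is low-attenuation if HU ≤ −950 and it lies
   inside a lobe label. The comparison is inclusive (≤); a flag gives
   the strict form. Voxels outside the lobe mask (airways, background)
   never count toward either numerator or denominator — the mask defines
   the lung.
2. **Cluster filter.** Image noise produces isolated sub-threshold
   voxels. Connected components are computed strictly in 2D per axial
   slice (8-connectivity by default, configurable), and components with
   in-plane area below 3 mm² (pixel count × pixel area) are discarded.
   Components are never merged across slices. The filter runs after
   thresholding, and no smoothing is applied anywhere; `min_area = 0` is
   the identity. Area exactly equal to the minimum is kept (the rule
   discards *strictly smaller* clusters).
3. **Tallies.** Per-lobe voxel counts and volumes aggregate exactly to
   left lung (LUL+LLL), right lung (RUL+RML+RLL) and whole lung;
   %LAA = 100 × LAA volume / region volume. A lobe absent from the mask
   is reported with an *undefined* (None/NaN) %LAA and flagged, never a
   silent zero.

The ±100 HI boundary is computed exactly in floating point by forming
the volume ratio before scaling by 100.

## Statistical pipeline

Cohorts are analysed separately for COPD (post-bronchodilator
FEV1/FVC < 0.70) and non-COPD subjects.

- **Exclusions.** COPD subjects with a positive bronchodilator response
  — FEV1 increase ≥ 200 ml *and* ≥ 12% of baseline — are removed, then
  subjects with chronic bronchitis or missing CB information. Every
  removal is logged with a reason; disposition counts sum to the input n.
- **GOLD staging** uses the fixed-ratio 0.70 criterion and 80/50/30
  FEV1%-predicted breakpoints; the ratio argument may be given as a
  fraction or a percentage.
- **Descriptives**: median (Q1, Q3) for continuous variables, n (%) for
  categorical ones.
- **Dominance proportion**: one-sample chi-square (1 df) of the HI > 0
  share against 50%.
- **Left–right symmetry**: two-sided sign test on paired HI(left) −
  HI(right), zeros dropped (exact binomial p).
- **Group comparisons** between HI ≤ 0 and HI > 0: Wilcoxon rank-sum
  per lung-function measure — exact null distribution when both groups
  have ≤ 25 tie-free observations, tie-corrected normal approximation
  otherwise — and a Pearson chi-square on the GOLD I–II vs III–IV
  dichotomy *without* continuity correction (a flag enables Yates; the
  uncorrected form is the package default).
- **Piecewise regression** of each outcome on HI with a knot at zero,
  via hinge terms HI⁺ = max(0, HI) and HI⁻ = min(0, HI). Constraining
  the two slopes equal reduces the model to ordinary linear regression
  on HI, exactly. An all-one-sided design is rejected as rank-deficient;
  fewer than 3 subjects on a side is flagged.
- **Adjusted linear models**: OLS of each outcome on LAA%, HI⁺, HI⁻,
  age, male and pack-years; complete cases per model with n reported;
  t-based 95% CIs. No multiple-testing adjustment (two-sided α = 0.05).
- **Logistic severity model**: ML logistic regression of 1{GOLD III–IV}
  on the same covariates; odds ratios with Wald CIs on the log-odds
  scale. Newton is tried first; a singular Hessian falls back to BFGS.
  True separation — constant outcome, non-convergence, or non-finite
  estimates/standard errors — raises a `SeparationError` rather than
  returning a diverged fit. A handful of perfectly predicted
  observations (fitted probability numerically 1) is tolerated as long
  as every coefficient remains identified.

## Synthetic phantoms

`generate_phantom` builds a voxel grid (default 64×64×48 at
0.7×0.7×0.625 mm — in-plane pixel sizes and section thickness typical of
thin-section chest CT) with five disjoint ellipsoidal lobes in plausible
positions (two left, three right, upper superior to lower; overlaps
resolved by normalised ellipsoid distance). Parenchyma HU is Gaussian
(−850 ± 40) truncated above the −950 threshold; emphysema clusters are
in-plane discs spanning 1–3 consecutive slices with log-uniform radii
1–8 mm, filled with Gaussian HU (−980 ± 10) truncated below the
threshold. Discs are inserted per lobe until the thresholded voxel
fraction reaches the target; the last insertions are capped (down to
single voxels) so the achieved fraction lands within ±20% relative of
the target, which is verified and otherwise raised as
`PhantomInfeasibleError` naming the lobe. The radius range deliberately
straddles the 3 mm² filter so sub-filter and supra-filter clusters both
occur; the generator's own tally is the *pre-filter* thresholded count.
All randomness flows from one `numpy` generator seeded by the spec; the
same seed reproduces the volume bit-for-bit. The phantom emulates only
what the downstream chain consumes — attenuation statistics, lobe
identity, cluster geometry. It has no airways, vessels, motion,
reconstruction-kernel or beam-hardening effects, so passing phantom
tests validates the measurement chain, not segmentation or acquisition.

## Synthetic cohorts

`generate_cohort` draws, per stratum (COPD / non-COPD):

- age: normal matched to the stratum median and IQR (67 (61,70) vs
  63 (60,67) years); male fraction 0.65 vs 0.51;
- pack-years and LAA%: lognormal matched to median/IQR (57 (40,77) and
  4.5 (1.5,12.2) for COPD; 45 (32,63) and 0.5 (0.2,1.3) otherwise),
  clipped at 200 pack-years and 60% LAA to keep tails physical;
- HI%: a two-part mixture with 80% mass above zero (truncated normals
  on each side, location 28/scale 20 above, 10/10 below — free knobs of
  the generator, since only the positive-mass fraction is anchored);
  left/right HI are the whole-lung HI plus independent Gaussian scatter
  (SD 8), making left−right differences symmetric about zero.

Each lung-function outcome is intercept + linear predictor + Gaussian
noise, with generating coefficient vectors over (LAA%, HI⁺, HI⁻, age,
male, pack-years) — e.g. FEV1%pred in COPD: (−1.54, 0.28, 0.02, 0.73,
9.53, −0.02). The intercept self-centres so the cohort mean equals the
stratum's anchor median; the residual SD defaults to the SD of the
linear predictor (covariates explain ≈ half the outcome variance) and
can be set per outcome, including 0 for exact noise-free recovery.

GOLD III–IV membership among COPD subjects is a Bernoulli draw from a
logistic model with generating odds ratios (1.28, 0.95, 1.03, 0.88,
0.25, 1.00) per unit of the same covariates; the intercept is solved by
root-finding so the expected severe prevalence is 26%. The drawn
severity determines the stored stage (III/IV split at FEV1%pred 30;
I/II split at 80). Consequently the simulated stage is consistent with
the severity model being recovered, not re-derived from the simulated
spirometry — a deliberate choice so that refitting the logistic model is
a clean parameter-recovery experiment; the spirometric `gold_stage`
operation is validated separately. Likewise the linear outcome models
are not truncated to physical ranges, so OLS refits are unbiased; rare
extreme values are accepted rather than censored.

Pre/post-bronchodilator FEV1 (litres) are derived from FEV1%pred and a
subject-level predicted-normal volume; optional generator rates inject
bronchodilator responders and chronic-bronchitis/missing-CB subjects to
exercise the exclusion stage (defaults 0: the default cohort is the
analytic, post-exclusion population).

## Simulation sizes and known limitations

Replicated-recovery experiments use 500 cohorts of n = 160 COPD
subjects, the scale at which the mean fitted HI⁺ slope (generating
0.28) is recovered well inside Monte-Carlo error and 95% CI coverage is
nominal. The logistic odds ratio is recovered only up to the
finite-sample bias of maximum likelihood: with ≈ 42 events and six
covariates at n = 160 the geometric-mean fitted HI⁺ OR is ≈ 0.94
against a generating 0.95, and the gap closes at larger n (≈ 0.949 at
n = 1600). This is a property of the estimator, not of the simulation;
bias-reduced (Firth-type) fitting would remove it but is not the
estimator the analysis specifies. Replicates where the logistic MLE
does not exist (true separation) are dropped and counted; they are rare
(≲ 1%) at these settings.

Other limitations: lobe geometry is schematic; the cohort generator
produces no missing data by default (real cohorts lose subjects to
missing pack-years and DLco, which the complete-case machinery handles
but the defaults do not exercise); and simulated spirometry is not
forced to satisfy the COPD definition subject-by-subject, so staging
real tables should always go through `gold_stage` rather than trusting
a stored stage.
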