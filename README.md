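# emphyhet

Lobe-wise CT emphysema quantification and heterogeneity analysis.

Emphysema burden on chest CT is conventionally measured as **%LAA** —
the percentage of lung voxels at or below −950 HU — but two lungs with
the same %LAA can distribute the disease very differently between the
upper and lower zones, with different consequences for pulmonary
function. `emphyhet` quantifies %LAA per lobe (after a 3 mm² in-plane
noise-cluster filter) and summarises the spatial distribution with a
signed **heterogeneity index**

```
HI = 100 · (V_upper − V_lower) / (V_upper + V_lower)      ∈ [−100, +100]
```

where V_upper / V_lower are LAA volumes in the upper zone (LUL, RUL,
RML — the right middle lobe counts as upper) and the lower zone (LLL,
RLL). HI = 0 when the volumes are equal or when whole-lung %LAA < 1%.
On top of this imaging metric sits the full cohort analysis: exclusion
rules (bronchodilator response, chronic bronchitis), GOLD staging,
nonparametric dominance comparisons, piecewise linear regression of
lung function on HI with a knot at zero (hinge terms HI⁺ = max(0, HI),
HI⁻ = min(0, HI)), covariate-adjusted multiple linear regression, and a
logistic model for severe (GOLD III–IV) disease.

It is aimed at quantitative-imaging and COPD researchers who want a
tested, scriptable reference implementation of this pipeline. Synthetic
lobe-labeled phantoms and simulated cohorts with known generating
models make every stage verifiable without any patient data; see
`docs/methods.md` for the underlying models and their assumptions.

## Worked example

```python
import emphyhet as eh

# an upper-dominant phantom: per-lobe target LAA fractions
spec = eh.PhantomSpec(
    lobe_laa_fractions={"LUL": 0.15, "LLL": 0.03, "RUL": 0.20,
                        "RML": 0.10, "RLL": 0.02},
    seed=42,
)
vol = eh.generate_phantom(spec)          # HU grid + lobe labels 1-5
quant = eh.quantify_volume(vol)          # threshold, filter, tally
print(quant.to_frame().round(3))
for scope in ("left", "right", "whole"):
    r = eh.compute_hi(quant, scope)
    print(scope, round(r.hi, 1), r.dominance)
```

prints

```
region  voxels  volume_ml  laa_voxels  laa_volume_ml  laa_pct
   LUL   10842      3.320        1627          0.498   15.006
   LLL    9918      3.037         296          0.091    2.984
   RUL    8356      2.559        1665          0.510   19.926
   RML    2449      0.750         245          0.075   10.004
   RLL    8910      2.729         171          0.052    1.919
  left   20760      6.358        1923          0.589    9.263
 right   19715      6.038        2081          0.637   10.555
 whole   40475     12.395        4004          1.226    9.893

left 69.2 upper
right 83.6 upper
whole 76.7 upper
```

Each lobe lands within 20% relative of its target fraction (e.g. LUL
15.0% vs target 15%), aggregates are exactly additive, and the
whole-lung HI of +76.7 reflects the upper-zone concentration: 1.083 ml
of emphysema above vs 0.143 ml below.

The statistical half works on cohort tables (one row per subject):

```python
df = eh.generate_cohort(eh.CohortSpec(seed=1))   # 350 subjects, 160 COPD
copd = df[df.copd == 1]
print(eh.proportion_positive_test(copd.hi_pct).detail)
# {'n_positive': 112, 'proportion': 0.7}    chi-square 25.6, p = 4.2e-07
fit = eh.fit_adjusted_linear(copd, "fev1_pct_pred")
print(fit.table.round(3))
```

```
            estimate  ci_low  ci_high  p_value
const         58.052   0.835  115.270    0.047
laa_pct       -1.469  -1.752   -1.185    0.000
hi_pos         0.086  -0.198    0.371    0.550
hi_neg         0.364  -0.352    1.079    0.317
age            0.437  -0.377    1.251    0.291
male           9.801  -0.923   20.525    0.073
pack_years    -0.052  -0.224    0.121    0.555
```

Overall emphysema (LAA%) is strongly negatively associated with FEV1%
predicted in this single simulated cohort; the HI⁺ slope is one noisy
draw around its generating value of 0.28 (across many replicated
cohorts the mean estimate recovers it — that experiment is what
`scripts/acceptance.py` runs).

The same chain is available from the shell:

```bash
emphyhet simulate-phantom --spec phantom.yaml --seed 42 --out-dir out/
emphyhet quantify out/phantom_image.nii.gz out/phantom_lobes.nii.gz --out quant.csv
emphyhet hi quant.csv --out hi.csv
emphyhet simulate-cohort --seed 1 --out cohort.csv
emphyhet analyze cohort.csv --out-dir analysis/     # table1.csv ... table5.csv
emphyhet run --config config.yaml --seed 1 --out-dir run/
```

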