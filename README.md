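# kneetwin

A tested, reusable implementation of the imaging-biomarker foundation of a
knee-joint digital twin: extraction of quantitative-MRI biomarkers — bone
and meniscus shape, cartilage thickness, cartilage T2 — into a
110-dimensional statistical-shape-model feature space, t-SNE-based cohort
matching, cross-sectional biomarker testing with false-discovery-rate
control, and bootstrap elastic-net stability selection for osteoarthritis
(OA) incidence and knee-replacement outcomes.

The package is aimed at methods researchers in musculoskeletal imaging and
imaging epidemiology who want the full analysis chain runnable and
verifiable without access to clinical MRI: every stage is exercised on
synthetic knee phantoms with analytic ground truth, generated by the
package's own `phantom` module.

## The methods at its core

* **T2 relaxometry.** Per voxel, multi-echo signals follow the
  three-parameter mono-exponential `S(TE) = α·exp(−TE/T2) + C`, fitted by
  Levenberg–Marquardt least squares (a vectorized batch solver makes
  whole-knee maps cheap; the scalar scipy route is kept and cross-checked).
* **Cartilage thickness.** The Euclidean distance transform is read at the
  morphological skeleton of the cartilage mask; thickness = 2·EDT, with the
  boundary taken as the 0.5 level of the trilinearly interpolated mask so
  the estimate is orientation-unbiased to a fraction of a voxel.
* **Statistical shape model.** Masks → marching-cubes surfaces → rigid
  iterative-closest-point registration to a reference knee (chosen by
  registration error) → curvature-weighted landmark matching → PCA per
  tissue–biomarker pair. The grid {femur, tibia, patella} × {bone shape,
  cartilage thickness, cartilage T2} plus {medial, lateral} meniscus ×
  shape, at 10 modes each, yields exactly **110 PC-mode features**.
* **Cohort matching.** Standardized covariates of cases and controls are
  embedded jointly in 3-D t-SNE (perplexity √N); each case is paired with
  the control at minimum embedded Euclidean distance, with replacement.
  Balance is reported as Cohen's d / SMD, point-biserial correlation,
  Wilcoxon signed-rank, and Cramer's V.
* **Cross-sectional testing.** Two-sided Wilcoxon rank-sum per feature,
  Benjamini–Hochberg step-up adjustment across the 110 tests
  (`P′(i) = min_{j≥i} min(1, (m/j)·P(j))`), percentile-bootstrap 95%/99%
  intervals (1000 resamples).
* **Stability selection.** 1000 bootstrap resamples of an
  elastic-net-penalized binomial GLM; a feature is *selected* when
  |coefficient| > 1e-5; weighted importance = selection frequency ×
  |mean coefficient|; features in the upper quartile of importance enter an
  unpenalized final logistic model reporting odds ratios `OR = exp(β)` with
  Wald intervals.

## Worked example

Build a 300-subject synthetic population with three planted shape modes
(score SDs 20, 14, 8), a planted +0.5 SD BMI confounder and an outcome
driven by the first femur shape mode, then run the analysis chain:

```python
import numpy as np, pandas as pd
from kneetwin.phantom import PhantomConfig, sample_landmark_population, make_cohort_table
from kneetwin.shape_model import build_pca
from kneetwin.cohort import (MatchConfig, embed_and_match, balance_report,
                             standardize_covariates)
from kneetwin.crossstats import cross_sectional_tests
from kneetwin.stabsel import StabilityConfig, bootstrap_elastic_net, final_logistic

cfg = PhantomConfig(n_subjects=300, seed=42)
_, mats = sample_landmark_population(cfg)
model = build_pca(mats["femur"], n_modes=10, tissue="femur",
                  biomarker="bone_shape", subject_ids=list(range(300)))
print("femur shape PCA mode SDs:", np.round(model.mode_sds[:4], 2))
print("explained variance fractions:",
      np.round(model.explained_variance_fractions[:4], 3))

feats = pd.DataFrame(model.scores,
                     columns=[f"BoneShape_Femur_PC{i+1}" for i in range(10)],
                     index=pd.Index(range(300), name="subject_id"))
table, truth = make_cohort_table(cfg, feats, beta={"BoneShape_Femur_PC1": 0.05},
                                 confounder_shift={"bmi": 0.5}, seed=42)
print("outcome prevalence:", round(table["outcome"].mean(), 3))

std = standardize_covariates(table, ["age", "bmi", "pain"],
                             ["sex", "race", "injury_history"])
cases = list(table.index[table["outcome"] == 1])
controls = list(table.index[table["outcome"] == 0])
mr = embed_and_match(std, cases, controls, MatchConfig(seed=42))
bal = balance_report(table, mr, ["age", "bmi", "pain"], ["sex"])
print("BMI Cohen's d pre -> post:",
      round(bal.continuous.loc["bmi", "pre_cohens_d"], 3), "->",
      round(bal.continuous.loc["bmi", "post_cohens_d"], 3))

matched = pd.concat([table.loc[mr.pairs["case_id"]],
                     table.loc[mr.pairs["control_id"]]])
res = cross_sectional_tests(matched, list(feats.columns), n_boot=200, seed=42)
print(res[["statistic", "p_raw", "p_adjusted", "tier"]].head(2))

X = (feats - feats.mean()) / feats.std()
sr = bootstrap_elastic_net(X, table["outcome"].to_numpy(),
                           StabilityConfig(n_boot=200, seed=42))
print(sr.table.sort_values("importance", ascending=False).head(2).round(4))
retained = sr.table.index[sr.table["retained"]].tolist()
fm = final_logistic(X[retained], table["outcome"].to_numpy())
print(fm.table.loc[retained[:1], ["coef", "se", "p", "odds_ratio"]].round(4))
print("pseudo R2:", round(fm.pseudo_r2, 4))
```

which prints:

```text
femur shape PCA mode SDs: [20.17 12.56  7.86  0.  ]
explained variance fractions: [0.65  0.252 0.099 0.   ]
outcome prevalence: 0.29
BMI Cohen's d pre -> post: 0.485 -> 0.148
                     statistic         p_raw  p_adjusted tier
BoneShape_Femur_PC1     9319.0  2.821953e-07    0.000003  ***
BoneShape_Femur_PC2     7396.0  5.155966e-01    0.729778   ns
                     frequency  mean_coefficient  importance  retained
BoneShape_Femur_PC1      1.000            1.0078      1.0078      True
BoneShape_Femur_PC3      0.960           -0.2051      0.1969      True
                       coef      se       p  odds_ratio
BoneShape_Femur_PC1  1.1034  0.1722  0.0000      3.0143
pseudo R2: 0.1577
```

Reading it: PCA recovers the three planted deformation modes (SDs
20.2/12.6/7.9 vs 20/14/8; a fourth mode carries nothing). The planted 0.5 SD
BMI imbalance shrinks to 0.15 after t-SNE matching. The rank-sum stage
flags exactly the outcome-driving mode after BH adjustment (`***`), stability
selection ranks it first with selection frequency 1.0, and the final
logistic model estimates OR ≈ 3.0 for one SD of that mode — consistent with
the planted log-odds coefficient.

A thin CLI covers batch use: `kneetwin simulate`, `kneetwin t2`,
`kneetwin thickness`, `kneetwin match`, `kneetwin select` (see `--help`).

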