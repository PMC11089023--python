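# ecvrisk

Tools for a CT-derived **extracellular volume (ECV) fraction** imaging
biomarker and a **points-based progression risk score** in locally advanced
pancreatic cancer (LAPC) treated with intraoperative radiotherapy (IORT),
together with the survival-analysis machinery needed to build and validate
such scores (Cox regression → Sullivan points → maxstat cutoff →
time-dependent ROC and calibration).

Intended users: imaging researchers and biostatisticians prototyping or
stress-testing ECV-based prognostic scores on synthetic phantoms and
simulated cohorts, or applying the shipped scoring table to their own
tabular cohorts.

## The model

**ECV mapping.** On voxel-aligned unenhanced (N) and portal-venous-phase
(PVP) CT volumes, per-voxel tissue ECV is

```
ECV = (1 − hematocrit) · (ΔHU_tissue / ΔHU_aorta) · 100 %
```

with `ΔHU = PVP − N` attenuation and `ΔHU_aorta` the mean enhancement over
an aortic blood-pool mask. The tumor value is the mean over the VOI
segmentation (averaged across readers; Dice quantifies segmentation
agreement).

**Risk score.** Four predictors of progression-free survival (PFS) are
combined into integer points: CA19-9 non-response (+2), rim enhancement
(+1), peripancreatic fat infiltration (+1), and the ECV category
(≥ 20 % → −2, 16–20 % → 0, < 16 % → +1; higher ECV is protective). Totals
range from −2 to 5; a total ≥ 2 is high risk. The generic Sullivan
construction (`points = round(β·(value − value_ref)/B)` from Cox
coefficients) is provided for building new tables.

**Survival evaluation.** Kaplan–Meier / log-rank / Cox (Efron ties) via
lifelines; time-dependent cumulative/dynamic AUC with IPCW via
scikit-survival; maximally-selected-rank-statistics cutpoint search with a
seeded permutation p-value, bootstrap calibration curves and horizon
classification metrics (exact Clopper–Pearson CIs) implemented here.

**Synthetic data.** Spherical-region CT phantoms with analytically known
ECV, and survival cohorts simulated from a Weibull proportional-hazards
model whose defaults are the published covariate prevalences, hazard ratios
(2.058 rim, 1.612 fat, 1.594 CA19-9 non-response, 0.941 per % ECV) and
3/6/12-month marginal PFS anchors (88.3 / 52.4 / 20.4 %).

## Worked example

```python
import numpy as np
from ecvrisk import *

# 1. phantom -> ECV recovery
p = generate_phantom(PhantomSpec(noise_sd=2.0, seed=1))
delta = compute_delta_hu(p.pair)
d_aorta = blood_pool_delta(delta, p.aorta_mask)          # 99.89 HU
ecv = compute_ecv_map(delta, d_aorta, 0.40)
mean_ecv_in_voi(ecv, p.tumor_mask)                       # 18.10 % (truth 18.0 %)

# 2. score a patient
total_score({"ca199_responder": 0, "rim_enhancement": 1,
             "fat_infiltration": 1, "ecv_pct": 15.9})
# RiskAssessment(per_feature={'ca199_responder': 2, 'rim_enhancement': 1,
#                'ecv_pct': 1, 'fat_infiltration': 1}, total=5, risk_class='high')

# 3. simulate a cohort and evaluate the score
df = generate_cohort(default_cohort_spec(300, seed=7))
data = SurvivalData.from_frame(df)
scores = np.array([total_score(r).total for r in
                   df[["ca199_responder", "rim_enhancement",
                       "fat_infiltration", "ecv_pct"]].to_dict("records")], float)
high, low = data.subset(scores >= 2), data.subset(scores < 2)
km_estimate(high).median, km_estimate(low).median        # 5.47 vs 8.74 months
logrank_test(high, low)                                  # chi2 = 51.48, p < 1e-12
time_dependent_auc(scores, data, 6.0).auc                # 0.683
maxstat_cutpoint(scores, data, n_perm=199, seed=1).cutpoint   # 2.0
```

High scorers progress roughly twice as fast as low scorers, the score
discriminates 6-month progression (AUC ≈ 0.68 at this cohort size), and the
outcome-driven cutpoint search rediscovers the shipped cutoff of 2 points.

The `ecvrisk` command exposes the same pipeline from the shell
(`ecvrisk simulate | ecv-map | score | evaluate | run`).

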