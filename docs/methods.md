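# Methods

## ECV estimation from dual-phase CT

Tissue extracellular volume fraction is estimated from conventional
contrast-enhanced CT as

ECV = (1 − Hct) · (ΔHU_tissue / ΔHU_aorta) · 100 %,

where ΔHU is the portal-venous minus unenhanced attenuation and the aortic
blood pool supplies the enhancement reference. The model assumes the
contrast agent has equilibrated between plasma and the extravascular
extracellular space at the portal-venous delay, that both phases are
voxel-aligned, and that the hematocrit converts blood enhancement to plasma
enhancement. Consequences for the implementation:

* **Alignment is a precondition, not a step.** Deformable registration
  belongs to upstream tooling; the package validates grid shape and affine
  metadata and refuses mismatches. A rigid whole-voxel translation utility
  (`apply_misregistration`) exists solely to probe the sensitivity of ECV
  recovery to residual phase mismatch.
* **Blood-pool summary** defaults to the mean over the aorta mask (median
  available). A non-positive aortic enhancement is rejected outright: it
  indicates a protocol failure, not a computable input.
* **No clipping or denoising.** Per-voxel ECV outside [0, 100] % is
  physically impossible but numerically informative (noise, vessels,
  mis-segmentation), so such voxels are flagged and preserved rather than
  altered.
* **Hematocrit units.** Fractions in [0, 1) are expected; values in
  (1, 100] are interpreted as percentages and divided by 100 with a
  warning, since both conventions circulate in clinical exports.
* Linearity: multiplying all enhancements by a common factor leaves the map
  unchanged, which the tests assert; this is what makes the ratio robust to
  injection-rate and scanner-output differences to first order.

## Risk score

The shipped table assigns CA19-9 non-response +2, rim enhancement +1,
peripancreatic fat infiltration +1, and ECV category ≥ 20 % / 16–20 % /
< 16 % → −2 / 0 / +1; totals span −2…5 and ≥ 2 points is high risk. The
"16–20 %" bin is implemented as the half-open interval [16, 20) so the
three bins partition the axis, with 20 % falling in the "≥ 20 %" category.

The table is shipped verbatim rather than re-derived. A Sullivan
construction (points = round(β·(value − value_ref)/B) for base increment
B > 0) is provided for building candidate tables from Cox coefficients, but
no single B reproduces the shipped points from the published coefficients
(non-response β ≈ 0.466 carries 2 points while rim β ≈ 0.722 carries 1), so
re-derivation is not treated as a ground truth anywhere. Rounding is
half-away-from-zero — the tie rule is rarely stated in the score-building
literature, so it is fixed and documented here; continuous-feature
categories are represented by bin midpoints by default.

CA19-9 response means a decline of **strictly more than** 50 % from
baseline or a post-treatment value **strictly below** the 37 U/mL normal
limit; both boundary readings follow the literal clinical wording, and
records with baseline ≤ 37 U/mL are rejected as ineligible rather than
classified.

## Survival machinery

* **Cox fits** use lifelines' partial-likelihood maximization with the
  Efron tie correction (the sensible default for continuous simulated
  times with occasional ties).
* **Time-dependent ROC** is the cumulative-cases / dynamic-controls AUC
  with inverse-probability-of-censoring weights from the censoring
  Kaplan–Meier (scikit-survival's `cumulative_dynamic_auc`); the
  incident/dynamic variant is out of scope. Without censoring this reduces
  exactly to the Mann–Whitney AUC of cases vs controls, which a test
  verifies against `scipy.stats.mannwhitneyu`.
* **Maxstat cutpoint.** Candidate cuts are midpoints between consecutive
  distinct score values whose left-group proportion lies inside the
  (0.10, 0.90) quantile window (the conventional maxstat default). For each
  candidate the standardized two-group log-rank statistic |O−E|/√V is
  computed by a vectorized risk-set tabulation over all candidates at once;
  the reported cutpoint is the smallest observed value above the selected
  midpoint, so strata are {score ≥ cut} vs {score < cut}. Inference uses a
  seeded permutation of score labels (p = (1+exceedances)/(n_perm+1)), an
  exact Monte-Carlo test, in place of improved-Bonferroni approximations.
* **Calibration** bins patients by quantiles of predicted survival
  (empty bins collapse with a warning), compares the bin-mean prediction to
  the within-bin Kaplan–Meier estimate at the horizon, and attaches
  percentile bootstrap CIs over patient resamples; `n_boot = 0` yields
  point estimates only. Deterministic given the seed.
* **Horizon classification metrics** treat "progression-free at the
  horizon" as the positive class; subjects censored before the horizon are
  unclassifiable and are excluded with their count reported. Proportion CIs
  are exact Clopper–Pearson, matching the exact-style intervals typically
  reported with such tables.
* **Median survival** is reported as not reached (infinity) when the curve
  never crosses 0.5 — never extrapolated.

## Synthetic-data generator

**Phantoms** are spherical tumor and aorta regions on a uniform background,
with per-region enhancement added to the portal-venous phase and optional
additive Gaussian HU noise drawn independently per phase. The per-voxel
ground-truth ECV is known analytically, so noiseless recovery must be exact
(asserted at 1e−9). Phantoms emulate the *arithmetic* of ECV mapping only —
no anatomy, partial-volume effects, beam hardening or contrast kinetics —
so passing phantom tests validates the computation, not clinical image
quality.

**Cohorts** draw binary covariates independently at prevalences 37/103
(rim enhancement), 41/103 (fat infiltration) and 39/103 (CA19-9
non-response), ECV from a normal with mean 19.1 % and sd (23.3−14.7)/1.349
≈ 6.37 % (sd recovered from the interquartile range) truncated to
[0, 60] %, and event times from a Weibull proportional-hazards model with
log-hazards ln 2.058, ln 1.612, ln 1.594 and ln 0.941 per % ECV. Covariates
are simulated independently because no correlation structure is published.
Censoring defaults to none (the reference cohort observed progression in
every patient); administrative censoring at a fixed time is available for
exercising censoring-aware statistics.

The **baseline hazard** is a two-parameter Weibull fitted by least squares
of log(−log S) on log t to the printed marginal PFS anchors S(3) = 0.883,
S(6) = 0.524, S(12) = 0.204 (giving k ≈ 1.84, λ ≈ 8.71 months). The linear
predictor is centered at the population covariate means (prevalences; ECV
mean) so that the baseline describes an average patient; with the default
coefficients this leaves the simulated marginal median PFS near the
anchors' implied median (≈ 6.9 vs 6.40 months, inside the ±0.8-month band
the dispersion of the linear predictor permits). Without centering, the
strongly protective ECV term would shift the marginal median by several
months and the anchors would no longer describe the cohort.

## Problem sizes and numerical choices

Simulation-based checks use the sizes at which their tolerances are
well-separated from Monte-Carlo noise: n = 5000 for Cox coefficient
recovery (HR standard errors ≈ 3 %, tolerances 10 %, 2 % for the per-%
ECV effect), n = 50 000 for the marginal-median check (±0.8 months),
100 replicates of n = 300 for changepoint recovery, 100 null datasets ×
199 permutations for the maxstat type-I check, and 200 cohorts of n = 500
for Cox CI coverage (93–97 % band). All stochastic procedures take
explicit integer seeds; pipeline runs derive per-stage seeds from one root
seed via `numpy.random.SeedSequence`, and identical configurations
reproduce output files byte-for-byte.

## Known limitations

* Tabular inputs only for the cohort side; imaging inputs are NIfTI (no
  DICOM ingestion) and must be pre-registered.
* Single-measure absolute-agreement ICC(2,1) is the only ICC form exposed;
  the agreement interpretation bands reproduce the conventional printed
  bands, mapping the (0.20, 0.21) gap to "fair".
* No competing risks, time-varying covariates or overall-survival
  endpoints; proportional hazards is assumed, not diagnosed.
* The cohort generator reproduces published *marginals* (prevalences,
  hazard ratios, survival anchors); joint covariate structure, measurement
  error in ECV, and inter-scanner variation are not modelled, so
  simulation-based validation speaks to the statistical machinery, not to
  clinical transportability.
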