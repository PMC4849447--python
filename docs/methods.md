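# Methods

This note documents the models, estimators, numerical choices and known
limitations of `fcbwas`.  Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Synthetic cohort model

The generator produces the data structure a multi-site case–control
resting-state study assumes, with analytically controlled moments.

**Connectivity target.**  For subject *s* at site *k*, the target
Fisher-z connectivity of link (a, b) is

    z_ab(s) = z0 + u_ab(k) + Σ_c β_c (x_c(s) − x̄_c) + 1[s is patient]·δ_ab

with baseline `z0 = 0.1`, per-site symmetric link offsets
`u(k) ~ N(0, σ_site²)` (σ_site = 0.1), covariate coefficients β on age,
sex, antipsychotic dose and mean framewise displacement, and planted
group shifts δ on the effect links only.  Defaults plant ten links of
|δ| = 0.3 with alternating sign on one hub region — the mixed
increase/decrease pattern a dysconnectivity hub exhibits.  δ is a
calibration choice in Fisher-z units (no published effect sizes exist
on this scale); 0.3 with 40+40 subjects per site gives per-site t ≈ 10,
i.e. a strong, unambiguous benchmark for recovery tests.

**Sampling.**  The target correlation matrix is `C = tanh(Z)` with unit
diagonal.  Region series are obtained by Cholesky mixing,
`x_t = L ε_t` with `LLᵀ = C`, which makes the *expected* sample
correlation equal C exactly up to the O(1/T) bias of the empirical
correlation; subject-level variability in measured z then arises from
finite sampling (SD ≈ 1/√(T−3) per link at T = 150 timepoints).
Temporal autocorrelation is added by an AR(1) recursion on the mixed
innovations, `x_t = φ x_{t−1} + √(1−φ²) L ε_t` (default φ = 0.3, 50
burn-in samples), whose variance-preserving scaling leaves the lag-0
cross-correlation untouched.  If a requested configuration yields an
indefinite C (possible for extreme effect maps), eigenvalues are
clipped at 1e-8 and the matrix renormalized to unit diagonal; default
configurations never trigger this path.

**Voxel level.**  The grid (default 12×12×12 voxels at 3 mm) is tiled
into equal near-cubic blocks, one per region; a voxel's series is its
region's series plus independent N(0, 1) noise.  This is a desk-scale
stand-in for a 47,636-voxel brain with 90 anatomical regions: the
statistics are exercised at full fidelity while link counts stay in the
hundreds (351 region links) instead of 10⁹.

**Phenotypes.**  Age uniform within site-specific ranges, sex
Bernoulli(½), dose gamma(2, 1.5) in 100-mg chlorpromazine-equivalents
for patients (0 for controls), motion half-normal (σ = 0.15 mm), PANSS
subscales and illness duration drawn at realistic scales for patients
and missing for controls.  An optional coupling rewrites a symptom
score so that, within each site, patients' scores correlate at a chosen
r with the realized Fisher-z of a chosen link (used by power tests).

**Determinism.**  Per-subject random streams are keyed by
(seed, site index, subject slot), so enlarging a site never reshuffles
existing subjects.  Same seed ⇒ bit-identical cohorts.

**What the generator does not emulate** — hemodynamic response shape,
physiological noise and scanner artefacts, spatial autocorrelation
beyond region membership, eyes-open/closed protocol differences, and
non-Gaussian heavy-tailed motion.  Passing tests therefore demonstrate
the correctness and calibration of the *statistics*, not robustness to
every real-data pathology.

## Preprocessing

Order: linear detrend → band-pass → spatial smoothing → nuisance
regression → scrubbing.

- **Motion exclusion**: a subject is excluded if any between-volume
  parameter change exceeds 3 mm translation or 3° rotation (strict
  inequality; an `absolute` mode screens raw excursions instead — the
  between-volume reading is the default because the criterion names
  motion *between volumes*).
- **Band-pass** (default 0.01–0.08 Hz): zero-phase forward–backward
  Butterworth of order 4 whose design corners are pre-shifted so the
  *two-pass* response is 3 dB down at the nominal band edges.  A plain
  order-2 two-pass design sags to 0.69 amplitude at 0.07 Hz, which
  would attenuate genuine low-frequency signal near the band edge; the
  compensated order-4 design measures ≥ 0.95 across 0.02–0.07 Hz and
  ≤ 0.006 at 0.005 and 0.15 Hz.  Filter quality is asserted on the FFT
  bin of sinusoidal probes, since filtfilt edge transients contaminate
  time-domain maxima.
- **Smoothing** (default FWHM 8 mm): Gaussian with
  σ = FWHM/(2√(2 ln 2)) per axis, converted to voxels via the affine.
- **Nuisance regression**: residualization against motion parameters
  and global/WM/CSF-style regressors plus intercept; regressors are
  band-passed identically first so the regression cannot reintroduce
  out-of-band variance.  Rank deficiency is reported naming the
  collinear columns.
- **Scrubbing**: framewise displacement (Power convention, rotations
  converted on a 50 mm sphere) > 0.5 mm censors the spike plus one
  volume back and two forward (configurable); censoring everything is
  an error, not an empty matrix.

## Link-wise statistics

**Within-site test.**  One linear model per link,
`z ~ intercept + group + covariates`; the group coefficient is the
covariate-adjusted patient−control mean difference, its squared SE the
effect variance passed to the heterogeneity stage (with no covariates
these equal the classic mean difference and pooled-variance formula
exactly, and the t equals the textbook pooled two-sample t).  The
two-tailed p is converted to a **signed** z = sign(t)·Φ⁻¹(1 − p/2).
The unsigned textbook conversion Φ⁻¹(1 − p) produces the same |z| but
discards direction, which the downstream increased/decreased claims
need; an `unsigned=True` switch reproduces the literal formula.
p-values are floored at 1e-300 before quantile inversion.

**Meta-combination.**  `Z = Σ w_i z_i / √(Σ w_i²)`.  Default weights
√n_i (site sample size n_i), the standard sample-size weighting for
which Z is exactly N(0,1) under the null; `weights="n"` is available.
Z is scale-invariant in the weights, reduces to the single-site z for
k = 1, and any non-finite site z marks the link missing rather than
silently dropping a site.  Combined p = 2(1 − Φ(|Z|)), Bonferroni
threshold = family α / number of links.

**MA and clusters.**  MA(i) = #{j : p_ij < α_bonf}; the counts satisfy
Σ MA = 2·(significant links) exactly.  Cluster extraction takes
connected components (26-connectivity default; 6/18 available) of
voxels with MA ≥ 1, discards components below 20 voxels, sorts by peak
MA and reports peaks in mm via the affine.  In the region-level
pipeline the MA counts are painted onto the atlas volume before
clustering.

**Heterogeneity.**  Cochran's Q with fixed-effect weights 1/v_i and a
χ²_{k−1} reference; heterogeneous ⇔ q_p < 0.05.  Random effects use
the DerSimonian–Laird moment estimator
τ² = max(0, (Q − (k−1)) / (Σu − Σu²/Σu)), re-pooling with weights
1/(v_i + τ²).  τ² truncates to exactly 0 when Q ≤ k−1, making RE
collapse to fixed-effect pooling.  DL was chosen over REML/Paule–Mandel
as the standard closed-form moment estimator; the non-goals exclude
meta-regression.

**Clinical correlates.**  Patients only.  Partial correlation = Pearson
correlation of the residuals of both variables on site dummies +
intercept; p from t = r√(df/(1−r²)) with df = n − n_sites − 1.  Sites
with fewer than two patients are dropped with a warning; missing scores
are dropped per variable (a site without symptom ratings simply
contributes nothing to those families).  BH step-up is applied per
clinical variable (each variable's links form one family; a single
global family is available) — the per-variable family mirrors the
one-column-per-variable layout of the clinical table this analysis
produces.

**Classification.**  Linear SVM, C = 1, features z-scored with
statistics of the training fold only; LOOCV decision values pooled for
the ROC (trapezoid AUC, identical to Mann–Whitney U/(n₁n₂)); best
cutoff by Youden's J.  Permutation p = (1 + #{perm ≥ observed})/(B+1)
with wholesale label permutation and the full LOOCV re-run per
permutation.  The default protocol takes the altered-link set as given
(selected on the full sample by the BWAS) — the classical circularity
of this design is deliberate and documented; a leakage canary test
(pure noise, p ≫ n) verifies that the *cross-validation itself* does
not leak.  Pooled multi-site runs site-mean-center the features first.

## Numerical choices

- Correlations are clipped to ±(1 − 1e-7) before `atanh`, so degenerate
  node pairs give z ≈ 8.1 instead of ∞; `corrcoef` output is
  symmetrized to remove last-bit asymmetry before transforming.
- Link storage is always the strict upper triangle, 0-based, row-major;
  `link_index`/`link_pair` are exact for arbitrary n via integer
  arithmetic (`isqrt`), verified at the 47,636-node scale.
- Voxel-scale link vectors are computed in row blocks against the
  standardized series and never materialize the full node×node matrix.
- The FDR-control acceptance check compares the 1,000-replicate
  empirical false-discovery proportion against the upper 99.9% binomial
  band around q = 0.05, because under the full null BH's true FDR
  *equals* q and the bare sample mean exceeds it half the time.

## Problem sizes

Default test and acceptance runs use 3 sites × 80 subjects, 27 regions
(351 links), 150 timepoints; generator moment checks use 220 subjects
at one site; Q calibration uses 5,000 simulated links; FDR calibration
1,000 replicates of 30 links × 80 patients; classifier null calibration
20 replicates × 99 permutations at n = 30.  These sizes were chosen so
each statistical check has conventional power while the whole suite
remains a desk-scale computation.

## Known limitations

- Voxel-level BWAS is exercised at toy grid sizes; the blocked link
  computation is the scalable path but no out-of-core accumulation is
  implemented.
- The per-site linear model assumes homoscedastic Gaussian residuals in
  Fisher-z units; heavy-tailed connectivity would call for robust
  alternatives.
- Dose enters linearly; nonlinear or cumulative-exposure medication
  effects are out of scope.
- The random-effects z uses a normal reference (no Knapp–Hartung
  adjustment), anticonservative at very small k.
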