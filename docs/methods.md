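# Methods

## The model

`remcm` implements receptor-enriched multifactorial causal modeling: a
per-subject, locally linear, time-invariant dynamical description of six
imaging-derived biological factors (gray-matter density GM, fALFF,
DAT-SPECT uptake, FA, MD, t1/t2 ratio) on a fixed brain parcellation.
For a subject and target factor *m*, the regional rate of change

    dS_mi/dt = sum_n (a0_nm + sum_k ak_nm r_ki) S_ni
               + sum_k ak_m r_ki + aprop_m p_mi + c_m

is regressed on, where `r_ki` are z-scored receptor densities (15
receptors), `p_mi = sum_j C_ij (S_mj - S_mi)` is symmetric connectome
propagation, and `c_m` an intercept.  The rate target is the forward
difference between consecutive visits divided by the inter-visit time;
predictor states are evaluated at the interval's start visit (the text
leaves the evaluation point open; the forward-difference convention makes
the regression coincide with a one-step discrete-time model, see below).

Counting terms: 6 direct factor effects, 6x15 receptor-factor
interactions, 15 direct receptor effects, 1 propagation coefficient and 1
intercept give **113 parameters per factor model** and 678 per subject;
the neuroimaging-only restricted model keeps 8 (6 direct + propagation +
intercept) and a single-receptor model 15.  The printed per-factor count
of the source framework only balances if the intercept is included, which
is the reading adopted here.

All non-intercept design columns are standardized (mean 0, population SD
1) within each subject x factor model, so coefficients are relative
effect sizes; de-standardized coefficients (`params_raw`) are also stored
for comparison against generative dynamics.  Columns that are constant or
pairwise collinear beyond |r| > 0.9999 are pruned with zero-filled
coefficients.  R^2 uses the subject-wise mean rate pooled over all
regions and intervals as reference and is stored unclipped (it can be
negative for pathological fits).

### Normalization conventions

* Imaging: each modality is z-scored with mean/SD pooled over all
  regions, visits and subjects (preserving between-subject severity
  differences); a per-subject switch exists.  Population (divide-by-n) SD
  throughout.
* Receptors: each receptor column z-scored across regions.
* Missing imaging values are rejected (imputation is out of scope);
  missing clinical scores are allowed and slopes use available visits.

## Validation machinery

* **Nested F-test** of the 113- vs 8-parameter model on identical rows.
* **Permuted-map test**: receptor densities shuffled across regions
  independently per receptor; the full model is refitted through the
  identical design-assembly path and the one-sided add-one p-value
  compares the true-map R^2 to the null distribution (default 1000
  permutations, configurable).
* **Fisher's method** combines subject-level permutation p-values per
  factor (chi^2 = -2 sum ln p, df = 2n).
* **Stability**: per coefficient, the across-subject mean's confidence
  interval (t-interval default, percentile bootstrap optional); stable
  means the CI excludes zero.  Effect shares are mean |coefficient|
  fractions among a factor's stable parameters, grouped by receptor
  family via a versioned YAML map.  No multiple-testing correction is
  applied across the 678 parameters at this stage — deliberately, and
  stated loudly.
* **Latent axes**: mechanism matrix X (subjects x 678 coefficients) and
  symptom matrix Y (subjects x 11 clinical decline slopes) are
  residualized on [1, age, education, sex] and z-scored; C = X'Y/(n-1) is
  decomposed by SVD.  Covariance explained uses squared singular values
  (s_k^2 / sum s^2; the linear convention is available by option).
  Significance: subject-correspondence permutations with orthogonal
  Procrustes alignment computed on the well-conditioned symptom side and
  applied to both sides; family-wise correction by the max aligned null
  singular value.  Stability: subject bootstrap with the same alignment,
  percentile CIs and bootstrap ratios (capped at 1e6 for degenerate
  loadings).
* **Influence maps**: per receptor x factor, single-receptor and
  restricted models are fitted for every subject; internally studentized
  residuals are pooled per region and the Wilcoxon rank-sum of the
  restricted model's |residuals| in the combined sample measures local
  improvement.  The null comes from region-shuffled receptor maps
  (restricted-model residuals are computed once and reused); the map
  stores z-scores against the null and flags one-sided empirical
  P < 0.05.

## Synthetic cohorts

The generator produces what the analysis assumes: ring-lattice correlated
Gaussian receptor maps (column z-scored; neighbor correlation =
`smoothness`, default 0.3), a symmetric log-normal-weight connectome
(edge density 0.3, rescaled to unit maximal nodal strength — connectome
units are arbitrary and a bounded graph Laplacian keeps propagation on
the same footing as local couplings), sparse population dynamics
(self-decay -0.3 always present, 15 further mechanisms per factor with
magnitudes 0.17-0.35 and random sign, small intercept drift), and
longitudinal trajectories from standard-normal baselines.

Between-subject coefficient deviations are **low-rank plus noise**: five
shared variation modes (per-coefficient scale 0.1) with standard-normal
subject scores plus i.i.d. jitter (SD 0.03).  Fitted mechanism matrices
of real cohorts are strongly correlated across coefficients; fully
isotropic 678-dimensional variation would put the permutation-null
singular value at the theoretical ceiling of the signal, making any
mechanism-symptom axis undetectable at realistic cohort sizes.  The
first two modes (normalized) are the planted mechanism loadings; clinical
decline slopes are standardized latent scores times axis strengths
(default 4 and 2, i.e. strong planted axes) mapped through orthonormal
symptom loadings, plus slope noise (SD 0.3).  Scores are exactly linear
in time so two visits recover the slopes.

Two integration modes and two noise placements:

* **continuous** (`euler_dt=0.01` y): explicit Euler on the differential
  equation.  The forward difference between visits then equals the
  *time-averaged* right-hand side, which differs from the regression
  model's instantaneous RHS by a term of order the inter-visit gap
  (~0.5 y) — a deliberate model-mismatch regime for robustness studies.
* **discrete-exact** (`euler_dt=None`): one Euler step per inter-visit
  interval, so the generative map and the regression model coincide.
  Estimator-recovery and test-calibration studies use this mode: recovery
  of generating coefficients is only defined when the generative and
  statistical models agree.
* **visit noise** (default, SD 0.1): i.i.d. Gaussian observation noise
  per recorded visit.  Consecutive finite-difference rows then share an
  endpoint (MA(1) errors) and receptor columns repeat across intervals,
  making the nested F-test structurally conservative.
* **process noise**: Gaussian noise injected into the dynamics between
  recordings.  Regression errors are i.i.d. given the predictors and
  the permutation test is exact at any noise level.

Stability guards: a per-step update-norm check (rescales dynamic
coefficients, logged) and a horizon-growth guard that adds self-decay
(an exact diagonal shift of the operator, recorded in the ground truth)
whenever any subject's dominant eigenvalue would grow states beyond e^1
over the visit horizon — keeping simulated pathology on the O(1) scale of
z-scored imaging.  Default observation noise 0.1 was chosen to reproduce
the qualitative full-vs-restricted explained-variance gap seen with real
data (full R^2 ~ 0.97, restricted ~ 0.65 on the default fixture).

The default fixture uses 20 subjects, 40 regions and 5 half-yearly
visits: 160 design rows, the smallest round size that identifies the
113-column model with margin.  (Thirty regions x three intervals — a
surface reading of small-fixture sizes — gives 90 rows and is not
identifiable.)  Recovery studies run at the real template's scale of 95
regions with 3 intervals (285 rows).

## Calibration findings worth knowing

* The nested **F-test is exactly calibrated only under strict
  exogeneity**.  With noise in the states (either placement), past noise
  re-enters later predictors (lagged-state feedback), and at realistic
  noise (SD 0.1) the test over-rejects (~15% at nominal 5% on one-factor
  nulls); at SD 0.01 the size is nominal.  The calibration study
  therefore runs in the small-noise regime; the inflation at larger noise
  is a property of pooled finite-difference regressions, not of the
  implementation.
* The **permuted-map R^2 test is exact by exchangeability** at any noise
  level and any model mismatch, as is the influence-map null.
* At the 160-row desk fixture the 113-parameter model partially overfits
  even permuted maps, so per-fit permutation power is limited there
  (median p ~ 0.06); at the 95-region study scale the same test is
  decisive (median p = 0.01).

## What the synthetic tests do and do not show

Passing tests demonstrate internal consistency: the estimator recovers
the dynamics that generated the data, the permutation machinery holds its
size, planted low-rank mechanism-symptom structure and planted regional
receptor pathways are found.  They do not validate the biological model
against real data: real imaging noise is neither i.i.d. nor Gaussian,
real receptor templates carry spatial autocorrelation that the
region-shuffling null deliberately ignores, regions have geometry and
hemispheric symmetry the ring lattice lacks, and real cohorts have
missing visits and modalities (out of scope here).

## Numerical choices

* OLS via `numpy.linalg.lstsq`; residual orthogonality checked in tests
  against statsmodels as an independent oracle.
* Population-SD z-scoring everywhere; tolerance 1e-8 on normalized
  moments.
* Collinearity pruning threshold 0.9999 (pairwise correlation), first
  column kept.
* Add-one convention for all permutation p-values; empirical one-sided
  tails.
* Internal (not jackknife) studentization; rows with leverage >= 1-1e-8
  fall back to plain z-scoring.
* Bootstrap resamples with fewer than 3 distinct subjects are redrawn and
  logged; bootstrap ratios capped at 1e6.
* Ties in rank statistics get midranks; an all-tied region returns the
  null-mean statistic.

## Known limitations

Regularization, mixed-effects pooling, time-varying coefficients,
spatial-autocorrelation-preserving nulls and out-of-sample symptom
prediction are out of scope.  The directed propagation variant is not
implemented: symmetric connectivity is assumed throughout.
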