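# remcm — receptor-enriched multifactorial causal modeling

`remcm` models how multiple imaging-derived biological factors of a
degenerating brain — gray-matter density (GM), resting-state activity
(fALFF), dopamine-transporter availability (DAT-SPECT), directed and
undirected white-matter microstructure (FA, MD) and dendritic density
(t1/t2 ratio) — reshape each other over time, and how much of that
reshaping is mediated by the local density of 15 neurotransmitter
receptors.  It is aimed at researchers analysing longitudinal,
multimodal regional imaging of neurodegenerative cohorts (the motivating
application is Parkinson's disease) together with a receptor atlas, a
tractography connectome and clinical assessments.

## The model

For each subject and target factor *m*, the regional rate of pathology
change is a locally linear, time-invariant dynamical system

```
dS_mi/dt = Σₙ (α₀ⁿ→ᵐ + Σₖ αₖⁿ→ᵐ r_ki) S_ni      direct + receptor-mediated
         + Σₖ αₖᵐ r_ki                           local receptor effects
         + α_prop ᵐ Σⱼ C_ij (S_mj − S_mi)        connectome propagation
         + cᵐ
```

with `r_ki` the z-scored density of receptor *k* at region *i* and `C`
a symmetric anatomical connectome.  Fitted by OLS per subject × factor,
this gives 113 standardized coefficients per factor model (678 per
subject), each an interpretable mechanism.  Downstream stages quantify:

* the contribution of receptor terms (nested F-tests against the
  8-parameter neuroimaging-only model; one-sided R² tests against
  region-shuffled receptor maps; Fisher combination per factor),
* mechanisms stable across subjects (confidence intervals for the mean
  coefficient; effect shares grouped by receptor family),
* latent axes linking mechanisms to clinical decline (SVD of the
  cross-covariance between the 678 coefficients and 11 clinical slope
  measures, with Procrustes-aligned permutation tests, subject
  bootstrap, and per-parameter variance attribution `U²/ΣU²`),
* regional receptor-influence maps (Wilcoxon rank-sum of studentized
  residuals of single-receptor vs neuroimaging-only models, z-scored
  against permuted-map nulls).

A synthetic-cohort generator with full ground truth (known dynamics,
planted latent axes, planted regional receptor pathways) backs every
stage with recovery and calibration tests; see `docs/methods.md`.

## Worked example

```python
import remcm

cohort, truth = remcm.make_cohort(n_subjects=20, seed=7)   # synthetic
cohort = remcm.zscore_imaging(cohort)
results = remcm.fit_cohort(cohort)
print(results.summary())
```

```
Cohort fit: 120 models (20 subjects x 6 factors), 0 failed
  per-factor R^2 (median [IQR]):
    GM     0.988 [0.986, 0.990]
    fALFF  0.988 [0.985, 0.990]
    DAT    0.987 [0.984, 0.989]
    FA     0.986 [0.983, 0.988]
    MD     0.986 [0.985, 0.989]
    t1t2   0.984 [0.981, 0.988]
```

One fit per subject and factor; the median R² near 0.99 says the
113-term model explains almost all rate-of-change variance at this noise
level.  Are the receptor terms doing work?

```python
restricted = remcm.fit_cohort(cohort, [])       # neuroimaging-only, 8 terms
F, p = remcm.nested_f_test(results[("sub-000", "GM")],
                           restricted[("sub-000", "GM")])
print(f"subject sub-000, GM: F = {F:.2f}, p = {p:.3g}")
```

```
subject sub-000, GM: F = 3.89, p = 5.69e-07
```

— the 105 receptor-dependent terms significantly improve this subject's
gray-matter model beyond what the extra parameters alone would.  Linking
mechanisms to clinical decline:

```python
axes = remcm.MechanismSymptomPLS(results).fit(n_perm=500, n_boot=200,
                                              seed=7)
print(axes.summary())
```

```
Mechanism-symptom latent axes
  axis 1: s=19.2788  cov expl  68.3%  r=+0.970  p=0.01597
  axis 2: s=11.7733  cov expl  25.5%  r=+0.980  p=0.996
  axis 3: s=3.5592  cov expl   2.3%  r=+0.967  p=1
  ...
```

The generator plants two mechanism–symptom axes; at this small cohort
size (n = 20) the family-wise permutation test recovers the dominant one
(68% of covariance, projection correlation r = 0.97, p = 0.016) while
the second does not reach significance — at the cohort sizes the
acceptance studies use (n = 80) both planted axes and only those two are
detected.

Regional influence maps work the same way:

```python
imap = remcm.influence_null_z(cohort, "M2", "MD", n_perm=1000, seed=7)
print(imap.summary())          # regions where M2 informs MD dynamics
```

A thin CLI mirrors the library: `remcm simulate`, `remcm fit`,
`remcm validate`, `remcm stability`, `remcm axes`, `remcm influence`
(see `remcm --help`).

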