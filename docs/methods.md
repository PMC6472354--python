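# Methods

This note describes the statistical machinery implemented in
`sigcoherence`, the choices made where the design was genuinely open, and
what the synthetic testbed does and does not establish.

## Study design the package targets

Two arms of a longitudinal birth-cohort blood-transcriptome study:

* **Longitudinal arm.** Children sampled 1–4 times during the first year
  of life; the exposure of interest (Cesarean section, `cs`) is a
  child-level binary label. Expression is normalized log2 intensity.
* **Cross-sectional arm.** Children who seroconverted to islet
  autoantibody positivity (`ab = 1`), each contributing the earliest
  sample within six months after seroconversion, compared against
  age-matched samples of children who did not seroconvert.

The scientific question downstream of per-gene testing is whether the two
risk factors regulate the transcriptome *coherently*: whether genes pushed
up by one factor tend to be pushed the same way by the other.

## Per-gene models

### Longitudinal factor: penalized-spline mixed model

For gene *i* and sample *j*:

    y_ij = b0_i + bCS_i * x_CS,j + s_i(age_j) + u_i,child(j) + e_ij

with `s_i` a natural cubic regression spline (k = 5 basis functions, knots
at quantiles of the observed ages, second-derivative curvature penalty),
`u_i,child ~ N(0, sigma_ID,i^2)` a gene-specific child intercept, and
`e_ij ~ N(0, sigma_eps,i^2)`. The penalized spline and the child intercept
are treated as variance components; the restricted likelihood, profiled
over the residual variance, is maximized over the two log variance ratios
with a two-start Nelder–Mead search (objective tolerance 1e-8). The child
block of the mixed-model equations is diagonal, so each evaluation reduces
to a small Schur complement — the sweep costs ~30 ms per gene at cohort
scale.

The factor test is Wald: `t = bCS / se(bCS)` with the Bayesian covariance
`sigma^2 (C'C + P)^(-1)` of the penalized fit, referred to a t
distribution with `df = n - edf`, where `edf` is the trace of the hat
matrix of the whole penalized fit. A standard-normal reference is
available (`reference="normal"`). Degenerate inputs (constant response,
a factor level carried by a single child) yield flagged, non-converged
rows rather than exceptions; sweeps never abort on a single gene.

Choices worth knowing:

* k = 5 with a curvature penalty is deliberately small: one year of age
  span, at most four points per child. The penalty nullspace (straight
  lines in age) is carried in the fixed effects.
* Variance components are estimated per gene with no shrinkage across
  genes.
* With the smoothing parameter pinned at infinity and the child intercept
  removed, the model reduces exactly to OLS of `y ~ 1 + x + age`; this
  reduction is tested to 1e-3 on t.

### Cross-sectional factor: age-adjusted linear model

`y_ij = b0_i + bAB_i * x_AB,j + bage_i * age_j + e_ij`, fitted by OLS with
a t(n-3) reference. The sweep is vectorized across genes (shared design,
one pseudo-inverse). When a control child has several eligible samples,
the default policy keeps the single sample nearest the median selected
case age, preserving one independent observation per child; the
`all` policy keeps every sample.

### FDR

Benjamini–Hochberg step-up, implemented directly and tested for exact
agreement with an independent implementation; default level 0.1.

## Pathway enrichment (sample permutation)

Per gene, the *local* statistic is the pooled two-sample t of the
**reduced-model residuals** (the model above without the factor term)
between factor groups. Per pathway, the *global* statistic is the Wilcoxon
rank-sum of |local t| of member genes against all non-members,
standardized to mean 0 / variance 1 under gene-label permutation with
mid-ranks and tie correction (signed ranks available). Significance comes
from permuting the **factor labels** B times (default 5000) and
recomputing every global statistic; `p = #(|z_perm| >= |z_obs|) / B`.

* Permutation unit: children for child-level factors and the longitudinal
  engine (all samples of a child move together, preserving within-child
  dependence); samples otherwise.
* Because the reduced model never sees the factor, its residuals are
  computed once and reused across all permutations; the equivalence with
  recomputation from scratch is tested.
* Label permutation preserves the gene–gene correlation structure, which
  is what protects the pathway test from false positives driven by
  correlated transcripts; this robustness is tested by embedding a
  factor-null block with pairwise r = 0.8.
* Per-permutation substreams are derived from (seed, permutation index),
  so results do not depend on how work is chunked.
* `q` is BH across pathways with permutation p-values floored at 1/B
  (a zero count cannot be ranked otherwise); the raw `p_perm` column is
  unfloored. A `+1`-corrected estimator is available (`plus_one=True`).
* Pathway direction: `n_up`/`n_down` count members by the sign of the
  full-model factor coefficient; the sign of the *directed p-value*
  `-log10(p) * sign` is the sign of the mean full-model factor t over
  members. For node-level displays, a node annotated with several genes
  takes the member value of largest magnitude.

## Signature coherence

A signature is the vector of standardized effects: factor t-statistics at
gene level, directed p-values at pathway level. Coherence between two
factors is the Pearson correlation over common ids. Significance:
relabel one factor across its exchangeable units, recompute that factor's
entire signature, repeat B times, and report

    p_perm = (1/B) * sum_i I(|rho_i| > |rho_obs|)

Two deliberate choices:

* **Two-sided magnitudes.** The comparison uses |rho_obs| (ties count as
  non-exceedances). Comparing |rho_i| against a signed observed value
  would return p near 1 for any negative observed correlation, which is
  inconsistent with how negative control correlations behave.
* **What the null is.** Permuting the labels destroys the factor's entire
  association with expression, so the test's null hypothesis is label
  exchangeability — "this factor has no effect" — not "the two factors'
  effects are uncorrelated". If both factors have real effects on the
  same genes but with independent values, the test will still often
  reject, because an estimated-signature correlation over a shared active
  gene set is overdispersed relative to the no-effect null. Calibration
  claims in the test suite therefore use a permuted factor that is
  independent of expression. Interpret a small p as evidence against
  "the permuted factor does nothing", quantified through the correlation.

Pathway-level recomputation inside each of the B relabelings uses a
reduced inner permutation budget (default 200) for the per-pathway
enrichment p-values; full nesting adds nothing to a correlation of
directed p-values and would be computationally pointless.

### Negative controls

`control_factor_scan` repeats the coherence test for factors expected to
be inert (gender, maternal diabetes, multiple first-degree relatives).
In a case-control arm with few cases, a control factor's chance
correlation with the case label (phi sd ≈ 1/sqrt(n_children), ≈ 0.11 at
89 children) lets its signature absorb part of the case-label signal and
masquerade as coherent. The scan therefore accepts an `adjust_for`
nuisance covariate; the demo pipeline adjusts control signatures for the
case label, so a control's correlation reflects its own effect only. The
default in `coherence_test` remains unadjusted.

### Immune-gene shift

Wilcoxon rank-sum of |t| between genes in a user-supplied immune
annotation and all other genes: exact enumeration over assignments when
both strata have ≤ 10 genes, otherwise the normal approximation with tie
correction. A signed-t variant is available.

## Synthetic data generator

The generator emulates the cohort's statistical structure on the log2
scale: per-gene baseline `mu ~ N(7, 1)`; genes partitioned into disjoint
pathways; a fraction of pathways *active*, their member genes receiving
`(beta_cs, beta_ab)` from a bivariate normal with marginal sds
`effect_sd` / `ab_effect_sd` and correlation `rho_true`, all other genes
exactly zero (unambiguous ground truth for pathway ranking); gene-specific
child intercepts `N(0, sigma_ID^2)` — gene-specific, because a single
intercept shared across genes would induce spurious cross-gene
correlation; a smooth per-gene age trend (amplitude-scaled centred cubic,
within the span of the downstream spline basis); i.i.d. Gaussian noise.
Defaults mirror the target design: 87 children, 1–4 samples each in
ages 0.04–1.0 y, 15 cases vs 74 control children in the cross-sectional
arm, prevalences cs 0.45 / ab 0.17 / gender 0.5 / maternal diabetes 0.2 /
multiple first-degree relatives 0.2, sigma_ID = sigma_eps = 0.3,
effect_sd default 0.1 (the longitudinal exposure's per-gene signal is
weak; analyses that need visible signal say so explicitly, e.g. the demo
uses 0.5). Ages are uniform within range; case ages are seroconversion
age plus a delay inside the selection window, and control ages are drawn
from the same construction, emulating age matching without an explicit
matching algorithm. Everything is reproducible from `(config, seed)`
through named substreams.

What the generator does **not** model: probe-level noise physics, batch
effects, missing values, visit-schedule age clustering, and gene–gene
correlation beyond what shared design effects induce (the correlated
block used in robustness tests is constructed explicitly). Passing tests
on this testbed demonstrate the estimators' statistical correctness under
the assumed model, not performance on any real cohort.

## Demo and problem sizes

`run_demo` simulates both arms from one ground truth (rho_true = 0.6,
effect_sd 0.5, 2000 genes, 25 pathways by default), runs the GAMM sweep +
enrichment on the longitudinal arm, the linear sweep + enrichment on the
cross-sectional arm, gene- and pathway-level coherence (B = 500 / 200,
inner 200), the adjusted control scan, and the immune shift (the demo's
"immune" list is the active pathways' genes plus a pad of null genes),
writing all tables with a seed/config header plus a JSON manifest of
digests. Identical seed and config give byte-identical tables.

The test suite exercises the same chain at reduced sizes (120–400 genes,
6–12 pathways, 20-replicate batches) chosen so the whole suite runs in
minutes; `scripts/acceptance.py` reruns the full-scale demo. One sizing
fact matters for interpretation: the observed correlation between two
estimated t-signatures is attenuated both by estimation noise and by the
fraction of genes with no effect, roughly
`rho_obs ≈ rho_true * sqrt(att_cs * att_ab)` with
`att = f*snr^2 / (f*snr^2 + 1)` for active-gene fraction `f`; recovery
experiments that expect `rho_obs ≈ rho_true` therefore use configurations
whose active pathways cover most genes.

## Known limitations

* The GAMM's Wald-t reference with plug-in variance ratios is slightly
  conservative in small samples (empirical null t sd ≈ 0.95); no
  small-sample df correction (e.g. Satterthwaite) is applied.
* `adjust_for` is implemented for the gene-level linear engine only.
* Gene-level coherence with a GAMM-permuted factor refits the mixed model
  per permutation and is impractical beyond small problems; the intended
  use permutes the cross-sectional factor.
* Probe-to-gene collapsing is out of scope: callers supply a matrix
  already keyed by unique gene ids.
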