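# Methods

## Scoring model

The IMM-AGE flow score treats a cohort of samples as points on a
one-dimensional immunosenescence trajectory embedded in the space of eight
adaptive-immune subset frequencies (total T cells, naive CD4, effector
memory CD4/CD8, EMRA CD8, CD28⁻ CD8, CD57⁺ CD8, regulatory T cells). The
assumptions are: (i) these eight frequencies move monotonically (in
expectation) along a single dominant axis of immune ageing; (ii) the cohort
samples that axis densely enough for a Gaussian-kernel diffusion map to
recover it; and (iii) the least senescent sample — the one with the highest
CD28-positive CD8 fraction — marks the biological start of the trajectory.

The pipeline is transductive: the embedding exists only over the fitted
cohort, so scores from different cohorts (or different feature
configurations) are comparable in rank but not in absolute value. Repeated
samples of one subject across timepoints enter as independent points, which
is what lets a patient's trajectory position be read per visit.

### Stages and numerical choices

1. **Missing-value exclusion.** Samples lacking any of the eight required
   features are excluded before any statistic is computed, and reported in
   `excluded_ids`. No imputation.
2. **Trimmed standardization** (`trim_fraction`, default 0.10 per tail).
   With n samples, k = ⌊trim·n⌋ order statistics are dropped from each end;
   the remaining values give the mean and the (n−1)-denominator SD by which
   *all* samples are standardized. A constant trimmed set raises a
   degenerate-feature error naming the feature rather than silently
   dividing by zero. Standardization pools healthy controls and all trauma
   timepoints of the analysis run: the score is a cohort-relative quantity,
   and stratifying the standardization would destroy the cross-group
   comparability that the downstream contrasts rely on.
3. **Diffusion map.** Euclidean distances in standardized space; Gaussian
   kernel with bandwidth σ = median of the non-zero pairwise distances — a
   scale-free default appropriate when no physical kernel width exists.
   Anisotropic density normalization with α = 1 (kᵢⱼ = wᵢⱼ/(qᵢqⱼ)) removes
   sampling-density bias, which matters here because trauma samples
   oversample the high-senescence end of the axis. The Markov matrix is
   eigendecomposed through its symmetric conjugate (exact, via
   `scipy.linalg.eigh`), which is both faster and numerically safer than
   iterating on the non-symmetric matrix; cohorts of a few hundred samples
   make a dense solve trivial. Defaults `n_components = 3` and
   `diffusion_time = 1` fit an 8-dimensional feature space and small
   cohorts; both are exposed. Eigenvector signs are fixed so the
   largest-magnitude entry of each component is positive; scores are
   invariant to this choice because they are distances.
4. **Rooting.** Default rule: argmin of the raw CD28⁻ CD8 frequency, ties
   broken by lexicographically smallest sample id. CD28 loss is the
   canonical senescence marker in the feature set, so its minimum is the
   least-aged end. An explicit root (`explicit:<id>`) is supported for
   sensitivity analyses.
5. **Pseudotime and scaling.** Raw score = diffusion distance from the root
   in the eigenvalue-weighted embedding (not a graph shortest path and not
   a principal curve: diffusion distance is the simplest quantity that is a
   true metric on the embedding and provably reproduces position order for
   samples on a 1-D manifold, which the test suite checks against a
   collinear oracle). Min-max scaling to [0, 1] is exact: the root is the
   minimum at 0; duplicated maxima all score 1.

## Synthetic cohort generator

The generator emulates the *statistical structure* the analysis assumes,
not raw cytometry. One latent immune age per sample drives everything:

- **Controls** (default n = 55): latent = scaled chronological age (drawn
  uniformly on 20–85 years) plus Gaussian noise (SD 0.35 on a latent scale
  where the age range spans [−1, 1]).
- **Trauma** (default n = 57, sampled days 3/14/28/60): the control
  expectation plus a positive latent offset peaking at day 14
  (1.1/1.5/0.9/0.5), matching the observed nadir of naive T cells at two
  weeks post-injury and partial recovery by day 60.
- **Frequencies** are compositional: CD45RA/CCR7 quartets and sibling
  splits are Dirichlet draws whose mean vectors shift linearly with the
  latent (precision ≈ 150, i.e. ~4 percentage points of noise on a 45%
  subset); single gates are Beta draws; the senescent CD28⁻CD57⁺ gate is a
  Beta(24, 6)-distributed fraction of the min(CD28⁻, CD57⁺) bound, so the
  intersection invariant holds by construction.
- **Lymphocyte counts** are log-normal with trauma multipliers
  0.55/0.50/0.70/0.90 (nadir before day 60); **cytokines** (IL-6, TNFα,
  IL-10, IL-8 in pg/ml, CRP in mg/ml) are log-normal and right-skewed
  (σ_log = 0.8 in patients), elevated after trauma with a day-3 peak and
  multiplied again under sepsis (IL-6 ×4, TNFα ×3, IL-10 ×1.8, CRP ×1.9) —
  reproducing the pattern where group SDs exceed means.
- **Sepsis** labels come from a logistic model on the day-3 latent, centred
  so the marginal rate tracks `sepsis_rate`. The default rate is 0.65; the
  source cohort reports two slightly different prevalences (64.9% and
  67.85%), and 0.65 sits at the printed count-based figure without
  resolving the discrepancy.
- **Missingness**: trauma subjects miss each post-baseline visit
  independently and completely at random with `dropout_rate` (default 0.3,
  chosen to reproduce per-timepoint n that shrink non-monotonically, e.g.
  54→38→41→16). A separate `feature_missing_rate` (default 0) knocks out
  individual panel entries to exercise the exclusion rule.
- **Randomness** is hierarchical: one global seed spawns one stream per
  subject, so adding subjects never perturbs existing ones, and identical
  seeds give byte-identical output tables.

What the generator does *not* emulate: within-subject longitudinal
autocorrelation beyond the deterministic timepoint offsets, gating/
compensation noise, batch effects, age–injury interactions, and any
dependence of dropout on severity (dropout is MCAR). Passing tests
therefore demonstrate that the pipeline recovers a planted 1-D latent
structure under realistic compositional noise — not that real trauma
cohorts satisfy that structure.

## Comparison statistics

The normality screen is a Lilliefors-style Kolmogorov–Smirnov test
(parameters estimated from the sample, table p-values) — the appropriate
form when mean and SD are not known a priori. The two-group default is the
pooled-variance Student t test; Welch is available, and the routing when
normality fails is deliberately configurable rather than hard-coded,
because no canonical non-parametric fallback is part of the analysis
contract. Bonferroni adjustment is min(1, m·p) over the m *requested*
contrasts. Univariate regressions are ordinary least squares with the slope
F test (equal to the squared-t test for one predictor); R² is the squared
Pearson correlation. All tests are two-sided at α = 0.05.

## Random-forest sepsis ranking

Bootstrap-per-tree forest (default ntree = 500, mtry = ⌊√p⌋) over sklearn
decision trees, with the bagging, out-of-bag bookkeeping and permutation
importance implemented in the package: per tree, OOB accuracy is compared
against OOB accuracy after permuting one feature's values, and the per-tree
decreases are averaged into the mean decrease in accuracy (MDA) that orders
the ranking (ties broken alphabetically). OOB predictions are majority
votes over the trees for which a sample was out of bag; the reported OOB
accuracy is exactly the trace of the OOB confusion matrix over its total.
Rows with missing features are list-wise deleted and counted
(`n_dropped_`). Class imbalance can be addressed with an optional
stratified bootstrap (default off). Duplicated informative features split
their MDA — the ranking should be read per correlated block, a documented
and tested property. Which samples feed the forest is an explicit argument
(the pipeline default is the day-3 trauma visit): pooling timepoints mixes
within-subject replicates into the bootstrap and is left to the caller's
judgement.

## Problem sizes and determinism

Default test and acceptance runs use cohorts of roughly 200 samples
(100 controls + 35 trauma subjects over four timepoints with 30% visit
missingness), 500-tree forests at n = 200 × 10 features, and
1000–2000-replicate null calibrations — sizes at which every stage is exact
(dense eigendecomposition, full enumeration of OOB sets) and the whole
suite completes in well under a minute per module. Every pipeline artifact
embeds the global seed and a hash of the configuration (excluding the
output directory); two runs with the same hash are byte-identical, which
the acceptance suite verifies by hashing all artifacts.

## Known limitations

- Scores are cohort-relative; adding or removing samples changes every
  score, not just the new ones. Cross-cohort comparisons must re-fit on the
  pooled data.
- The diffusion map assumes a single dominant trajectory; genuinely
  multi-branch immune topologies would fold into one axis.
- The pooled-standardization choice means a heavily imbalanced cohort
  shifts the trimmed statistics toward its larger arm.
- The root rule depends on a single feature; an outlier CD28⁻ CD8
  measurement can relocate the origin (mitigated by the trimmed
  standardization but not eliminated; an explicit root override exists).
- The generator's linear latent→mean maps are a convenience; real subset
  frequencies saturate near gate boundaries.
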