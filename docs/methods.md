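# Methods

## Problem setting

`stableselect` addresses feature (SNP) selection for case/control cohorts
in the regime where few variants reach genome-wide significance but many
weak effects may still carry predictive signal. Instead of a single
significance cut, it asks which SNPs *stably* survive a
predictivity-driven selection when the whole procedure is replicated over
random re-splits of the data, and then evaluates what the surviving sets
are worth in association and classification terms.

## Model and ranking statistic

The working model is weighted linear regression of the (0/1) status
vector on scaled genotype dosages,

    y = X m + ε,     E(ε) = 0,   cov(ε) = Δ_y²  (diagonal),

with an intercept column X₀ = 1 and the goodness-of-fit functional

    E²(m) = (y − Xm)ᵀ Δ_y⁻² (y − Xm) + C mᵀm .

With W = Δ_y⁻², the closed-form estimators are

    m̄      = (XᵀWX + CI)⁻¹ XᵀWy
    cov(m̄) = (XᵀWX + CI)⁻¹ XᵀWX (XᵀWX + CI)⁻¹
    E²_res  = yᵀWy − (Xm̄)ᵀW(Xm̄) − C m̄ᵀm̄ ,

and the exact decomposition E²(m) = E²_res + (m−m̄)ᵀ(XᵀWX+CI)(m−m̄)
holds for every m (this is asserted to 1e-10 relative precision in the
test suite, as is the conservation of yᵀWy into residual + explained +
penalty parts). The L2 penalty exists to control "splining": in
underdetermined systems the unpenalized fit drives coefficients along
near-null eigendirections to fit noise exactly.

The per-SNP ranking score ("heritability component") is the j-th
diagonal share of the explained term,

    h_j = m̄_j² · (x_jᵀ W x_j),

i.e. the diagonal of diag(m̄)·XᵀWX·diag(m̄). Cross-covariance terms
between features are deliberately dropped — on LD-pruned panels they are
small, which is why LD pruning precedes ranking. A flag
(`include_cross_terms`) switches to the full row sums, which add up
exactly to (Xm̄)ᵀW(Xm̄).

Numerical path: the p×p regularized normal equations are solved when
p ≤ n, otherwise the algebraically identical n×n dual system
m̄ = Zᵀ(ZZᵀ + CI)⁻¹ W^{1/2}y with Z = W^{1/2}X; both paths are compared
on small instances in the tests. Δ_y defaults to the identity
(homoscedastic); per-sample weights are accepted but nothing in the
package estimates them. Genotype columns are mean-imputed (missing
calls), centred and scaled to unit variance before the fit; the
intercept column is exempt and is excluded from ranking.

## Selection: nested subsets, Youden curve, first local maximum

Each replication proceeds as:

1. Draw `n_folds` class-stratified train/test splits of the working
   samples (test fraction `s_test`); fit the ridge on each train part
   and average the per-fold scores c_{i,j} into c_j.
2. Stable-sort features by decreasing c_j (ties keep column order).
3. Build nested prefix subsets F_0 ⊂ … ⊂ F_{n_steps−1} with
   |F_i| = (i+1)·⌊p/n_steps⌋ and the last subset completed to all p.
4. For each of `m_folds` fresh stratified splits (test fraction
   `t_test`), train a linear-kernel maximum-margin classifier on each
   F_i and record its Youden index J = sensitivity + specificity − 1 on
   the held-out part, at the classifier's native decision threshold
   (single operating point, no threshold sweep).
5. Average J over folds into the Youden curve K and cut at the first
   (left-to-right) interior local maximum, K[j−1] ≤ K[j] ≥ K[j+1];
   plateaus resolve to their first index, and a curve with no interior
   local maximum (e.g. strictly monotone) falls back to its first
   global argmax. The selected set of the replication is F_{j_max}.

The classifier is scikit-learn's liblinear `LinearSVC` at its default
regularization (L2, C=1): the linear-kernel maximum-margin objective
with a solver that converges reliably even on unseparable, label-noise
data, where kernelized SMO solvers become extremely slow. The solver
stopping tolerance is 1e-3 — far below the Youden-score resolution that
matters for locating the curve peak. AUC, when reported, comes from the
decision-function ranking.

## Stability replication and support

The outer loop repeats ranking + selection `n_iterations` (N) times
with fresh splits; a SNP's *support* is the number of replications whose
cutoff set contained it, and a *stable set* collects SNPs with support
above a threshold (e.g. 40 of 50). The rationale is the two-type
Bernoulli model: if a fraction f of SNPs is truly active and one
replication falsely identifies a null SNP with probability α and rejects
an active one with probability β, the expected true-positive fraction
among fully supported SNPs is f(1−β)ᴺ/(f(1−β)ᴺ+(1−f)αᴺ) → 1 for large N
whenever 1−β > α. The closed form is cross-checked against a Monte-Carlo
of the process in the acceptance suite.

Support counting is only informative to the extent replications
decorrelate: if every replication ranks on (essentially) the full
working sample, a fixed dataset's spurious champions are re-selected
every time and support saturates even under a null phenotype. The
replication scheme therefore determines what support means, and its
parameters are part of the study design (see below).

Seeding: a master seed expands into one `SeedSequence([master, rep])`
per replication, each spawning separate ranking and scoring streams, so
runs are bit-reproducible and replications are independent of execution
order.

## Quality control

Fixed order: missingness → MAF → HWE → LD pruning; each filter preserves
column order and is idempotent. Defaults: per-SNP missingness ≤ 0.05,
MAF ≥ 0.05, HWE p ≥ 1e-12, LD pruning with 50 kb windows, step 5 SNPs,
r² ceiling 0.5. The HWE test is a 1-df chi-square goodness of fit on
pooled genotype counts (cases and controls together); monomorphic SNPs
are assigned p = 1 and left to the MAF filter. An exact HWE test (as
PLINK uses) would differ in the far tail but both are far beyond the
1e-12 threshold for any realistic violation. LD pruning is greedy within
sliding windows: the later-positioned SNP of an offending pair is
removed, r² is computed on mean-imputed dosages, zero-variance pairs
count as r² = 0, and passes repeat until no surviving within-window pair
exceeds the ceiling.

## Synthetic cohorts

The generator emulates the qualitative structure of a late-onset
dementia cohort, not human LD maps or ancestry:

- Genotypes: per-SNP MAF uniform on [0.05, 0.5]; dosage = sum of two
  allele draws, so unlinked SNPs sit at Hardy–Weinberg proportions.
  Optional LD blocks correlate allele draws through an equicorrelated
  latent Gaussian (copula thresholding). SNPs are 1 kb apart on one
  synthetic chromosome.
- Phenotypes: Bernoulli with logit P(case) = intercept + Σ β_c·dosage_c;
  the intercept auto-centres so prevalence ≈ 0.5 (the cohort the design
  emulates is 46% cases).
- Presets: `ad-like` = 3 strong causals (per-dosage OR 2.5, the
  APOE-region pattern) + 12 weak causals (OR 1.15) among 500 SNPs;
  `weak-signal` = 12 weak causals only (the weak-chromosome pattern).
  Strong causals draw their MAF from the common range [0.15, 0.35]
  (APOE4-like frequencies): a locus is "strongly associated" in the
  marginal sense only if its effect size *and* frequency give it more
  association information than the null background, and an OR-2.5
  allele near MAF 0.05 does not qualify at n = 600. Weak causals and
  null SNPs keep the global spectrum.
- Null control: `shuffle_phenotypes` permutes the status-to-sample
  assignment, conserving class counts and destroying all association.

What passing tests on these cohorts do *not* show: behavior under
population structure, realistic LD, rare variants, or case/control
imbalance far from 1:1.

## Study configuration (desk scale)

`default_study_config` fixes the knobs used by the test suite and the
acceptance script on 600-sample × 500-SNP cohorts:

| knob | value | why |
|---|---|---|
| n_folds | 1 | each replication ranks on a single subsample so that replications decorrelate; with fold-averaged rankings every replication converges on the full-sample ranking, and under a null phenotype the same spurious champions reach full support in every replication |
| s_test | 0.5 | half-sample ranking maximizes between-replication independence while keeping enough samples (300) to rank strong effects reliably |
| m_folds | 2 | scoring folds; only the location of the curve's first peak matters, not its level |
| t_test | 0.25 | scoring held-out fraction |
| n_steps | 50 | curve resolution: the cutoff prefix grows in increments of p/50 (=10), so selected sets stay proportionally small and membership is informative |
| C | p (=500) | SNP-BLUP-style penalty: with standardized dosages, per-marker prior variance 1/p of the phenotypic scale; keeps coefficients from splining when p ≈ n. C = 1 (the library default elsewhere) leaves the near-null eigendirections essentially unpenalized at this aspect ratio and ranking becomes unstable |
| N | 20 (tests) / 50 (library default) | replication count |

The library-level `PipelineConfig` defaults stay at production scale
(n_folds = 5, m_folds = 5, n_steps = 100, C = 1, N = 50), suited to
cohorts where the sample count dwarfs the selected-feature count.

## Downstream evaluation

- Per-SNP association: maximum-likelihood logistic regression (IRLS via
  statsmodels), Wald p on the dosage coefficient, OR = exp(coef).
  Complete separation or non-convergence yields a flagged result with
  NaN p rather than a fabricated value. Constant dosages raise.
- 2×2 contingency inference: OR = n_DE·n_de/(n_De·n_dE); log OR treated
  as normal with σ² = Σ 1/cell, two-sided p. Any zero cell triggers the
  Haldane–Anscombe +0.5 correction on all four cells, flagged.
- Significance subsetting uses −log₁₀(p) (GWAS convention); p-values are
  raw — the thresholds in use are deliberately extreme, no FDR layer.
- Predictivity of a SNP set: fold-averaged F1 / AUC / precision / recall
  of the linear-kernel classifier on stratified held-out splits. Paired
  comparisons between subsets should use the same seed so both are
  scored on identical splits.
- PRS weight selection: an equal-width 50-bin histogram over the β
  range; SNPs in bins holding < 2×10⁻⁴ of all SNPs (the sparse tails
  outside the neutral spike) are selected. If all weights are equal the
  selection is empty. An alternative |β| > 2×10⁻⁴ magnitude rule is
  available behind a flag.

## Numerical and degenerate-case choices

- Stratified splits allocate the test set by global rounding with
  largest-remainder apportionment across classes (ties to controls), so
  a 10+10 cohort at fraction 0.2 holds exactly 2 cases + 2 controls out.
- `ridge_fit` refuses C = 0 on singular or underdetermined systems
  rather than pseudo-inverting.
- Ranking ties keep original column order (stable sort); NaN scores
  raise.
- A degenerate scoring subset (all-constant training columns) scores
  J = 0 for that fold with a warning.
- Missing genotypes are mean-imputed per SNP at analysis time, after QC.
  This is a deterministic stand-in for genotype imputation proper, which
  is out of scope.

## Known limitations

- Selection granularity is bounded below by p/n_steps SNPs per
  replication, so on a 500-SNP panel the union of selected sets spans
  30–50% of the panel — proportionally far larger than a
  production-scale selection. Classifiers trained on such unions at a
  few hundred samples pay a measurable noise-dilution penalty, which
  blurs F1 comparisons between the full selected set and its
  high-support subset: at this cohort size those two F1 values differ
  by up to ~0.1 in either direction, whereas with tens of thousands of
  samples and sub-percent selections they would essentially coincide
  for strong-signal cohorts.
- The weak-signal contrast (whole selected set vs top-supported subset)
  is a small effect of the same order as that dilution penalty; it is
  measured with paired splits, but at 600 samples individual cohorts go
  either way.
- Support decorrelation and support concentration trade off directly:
  fold-averaged ranking concentrates support on stable features (good
  for contrasting high-support subsets) but re-selects a fixed
  dataset's spurious champions in every replication, saturating support
  under a null phenotype. The study configuration privileges the null
  calibration; a support-concentrating variant is one
  `PipelineConfig(n_folds=5, s_test=0.2, ...)` away.
- The heritability score drops LD cross terms; on un-pruned panels
  correlated features share credit unpredictably.
- The chi-square HWE test is anti-conservative at very low minor-allele
  counts compared to the exact test; irrelevant above MAF 0.05 at the
  1e-12 threshold, but do not reuse the filter for rare-variant panels.
- `run_stability` is sequential; replication seeds are pre-derived, so a
  parallel map over replications would give identical results, but none
  is built in.
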