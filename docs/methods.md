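# Methods

## Mutation contexts

Variant calls are aggregated to gene level: a gene is mutated in a
patient iff at least one nonsilent call (default vocabulary: missense,
nonsense, frameshift/in-frame indel, splice-site, nonstop,
translation-start, in both MAF `Variant_Classification` spelling and
plain lower-case tokens; configurable because MAF dialects differ) falls
in the gene body.  Patients present in the count matrix but absent from
the mutation table are wild-type — in consortium call sets the absence
of a call means no mutation — and are logged.  A context is kept when
its mutation frequency f satisfies 0.05 < f < 0.95, i.e. both classes
exceed 5% of the cohort.

Each context is mapped to a discrete frequency category on the grid
{0.05, …, 0.50} through the minority-class fraction f_eff = min(f, 1−f);
permutation nulls are symmetric in the class labels, so the null count
distribution depends only on the minority fraction (this also covers
frequencies above 50%).  Mapping uses nearest-grid rounding with exact
midpoints rounded down; a `ceil` mode (smallest grid value ≥ f_eff) is
available.  Nearest rounding was chosen because it minimizes the
class-ratio discrepancy between the context and the null it is scored
against; the residual discrepancy (up to 0.025) is an approximation
inherent to the category design.

## DE engine

The engine is a two-group negative binomial GLM with log link,
model log μ = β₀ + β₁·mutant + log(effective library size), tested by a
1-df likelihood-ratio test.  Components:

- **Normalization** — trimmed mean of M-values: reference sample =
  upper-quartile closest to the mean upper-quartile; per sample, log2
  ratios against the reference over doubly-positive features,
  30%/5% two-sided trimming on M and A, precision-weighted mean; factors
  renormalized to geometric mean 1.  Effective library size =
  raw library size × scale factor.
- **Dispersions** — per-feature method of moments on common-scale
  pseudo-counts, (var − mean)/mean² pooled across the two classes by
  degrees of freedom, shrunk toward the across-feature median with
  weight w = 0.5 (floor 10⁻⁶).  Degenerate features receive the median.
  The shrinkage weight trades per-feature noise against bias for
  features whose variability deviates from the bulk; 0.5 is a neutral
  default, and w is exposed.
- **Testing** — fits are vectorized across features by IRLS (closed-form
  2×2 weighted solve per feature per iteration, linear predictor clipped
  at ±30, coefficients at ±20, ≤60 iterations); non-convergent features
  get p = 1 and a flag.  Features with total count < 10 are excluded
  before testing (configurable), features constant across samples get
  p = 1 and logFC = 0 by definition.  logFC is reported in log2 from
  normalized group means with a 0.125 prior count.  BH adjustment is
  standard step-up with monotonicity enforcement; the DE count N counts
  tested features with q < 0.05.

The engine interface is pluggable: the permutation layer only requires a
callable mapping a labelling to a DE count, so an external engine
(e.g. edgeR through rpy2 or subprocess) can be swapped in.  The test
suite cross-validates this engine against edgeR's glmLRT on a synthetic
cohort (logFC r > 0.95, p-value rank correlation > 0.9) and against
brute-force BH.  Exact numerical reproduction of edgeR's empirical Bayes
machinery is a non-goal; the framework's contribution is the permutation
layer, which is engine-agnostic.

## Permutation nulls and impact statistics

One null per (cohort, category): B = 1000 label permutations, each
assigning exactly round(category·n) patients to the mutant class
uniformly without replacement (class-ratio-controlled; an exact-n mode
matches a specific context's mutant count instead).  Normalization
factors and the low-count filter depend only on the counts and are
computed once; dispersions are re-estimated per permutation.  RNG
streams derive from a master seed per (cohort, category) so nulls are
reproducible and independent; all genes of one cohort mapping to one
category are scored against the byte-identical null.

For an observed count N:

- empirical P = (r+1)/(B+1), r = #{null ≥ N}; the add-one convention
  makes the floor 1/(B+1) ≈ .001 at B = 1000 (a raw r/B variant exists);
- z = (N − μ)/σ with sample moments of the null (missing when σ = 0);
- NB-modified P = P(X ≥ N) under a method-of-moments NB
  (r = μ²/(σ²−μ), p = μ/σ²); when the null is underdispersed (σ² ≤ μ)
  a Poisson(μ) fallback is used, and an all-zero null falls back to a
  vanishing pseudo-rate with a flag.  Tails are computed via scipy's
  `nbinom.sf`, i.e. the regularized incomplete beta, stable for extreme
  N.  No multiple-testing correction is applied across contexts — each
  context's NB-modified P is thresholded at α = .05 directly, mirroring
  the per-context decision rule of the framework; downstream users
  should keep this in mind when interpreting genome-wide scans.

## Prognosis

Per-feature screening fits univariate Cox proportional-hazards models on
row-standardized log-CPM, so hazard ratios are per SD of log-expression
and comparable across features.  The solver maximizes the Breslow
partial likelihood by vectorized Newton iterations on reverse-cumulative
risk sums (validated against lifelines and R `survival` with
`ties="breslow"` to ~10⁻⁶); p-values from the 1-df LRT.  At least two
observed events are required, otherwise results are missing and
flagged.

The aggregative statistic for a responsive set S: directions = sign of
each feature's univariate Cox log-HR; composite score = mean over S of
direction × z-scored log-CPM (zero-variance features excluded); s = Cox
LRT p-value of the endpoint on the composite.  s lives in [0, 1], and
its optimistic selection bias is removed by the permutation procedure:
(time, event) pairs are permuted jointly across patients
(equivalently, expression columns are permuted), and s is recomputed
per permutation *including re-selection of directions*, so the null
embodies the same selection.  p_perm = (#{s_perm ≤ s_obs}+1)/(B+1).  A
Beta(α, β) is fitted to the permuted statistics by method of moments
(α = m·c, β = (1−m)·c, c = m(1−m)/v − 1) and its CDF at s_obs gives the
Beta P; when the moment fit is invalid (v ≥ m(1−m)) the empirical
estimate is returned with a flag.  The composite instantiation
(direction-adjusted mean z-score → Cox LRT p) is a documented design
choice satisfying the constraints the framework places on the statistic
(unit interval, built-in permutation, Beta-approximable); the statistic
is pluggable.  OS and DSS are analyzed strictly separately; patients
missing an endpoint are dropped from that endpoint only.

## Enrichment

Upper-tail hypergeometric over-representation of a selected feature set
against named annotation sets, BH across terms.  The universe defaults
to the features that entered DE testing — enrichment against features
that never had a chance of selection would distort the null — and is
configurable.

## Synthetic cohorts

The generator emulates a bulk miRNA-seq cancer cohort:

| component | model | default | rationale |
|---|---|---|---|
| baseline means | log-uniform | [1, 1000] counts | spans the realistic dynamic range |
| dispersions | log-uniform | [0.02, 0.8] | biological CV ≈ 0.14–0.9, typical miRNA-seq heterogeneity |
| library sizes | log-normal | sdlog 0.35 | typical depth variation |
| mutations | Bernoulli(f_g) | f spread over (0.08, 0.45) | the observed frequency spectrum is low-skewed |
| effects | multiplicative 2^log2FC on k features | 3 genes × k = 60, &#124;log2FC&#124; = 1.5, random sign | moderate, detectable dysregulation |
| survival | exponential, hazard h₀·exp(β·composite) | h₀ = 10⁻³/day, β = 0.5 | proportional hazards hold exactly, so recovery is well-defined |
| censoring | independent uniform, scale calibrated to the target rate | 30% | administrative censoring |
| DSS | disease-specific deaths distinguished from background deaths | 15% missing | endpoint separation testable |

An optional `subpop_feature_frac` marks a fraction of features as
expressed only in a random patient subpopulation (prevalence uniform in
[0.1, 0.5]) — the bimodal, context-specific expression common for
miRNAs.  Such features violate the NB model and inflate naive DE counts
under random labels; they are the mechanism by which the test suite
builds *non-degenerate* permutation nulls and demonstrates that the
frequency-matched permutation test absorbs structural false discoveries
that a naive q < 0.05 count would report.

A truth ledger records every responsive (gene, feature, log2FC) triple,
the prognostic feature subset, and the drawn NB parameters, enabling
exact recall/precision and parameter-recovery accounting.  The
generator writes the same TSV dialects the readers consume, so it
doubles as a fixture generator.

### What the synthetic nulls do and do not show

Under exchangeable synthetic null cohorts this DE engine is essentially
calibrated: median null DE counts are near zero at every sample size
and category, and the monotone-in-(n, balance) check on medians holds
in that degenerate form.  We investigated extensively (including
running edgeR itself on identical synthetic data) whether the strong
growth of false-discovery counts with cohort size and class balance
reported for real tumor cohorts can be reproduced by an exchangeable
generator — Gaussian or heavy-tailed latent patient factors, minority
subtypes, subpopulation-expressed features — and found the opposite:
label exchangeability makes the pseudo-effect scale and the model
standard error shrink together, and every finite-sample miscalibration
we could induce concentrates in the *small*-group cells.  The
real-data growth therefore reflects model violations of real
transcriptomes interacting with the DE machinery (and, across cohorts,
the confounding of size with heterogeneity), not a property of
exchangeable null data.  This is precisely why the framework's
frequency-matched permutation null — which conditions on the actual
data — is the right control, and the calibration tests here show it
absorbing structural inflation wherever it arises.

## Numerical choices

Linear predictors clipped at ±30 (GLM) and Cox arguments at ±700 before
exponentiation; Newton steps damped to |step| ≤ 1 and coefficients
clipped at ±30 in the Cox solver; LRT statistics floored at 0; BH ties
preserved by stable sorting; empirical P uses the add-one estimator by
default; null caches are keyed by a content hash of counts, engine
parameters, category, B and seed.  Problem sizes in the test suite
(cohorts of 50–300 patients, 120–2000 features, B = 100–1000, 20–1000
replicates per experiment) were chosen as the smallest at which each
statistical property is expected to be decisively measurable.

## Known limitations

- Single-factor designs only: no covariate adjustment in DE or Cox.
- The dispersion estimator is a deliberately simple moment/shrinkage
  scheme, not edgeR's empirical Bayes; per-feature p-values on real,
  heterogeneous data will be miscalibrated — which the permutation
  layer is designed to absorb — but feature-level rankings inherit its
  noise.
- The composite prognosis statistic is an instantiation, not the only
  possible aggregation; weighted or rank-based composites may behave
  differently for skewed sets.
- The generator does not model miRNA co-expression networks, isoform
  structure, or batch effects; conclusions about real-data false
  discovery magnitudes cannot be drawn from its null cohorts (see
  above).
- Patient matching across tables is by exact identifier only.
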