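# Methods

## Structural model and identification

The package estimates the linear structural system

    Y = Y Γ' + X Ψ + ε,

where Y (n × p) is log-scale expression, X (n × q) genotype dosages,
Γ a zero-diagonal p × p matrix with Γ[i, j] the causal effect of gene j
on gene i, Ψ sparse cis effects, and ε disturbances independent of X.
Γ is not required to be acyclic: feedback loops and reciprocal
regulation are admissible, and I − Γ must merely be invertible.

Ordinary regression of one gene's expression on the others is
inconsistent here because the disturbances are correlated across genes
(shared latent factors) and the system is simultaneous. Cis variants
provide instruments: they are assigned at meiosis (independent of ε),
affect their own gene's expression, and influence other genes only
through it. Per target gene k the limited-information form

    Y_k = Y_(−k) γ_k + X ψ_k + ε_k,      Y_(−k) = X π_(−k) + ξ_(−k)

is estimated in two stages (2SPLS):

1. **Stage 1.** Each gene's expression is predicted from the pooled
   genome-wide instrument matrix. The pool is screened per gene by
   iterative sure independence screening (ISIS) down to
   ⌊n / log n⌋ columns (admission in batches of a third of the target,
   re-ranking residual correlations after each batch), then fit by
   ridge regression with the penalty chosen on a fixed grid
   ({0} ∪ 10^[−4,4], 41 points) by generalized cross-validation,
   GCV(λ) = n·RSS(λ)/(n − tr S_λ)², the trace including the intercept.
   A gene with no instruments gets its sample mean as prediction — it
   can then never be selected as a regulator, which is the correct
   structural behavior (its outgoing effects are unidentified).
2. **Stage 2.** For target k, both Y_k and the stage-1 predictions of
   the other genes are projected by the annihilator H_k of gene k's own
   instrument columns, and regulators are selected by adaptive lasso of
   H_k Y_k on H_k Ŷ_(−k). Nonzero coefficients are directed edges into
   gene k.

### The annihilator

H_k is the orthogonal-complement projector of span{1, X_S_k} — the
instrument columns *plus an intercept column*. The intercept is
absorbed into the projection deliberately: all regressions carry
intercepts, and with the ones vector inside the projection the
stage-2 estimate on a just-identified two-gene system reproduces the
classical 2SLS/IV estimator exactly (the package asserts agreement to
1e-8; in practice it is machine precision). With no instruments H_k is
the identity, so an instrument-less gene can still *receive* edges.
H_k is applied as v − Q(Qᵀv) from a QR basis — O(n·|S_k|) per
application, never an n × n matrix. Rank-deficient instrument sets
(possible after bootstrap resampling) drop dependent basis columns with
a warning.

### Adaptive lasso details

Columns are standardized internally; initial coefficients come from a
GCV-tuned ridge fit on the standardized columns (usable when p > n);
weights are w_j = 1/|β̂_init,j|^γ with γ = 1, and exactly-zero initial
coefficients exclude the column. The lasso path is computed by LARS
and interpolated at a 40-point log-spaced grid from λ_max down to
10⁻³λ_max — the lasso path is piecewise linear in λ, so interpolation
between knots is exact, and the final fit at the chosen λ comes from
the same path (no coordinate-descent tolerance).

λ is chosen by 10-fold cross-validation with the **one-standard-error
rule** by default: the largest λ whose mean CV error is within one
standard error of the minimum. CV-minimum and BIC rules are config
alternatives (`selection: cv_min | bic`). The 1-SE rule is the
package's choice because edge *selection* is the product here: the
CV-minimum systematically over-selects in the null direction, while the
1-SE rule keeps the false-edge rate of the instrumented pipeline low
without costing noticeable power at the effect sizes and sample sizes
the generator emulates. All CV fold seeds derive deterministically from
the master seed and the gene index, so results are independent of
worker count and scheduling.

## Instrument discovery

Candidates are sought in each gene's cis window: gene body ± 1000 bp,
1-based inclusive, clipped at position 1. MAF classes: common
(MAF ≥ 0.05), low (0.01 ≤ MAF < 0.05), rare (< 0.01).

* Common variants: simple-regression slope with two-sided t-test.
* Low-MAF and rare variants are aggregated *separately, one burden per
  class*, by the adaptive-sum procedure: variants whose marginal effect
  is negative with p < α₀ = 0.1 are recoded 2 − dosage, the burden is
  the row sum of the recoded matrix, its score statistic is referred to
  a permutation null in which the flip-and-sum is *recomputed inside
  every permutation* (otherwise the adaptive selection would inflate
  the test). Permutations are vectorized through precomputed Gram
  matrices, so 1000 permutations cost a few milliseconds per gene.

Candidacy requires p below a per-gene Bonferroni level: α / (number of
tests in that gene's window), α = 0.05 by default, with the count being
the number of common variants plus one per non-empty burden class.
Selection is greedy in ascending p (ties by genomic position, then id),
admitting a candidate only while its absolute Pearson correlation with
every admitted instrument stays below 0.3, stopping at three.

Burden pseudo-variants get ids `<gene>_burden_<class>`. Because burden
scores are row sums (they can exceed 2), instruments live in a separate
pooled instrument matrix rather than being appended to the dosage
matrix; downstream stages treat pool columns uniformly.

## Preprocessing

Two study templates plus a pass-through mode:

* Bulk-cohort ("gtex") expression filter: keep genes with TPM > 0.1 in
  ≥ 20% of samples *and* ≥ 6 reads in ≥ 20% of samples (both fractions
  inclusive). Normalization is TMM exactly as in edgeR: M-values on
  library-size-normalized counts against a reference sample (default:
  upper-quartile closest to the mean), two-sided trims of 30% on M and
  5% on A, inverse-delta-method-variance weighting, factors rescaled to
  log-mean zero; a unit test checks agreement with
  `edgeR::calcNormFactors` to 1e-6. Expression then becomes
  log2(CPM + 1) on effective library sizes (library size × factor).
* Tumor-cohort ("tcga") filter: drop genes with total counts below
  2.5 million (strict) or zero/missing in > 80% of samples. The
  total-count threshold is implausibly large for most genes but is
  applied verbatim with a config override (`tcga_min_total`). Zeros
  proxy missingness because HTSeq-style count matrices carry no NA.
  Count normalization uses median-of-ratios size factors with the same
  log2(CPM + 1) transform; a variance-stabilizing transform is *not*
  reimplemented — this stand-in is flagged here deliberately, since VST
  output is tied to a specific dispersion-fitting implementation.
* Genotype QC, in order: variant missing rate > 10% → sample missing
  rate > 10% → Hardy-Weinberg 1-df chi-square p < 1e-4 (the exact
  conditional test is available as `hwe_test: exact`; the two disagree
  only near the cutoff or at minor-allele counts below ~20, where the
  chi-square approximation is anticonservative) → minor allele count
  < 5. MAF is computed on the retained samples. Remaining missing
  dosages are imputed to the homozygous-major genotype; reference-panel
  imputation is out of scope.
* Confounders are removed by least squares (intercept + dummy-coded
  categoricals + numeric covariates), dropping collinear design columns
  with a warning. Genotype principal components (top 3 by default, on
  column-standardized dosages, zero-variance variants dropped) are
  removed **only** from the expression used for instrument discovery.
  The pipeline carries two expression versions: PC-adjusted for the
  local association scans (population structure confounds them), and
  non-PC-adjusted for network inference (the PCs carry genuine global
  regulatory signal). Residualization is idempotent and leaves
  residuals orthogonal to every design column.

## Bootstrap confidence and partitioning

Edge confidence is case-resampling: B with-replacement resamples of the
observations (rows of Y and of the instrument pool jointly), the full
two-stage fit repeated per resample with instrument sets held fixed
from the original data (instrument discovery precedes the bootstrap
loop; permutation burden tests inside every resample would multiply the
cost for no stated benefit). Frequencies accumulate as integer counts
divided once by B, so every entry is an exact multiple of 1/B. B
defaults to 1000; desk-scale tests use 25–50. Both the "present in
every bootstrap" (cutoff 1.0) and "present in ≥ 95%" views are
one threshold call away; no default cutoff is asserted.

The thresholded graph E_ij = 1[A̅_ij ≥ cutoff] (inclusive) feeds degree
d(i) = Σ_j (E_ij + E_ji), weakly connected components, and modularity

    Q(D) = (1/2N) Σ_(i,j) [E_ij + E_ji − d(i)d(j)/(2N)] δ_D(i,j),

evaluated over all ordered pairs including i = j (self-pairs contribute
their −d(i)²/(2N) term), N = number of directed edges. This is Newman
modularity of the symmetrized weighted graph, implemented verbatim
rather than a directed-modularity variant. Community detection is
fast-greedy agglomeration from singletons, merging the pair with the
largest strictly positive gain, ties broken by lowest label pair,
returning the best partition encountered. Greedy agglomeration is a
heuristic: on unstructured dense graphs it can miss the global optimum
by a few percent (verified against exhaustive partition enumeration on
tiny graphs); on clique-like community structure it recovers the
optimum. Both connected components and modularity communities are
reported, since "subnetwork" can mean either.

## Synthetic data

The generator draws exactly what the estimator assumes: HWE genotypes
(dosage ~ Binomial(2, MAF)), sparse Γ with effects uniform in a band
and spectral radius rejection-sampled below 0.9 (keeping (I − Γ)⁻¹
well-conditioned), Ψ supported inside each gene's body so the cis
window logic is exercised literally (genes on one chromosome at 10 kb
spacing, 5 kb bodies), Gaussian ε, and the exact solution
Y = (XΨ + ε)(I − Γ)⁻ᵀ. Expression is emitted on the log scale
directly for inference tests; a Poisson(2^Y) count mode exists solely
to exercise the preprocessing filters.

Default study conditions for the recovery experiments: p = 30 genes,
n = 800 samples, two cis variants per gene at MAF 0.3 with effect 0.8
(instrument strength R² ≈ 0.2 per gene), 10 regulations of |effect|
0.5, noise SD 1, B = 50 bootstraps. The endogeneity experiment adds a
shared standard-normal latent to both genes' disturbances — the regime
in which naive expression-on-expression regression fabricates edges and
instruments do not.

What the generator does **not** emulate: linkage disequilibrium between
variants, population admixture beyond a two-subpopulation PC test
fixture, count-level overdispersion, trans-eQTL effects, or nonlinear
regulation. Passing recovery tests therefore demonstrate correctness of
the estimator under its own assumptions, not robustness to the full
messiness of cohort data.

## Numerical choices and degenerate inputs

* All randomness flows from one master seed through named
  SeedSequence-derived streams (per gene, per bootstrap, per
  permutation block); worker count never changes any number.
* Zero-variance candidate columns are dropped with a warning; a
  constant instrument tests as degenerate (slope 0, p 1); an empty
  candidate list yields an instrument-less gene, not an error.
* Stage-level failures for a single gene are recorded and leave that
  gene's row of Γ̂ zero rather than aborting a transcriptome-wide run.
* Frequency thresholding compares integer counts (`count ≥ cutoff·B`
  with a 1e-9 guard), so boundary cutoffs like 0.95 behave exactly.
* Tolerances: projection/idempotence checks at 1e-10, lasso-path
  interpolation is exact to machine precision (asserted at 1e-8 against
  coordinate descent in tests), modularity against brute force at
  1e-12.

## Known limitations

* Outgoing edges of instrument-less genes are unidentified; no runtime
  rank-condition diagnostic beyond requiring ≥ 1 instrument is
  performed.
* The per-gene Bonferroni candidacy level is a convention; the
  appropriate multiplicity scope for instrument discovery (per-variant,
  per-gene, genome-wide) is exposed in config rather than decided.
* Lasso coefficients are shrunken; reported effect magnitudes are
  biased toward zero even when support recovery is exact.
* The burden permutation test is honest but conservative for sparse
  carriers; power at MAF near 0.01 is materially lower than at common
  MAF for the same effect size.
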