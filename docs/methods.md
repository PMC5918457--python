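# Methods

`famrv` implements gene-level rare-variant association tests for related
(family-based) samples, together with the surrounding machinery a real
study needs: pedigree kinship, quality control, family-based imputation of
missing genotypes, and a gene-dropping simulator that generates data with
exactly the statistical structure the tests assume. This note documents
the models, the numerical choices, and what the simulation-based checks do
and do not establish.

## The null model

For n subjects with phenotype Y and covariates X (intercept always
included), the null model is the polygenic linear mixed model

    Y = X beta + g + e,     g ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I),

where K is the covariance kernel: `2 * KCM` when relatedness comes from
the pedigree (KCM = matrix of kinship coefficients phi, so 2*phi is the
expected additive genetic correlation), or a genotype-derived GRM when
population substructure matters. Variance components are estimated by
restricted maximum likelihood (REML).

**Numerical strategy.** With a single kernel the restricted likelihood
profiles exactly to one dimension: after one symmetric eigendecomposition
K = U D U', rotating Y and X by U' diagonalizes the covariance, and for a
fixed ratio gamma = sigma_g^2/sigma_e^2 both beta-hat and sigma_e^2-hat
have closed forms. The profiled criterion is maximized over log(gamma) by
bounded scalar search, then polished by bisection on the analytic gradient
(80 iterations, so the optimum is a root of a freshly evaluated 1-D
function to machine precision and does not depend on the optimizer's
path). The sigma_g^2 = 0 boundary is always checked explicitly. We chose
this over iterative average-information REML because it is exact, has no
convergence failures to handle, and — decisive for the calibration
experiments — the O(n^3) eigendecomposition is computed once per kernel
and shared across all phenotype replicates, leaving each additional REML
fit at O(n) per likelihood evaluation. Covariate columns are standardized
internally (effects reported on the original scale) so that all downstream
p-values are invariant to covariate rescaling.

Binary phenotypes are fitted with the same working linear model on 0/1
outcomes. Under the null the resulting score tests retain their asymptotic
distribution; the prevalence-offset refinements of the quasi-likelihood
lineage for ascertained binary traits are deliberately out of scope.

## Score machinery and the four tests

For a gene with dosage columns G (missing entries imputed first, see
below) and per-variant weights w, the tests consume

    S = W^(1/2) G' P Y,    V = W^(1/2) G' P G W^(1/2),
    P = Sigma^-1 - Sigma^-1 X (X' Sigma^-1 X)^-1 X' Sigma^-1,

with Sigma = sigma_g^2 K + sigma_e^2 I at the REML estimates. Under the
null S ~ N(0, V) asymptotically, which is the only distributional fact the
tests use — relatedness enters solely through V.

* **Burden** (family-based weighted burden): Q_b = (1'S)^2 / (1'V1),
  compared to chi-square(1). Powerful when effects share a direction.
* **SKAT** (variance-component kernel test): Q_s = S'S, whose null is the
  mixture sum_i lambda_i chi2_1 with lambda_i the eigenvalues of V.
* **SKAT-O omnibus**: Q_rho = S'[(1-rho)I + rho J]S over the grid
  rho in {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1} (the established
  omnibus grid; a package choice, not a published constant). The statistic
  is the minimum per-rho p-value; its null probability is computed by the
  shared-factor decomposition: conditional on the common burden factor,
  the per-rho quantile constraints reduce to a one-dimensional integral
  over a chi-square(1) mixing variable, evaluated on a 48-node
  Gauss-Legendre grid after the substitution x = t^2 (which removes the
  density singularity at 0). rho = 1 is replaced by 0.999 inside the
  decomposition only; the endpoint statistics themselves are exact, so a
  single-point grid at rho = 0 or 1 returns SKAT or burden bit-for-bit.
  The result is capped by the Bonferroni bound over the grid and floored
  at the minimum per-rho p. When the decomposition degenerates (e.g.
  V1 ~ 0), the Bonferroni bound is returned and flagged.
* **Variable threshold (VT)**: thresholds are the distinct MAF values in
  the gene; at threshold T the weighted burden collapses variants with
  MAF <= T, giving z(T) = B(T)/sd(B(T)). The statistic is max_T |z(T)|
  (two-sided by default — protective effects are not excluded; a
  one-sided switch exists). Because phenotype permutation would break the
  family correlation, the null is taken exactly: the vector of z(T) is
  N(0, R) with R computed from V, and P(max |z| >= observed) is evaluated
  by randomized quasi-Monte-Carlo — 8192 Sobol points under a
  Cranley-Patterson rotation seeded per gene (unbiased; empirical
  accuracy ~1e-3) — with a Genz rectangle-probability refinement when
  fewer than 30 QMC exceedances remain, and always bracketed between the
  single-threshold bound 2*Phi(-stat) and its Bonferroni multiple. Plain
  Monte-Carlo draws (any count) and the pure Genz integral remain
  available as alternative methods and agree with the default within
  ~1e-3 in tests. Thresholds whose burden variance vanishes are dropped;
  variants sharing a MAF enter at the same threshold.

Default weights are Beta(MAF; 1, 25) as in the kernel-test lineage;
uniform and Madsen-Browning (1/sqrt(p(1-p))) are selectable. The default
rare-variant cutoff is MAF <= 0.05, and genes enter a scan only with at
least two rare variants and aggregate minor-allele count >= 4. Multiple
testing uses Bonferroni over tested (not skipped) genes.

## Mixture-of-chi-square tail probabilities

P(sum lambda_i chi2_1 > q) is computed by numerical inversion of the
characteristic function (Imhof's integral). The integrand
sin(theta(u))/(u rho(u)) oscillates at frequency ~q/2 under an envelope
decaying like u^-(1+m/2); it is integrated by composite 24-point
Gauss-Legendre panels of two oscillation periods each, truncated where
the envelope falls below tol * max(q/2, 0.01) (tol = 1e-9 by default),
plus a first-order integration-by-parts tail correction
g(U)cos(theta(U))/theta'(U), leaving a residual of order g'(U)/omega^2.
Batched evaluation shares one grid across many quantiles. Equal
eigenvalues use the closed chi-square form; eigenvalues contributing less
than 1e-5 of the total are dropped; the Liu-Tang-Zhang moment-matched
noncentral chi-square approximation is the fallback whenever the inversion
leaves (0, 1) or the grid would exceed its panel cap. Accuracy is verified
in tests against 1e6-draw sampling (within 3 Monte-Carlo SEs across
eigenvalue sets with ratios up to 1000:1) and, via the population
reduction oracle, against an independent Ruben-series implementation
(agreement ~1e-9).

## Kinship, QC and imputation

Kinship uses the classical recursion over a per-family topological order
(phi_ii = (1 + phi_fm)/2, phi_ij = (phi_fj + phi_mj)/2, founders
unrelated and non-inbred); a subject listing a single parent gets a
synthetic untyped founder partner so the recursion is total. Mendelian
checks test each offspring against the transmission bounds of its typed
parents (duos checked by default, switchable); an inconsistency increments
the variant once and each involved member once — an attribution
convention, since inconsistency identifies a trio, not a culprit.

Allele frequencies and Hardy-Weinberg statistics prefer founders, the
exchangeable unit in a pedigree: a variant's frequency comes from founders
when >= 30 founder alleles are typed there, else from all subjects; the
exact HWE test (conditional heterozygote-count enumeration, two-sided by
probability ordering) uses founder genotypes only. The filtering engine
applies subject rules first (call rate >= 0.95, Mendel rate <= 0.01),
recomputes variant statistics on the survivors, then applies variant
rules (call rate >= 0.95, HWE p >= 1e-8, Mendel rate <= 0.01) — the order
is fixed and documented because it affects the outcome. The HWE rule is an
*exclusion* threshold (variants with p < 1e-8 are removed). One pass is
made; a second pass with the same thresholds changes nothing on data
whose missingness is not adversarially concentrated, and the test suite
checks idempotence on such a fixture. The fixation index is the
Weir-Cockerham two-level estimator, combined genome-wide as a ratio of
sums. The GRM is the centered, frequency-scaled estimator with
pairwise-complete denominators; it is not forced positive semi-definite —
the REML layer adds a 1e-6 ridge if the spectrum dips negative.

Family imputation treats within-family dosages at frequency p as Gaussian
with mean 2p and covariance 2*Phi*2p(1-p) and fills missing entries with
the conditional (BLUP-type) expectation, clipped to [0, 2]; subjects with
no typed relatives get 2p. This linear form is exact for first and second
moments of Mendelian transmission and scales to arbitrary pedigrees;
exact peeling over genotype configurations would sharpen conditional
expectations for extreme genotype patterns and is noted as an extension.
The association layer uses the same rule for missing dosages inside a
tested gene (2p when no kinship matrix is supplied).

## The simulator and what the checks mean

`gene_drop` draws founder haplotypes Bernoulli(p) and transmits one
uniformly chosen allele per parent per variant, independently across
variants (linkage equilibrium). Phenotypes add a polygenic term drawn per
family from N(0, h^2 * 2KCM), residual N(0, 1-h^2), optional covariates
and optional per-variant causal effects scaled so a causal gene explains a
stated fraction of phenotypic variance. Built-in pedigree templates: trio,
a 3-generation 8-member family (grandparent couple, two children, two
marry-ins, two grandchildren), and a 3-generation 16-member family.
Defaults mirror the evaluation design the tests target: 50 families of 8,
200 genes of 8 rare variants with founder MAF ~ Uniform(0.001, 0.05)
(common variants for GRM construction draw from Uniform(0.05, 0.5)),
h^2 = 0.3, 200 null phenotype replicates on one fixed genotype panel —
40,000 null gene-tests, sized to finish in a few minutes on one CPU while
keeping the binomial SE of a 5% rate near 0.001. All randomness derives
from a master seed through a documented counter scheme
(SeedSequence((seed, stream, counter...))), so results are reproducible
piecewise and independent of scheduling or thread count.

What passing calibration shows: under Mendelian transmission, linkage
equilibrium, Gaussian phenotypes and a correctly specified kernel, the
four tests attain their nominal levels. What it does not show: robustness
to linkage disequilibrium between variants, genotyping error, ascertained
or heavy-tailed phenotypes, or kernel misspecification — none of which
the simulator generates.

Known limitation established during validation: in the mixed-direction
power regime (half the causal variants protective, effects at exact
cancellation, moderate power), the min-p omnibus trails the SKAT endpoint
by more than 0.05 in power. An exact Monte-Carlo omnibus — drawing the
null distribution of the minimum per-rho p directly — reproduces the same
power to the third decimal, so this is the multiple-testing cost inherent
in the min-p construction at that operating point, not an inaccuracy of
the analytic p-value (whose null calibration was verified empirically).

## Formats and conventions

Dosages count the ALT allele for VCF input and the minor allele for PED
input (orientation fixed after frequency computation, lexicographic
tie-break); the missing sentinel is NaN, never 0. Multi-allelic VCF sites
split into one bi-allelic record per ALT with carriers of other ALTs set
missing. Internal coordinates are 1-based; refFlat spans convert from the
UCSC 0-based-start convention on read (variant in gene iff
txStart < pos <= txEnd). One representative each of the interval
("gene chrom start end", 1-based closed) and direct ("variant_id gene")
mapping dialects is implemented. Relatedness matrices export as square
tab-delimited text with a `fid:iid` header row.
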