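# Methods

## Allele-balance model

Allele balance (AB) at position x is the fraction of amplified DNA derived
from haplotype 1, modeled as logistic(B(x)) with B a zero-mean Gaussian
process over genomic coordinates. The covariance

    k(x1, x2) = exp(a − (x1−x2)²/b²) + exp(c − (x1−x2)²/d²)

sums two stationary squared-exponential kernels. The short scale `d`
(default grid 10–1000 bp) absorbs correlation inflated by reads spanning
neighboring sites; the long scale `b` (500–50 000 bp) tracks amplicon-scale
imbalance, MDA amplicons being roughly 5–10 kb. `a` and `c` are
log-amplitudes (grid −6…1). The convention d ≤ b is enforced by swapping
terms, which removes the label ambiguity of a sum of identical kernel
forms. Observations are phase-standardized hSNP read counts: phasing lets
adjacent SNPs whose variant alleles lie on opposite haplotypes be reflected
(count → depth − count) onto one consistent haplotype, without which the AB
curve would show spurious jumps.

### Inference

The binomial likelihood makes the GP posterior non-Gaussian. We use the
standard Laplace scheme for GP models with non-Gaussian likelihoods:
Newton–Raphson on the latent block posterior (initialized at B = 0,
converged when the relative change of the log posterior falls below
√(machine ε) ≈ 1.5e-8, at most 50 iterations), with evidence

    log Z ≈ −½ αᵀB̂ + log p(Y|B̂) − Σ log diag(L),

L the Cholesky factor of I + W^{1/2} K W^{1/2} and W = D·p·(1−p) the
likelihood curvature. The binomial normalizing constants are included so
log Z estimates the true log evidence. A jitter of 1e-6·(e^a+e^c) is added
to K's diagonal before factorization.

Fitting treats a chromosome as independent blocks of 100 consecutive hSNPs
(a trailing remainder forms its own block) and maximizes the summed block
evidence over the parameter grid; the full grid of log-likelihoods is
returned for inspection. Prediction at a candidate site refits the hSNPs
within ±200 kb (capped at the nearest 100 per side) and applies the GP
predictive equations; with no hSNP in the window the site falls back to the
prior (μ = 0, σ² = e^a + e^c) and is flagged uninformed.

### Approximation accuracy

Against high-resolution numerical integration, the Laplace log evidence is
accurate to about 0.007 per site at depth ~30 and unit prior variance
(≈0.01 for 1-site blocks at depth 10, ≈0.02 for 3-site blocks). This is the
approximation's intrinsic error — the implementation agrees with an
independently coded 1-D Laplace to 1e-8 — and it cancels almost entirely in
the grid-search comparison of evidences. Posterior means and variances at
predicted sites agree with brute-force grid posteriors to ~1e-3 in typical
3-hSNP windows.

## Genotyping tests

All three tests compute the full outcome distribution P(Y = y′), y′ = 0…D,
by marginalizing a binomial over the Gaussian logit-AB posterior with
Gauss–Hermite quadrature (change of variable b = μ + √(2σ²)t, 128 nodes,
the count configurable; σ² = 0 reduces to the exact binomial). The p-value
of the observed count is the probability-ordered tail: the total probability
of outcomes no more probable (within 1e-12, ties included) than the observed
one. These discrete highest-density p-values are conservative by
construction: P(p ≤ α) ≤ α exactly under the null.

* ABC: null AB is μ* — whichever of ±μ has logistic value nearest the
  candidate VAF (ties to +μ), since a mutation may sit on either allele.
  Fixed cutoff 0.05.
* Artifact tests: equal mixture over the two alleles of
  Binomial(D, AB_allele/f), f = 2 for pre-amplification lesions (one strand
  of the allele), f = 4 for first-round amplification errors (one of four
  post-replication strands). The mixture is symmetric in μ → −μ, so no μ*
  is needed.

128 nodes resolve the integrand whenever the binomial outcome kernel is
wider than the node spacing; at the extreme of the tested range (depth 100
with σ² = 4) individual outcome probabilities are under-resolved and
doubling the node count restores agreement with dense-grid integration to
~1e-4. Operating σ² values — GP posterior variances with hSNPs in the
window — are far below that regime.

## Burden estimation and cutoff tuning

True sSNVs and hSNPs both sit on 50% of pre-amplification DNA, so their VAF
distributions should be similar in shape. Both sets are counted into 20 VAF
bins ([0,0.05), …, [0.95,1]). For a trial true-mutation count N_T, 1000
multinomial draws of size N_T with hSNP bin proportions are compared against
the candidate bin counts; the fit fraction F(N_T) is the share of draws
that nowhere exceed the observed counts, and the burden bound is the largest
N_T with F ≥ 0.005 (50-point geometric grid over [1, ΣS], then integer
bisection; each F(N_T) uses its own seeded stream so F is a well-defined
function of the data and seed). Per-bin expectations are
N_T,i = N_T·H_i/H and N_A,i = max(N_T·(1−H_i/H), 0.1); the 0.1 floor avoids
zero FDR estimates. The procedure runs per exact sequencing depth up to the
hSNP-depth 90th percentile, deeper sites pooled, with the unstratified table
as fallback for strata missing either site class. Candidates are binned by
raw single-cell alt VAF.

Artifact-test cutoffs are tuned per candidate: the achievable cutoffs are
the D+1 outcome-defined p-values of the artifact null; for each, power
1−β is the mass its highest-density rejection region captures under the
true-mutation model (ABC null at μ*), and the cutoff chosen is the largest α
with α·N_A/(α·N_A + (1−β)·N_T) ≤ θ (default θ = 0.1). α = 0 — no cutoff
meets the target — means the site is unpowered: the artifact hypothesis can
never be rejected there and the candidate fails. This matches the design
goal of calling only where power suffices; it is a heuristic guide, not
formal FDR control.

## Calling logic

A candidate passes single-sample genotyping iff p_ABC ≥ 0.05, p_preamp ≤
α_preamp, p_amp ≤ α_amp, no CIGAR flag, and depth ≥ 1. The artifact-test
polarity is deliberate: a small artifact p-value rejects the artifact
explanation and thereby *clears* the candidate, mirroring the logic in
which a candidate consistent with the pre-amplification model (large p) is
discarded even when its VAF looks mutation-like.

CIGAR filters compare each candidate's single-cell indel and clip read
fractions against 4000 sampled hSNP loci; the reference distribution is
restricted to hSNPs whose bulk fraction does not exceed the candidate's
(falling back to all sampled hSNPs when none qualify), and the candidate is
flagged above the 90th percentile. This bulk-conditioning reads the
two-dimensional (cell, bulk) comparison as "judge noisy-in-bulk loci against
equally noisy loci"; the one-dimensional alternative would flag every locus
that is merely hard to align in both samples.

Joint calling multiplies ABC p-values over samples with ≥1 supporting read
(J statistic), penalizing each factor by 1/10 when the GP posterior sd
exceeds 1. Thresholds come from J statistics of 4000 sampled hSNP sites
grouped by support count. The per-class threshold is the J value exceeded by
90% of the class's hSNPs — i.e. the 90th percentile counted from the
stringent end (the 0.10 quantile of J, linear interpolation), exposed as
`hsnp_pass_fraction`. Reading the percentile in the opposite direction
would reject 90% of genuine heterozygous sites and is incompatible with the
joint mode's purpose; the choice is configurable. Empty support classes
inherit the nearest smaller class's threshold. Joint mode applies no
artifact or CIGAR filters.

## Simulator

The generator draws hSNP positions with exponential spacing (mean 1500 bp,
the typical credible-hSNP spacing), an exact GP realization of B at all
sites (default truth a = 0, b = 10 000 bp, c = −4, d = 150 bp: unit-scale
logit variance with amplicon-scale correlation), truncated-Poisson depths
(mean 30 single cell and bulk), and binomial reads at each site's expected
fraction: the carrier-allele AB for hSNPs and true sSNVs (carrier haplotype
uniform), half that for pre-amplification artifacts, a quarter for
amplification artifacts. Bulk counts are balanced-binomial for hSNPs and
alt-free for somatic roles. Doublet mode halves the fraction of unshared
sSNVs (25% of template under balanced cell mixing). Fixtures are written as
a phased VCF, a joint count TSV and a truth TSV, byte-identical per config.

Default study conditions: 2000 hSNPs, 200 true sSNVs, 400 + 400 artifacts,
depth 30, target FDR 10%. Parameter-recovery checks use 5000 hSNPs over
three seeds; with these sizes the full test suite and the acceptance script
each run in minutes on one CPU.

What the simulator does *not* model: depth variability along the genome
(depths are i.i.d.), copy-number changes and structural variation, phasing
errors, chimeric reads, base-quality effects, and the branching structure of
MDA itself (artifact fractions are the idealized ½ and ¼ strand fractions).
Passing tests therefore demonstrate correctness of the statistical machinery
under the model's own assumptions, not robustness to every failure mode of
real amplified libraries.

## Numerical choices and degenerate inputs

* Probability ties in p-values and rejection regions use tolerance 1e-12.
* σ² = 0 posteriors bypass quadrature (exact binomial / mixture).
* Zero-depth candidates are flagged `low_depth` and auto-fail; zero-depth
  hSNPs are dropped at load time.
* Zero candidates in a stratum give N_T = 0, hence α = 0 (nothing callable).
* Multi-allelic and unphased VCF records are dropped with a warning; a
  duplicated hSNP position keeps the first record.
* The burden search and all subsampling are seeded; fits and predictions are
  fully deterministic.

## Known limitations

* The two-sided probability-ordered p-value is conservative at small depth;
  power below VAF ≈ 40% at 30× is minimal (by design, the ambiguity of
  imbalanced regions cannot be resolved by VAF alone).
* Laplace evidence carries an O(1/depth) per-site bias (quantified above);
  at grid-argmax level this is negligible, but absolute evidences should not
  be compared across models fit with different block structures.
* The depth-stratified burden tables are noisy for small simulated datasets;
  the unstratified fallback dominates unless strata are well populated.
* The diploid assumption is baked in: CNV regions shift true AB away from
  the model's expectations.
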