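# Methods

This note documents the statistical definitions, the partitioning and
scheduling model, the synthetic-data generator, and the numerical and
design choices behind `parallgwa`.

## Data model

Genotypes are biallelic SNP dosages: the code of individual *i* at SNP
*j* counts ALT alleles (0/1/2), with −1 for a missing call. Any
half-missing genotype (`0/.`) is treated as missing, and phase (`|` vs
`/`) is discarded everywhere — all estimators, including LD, assume
unphased data. Coordinates are 1-based (VCF convention); internal index
ranges are half-open and 0-based. Missing data are handled per statistic
by complete-case analysis, never by imputation.

## Per-SNP statistics (type 1)

**Genotype summary.** Counts n_AA/n_AB/n_BB/n_missing, call rate, and
alt-allele frequency q = (n_AB + 2 n_BB) / (2 n_called). An all-missing
SNP is reported with call rate 0 and NaN statistics rather than dropped,
so row order always matches input order.

**HWE exact test.** Conditional on the observed allele counts, the
heterozygote count h has the discrete distribution
P(h) ∝ n! 2^h / (n_rare-hom! · h! · n_common-hom!). The two-sided
p-value sums P(h) over all h (of matching parity) with P(h) ≤ P(h_obs);
ties are included and no mid-p correction is applied. Monomorphic
configurations give p = 1 by construction. The implementation evaluates
the log-weights with `gammaln`/`logsumexp`; the test suite checks it
against an exact-rational enumeration (integers + fractions) and the two
agree to 1e-12 for count sums up to 200. A tie slack of 1e-12 in log
space absorbs representation noise in exactly-tied states.

**Score test.** χ² = n·r², with r the Pearson correlation between
genotype code and trait over the n complete pairs. For a 0/1 trait this
is algebraically the Cochran–Armitage trend statistic (asserted to 1e-9
in tests). Zero genotype or trait variance gives χ² = 0, p = 1; fewer
than two complete pairs flags the row. P-values are the 1-df chi-square
survival function floored at the smallest positive normal double so
−log₁₀(p) stays finite.

**Regression.** Per-SNP `trait ~ genotype + covariates`. Linear models
are solved in closed form from the normal equations with the usual
σ̂²(XᵀX)⁻¹ covariance; logistic models by Newton–Raphson (start at 0,
max 25 iterations, gradient sup-norm tolerance 1e-8). The Wald statistic
is (β/se)². Inestimable rows — zero genotype variance, rank-deficient
design, singular information, non-convergence (which is how complete
separation manifests within the iteration cap) — carry a diagnostic code
in a `status` column instead of raising, because a genome scan must not
die on one degenerate SNP. Both models are cross-checked against
statsmodels in the test suite; statsmodels is never used in the
implementation itself.

## Per-individual statistics (type 2)

Call rate and heterozygous fraction per sample, and the
method-of-moments inbreeding estimate
F = (o_hom − e_hom) / (n_called − e_hom), where e_hom sums
1 − 2p_j(1−p_j) over the individual's called SNPs. Allele frequencies
p_j are computed once from the full sample including the focal
individual, with no n/(n−1) small-sample correction — the simplest
estimator consistent with routine QC practice; a leave-one-out variant
would change F by O(1/N) and is not implemented. Monomorphic SNPs
contribute 1 to e_hom automatically. Individuals with zero calls are
flagged (NaN), not dropped.

## Pairwise statistics (types 3 and 4)

**IBS.** Mean over pairwise-complete SNPs of 1 − |g_i − g_k|/2. The
frequency-weighted variant (genomic kinship) averages
(g_i/2 − p)(g_k/2 − p) / (p(1−p)) over pairwise-complete *polymorphic*
SNPs; its diagonal is 0.5(1+F_i) with F from the homozygosity module, so
an outbred self-kinship is 0.5. Pairs sharing zero usable SNPs are
flagged missing. The half-dosage residual scaling keeps the estimator on
the standard kinship scale used by the surrounding ecosystem.

**Two-locus EM.** Only the double-heterozygote cell of the 3×3 genotype
table is phase-ambiguous; EM splits it between the cis (AB/ab) and trans
(Ab/aB) resolutions proportionally to the current frequency product,
starting from linkage-equilibrium products. The haplotype-frequency
margins stay fixed at the observed allele frequencies at every
iteration, so the maximization effectively runs along the one free
parameter f_AB. Convergence: largest frequency change ≤ 1e-12 or 5000
iterations. The tolerance is deliberately tighter than the usual 1e-10
because EM's geometric convergence is slowest when the MLE sits on the
simplex boundary (f_AB → 0); at 1e-12 the attained log-likelihood is
within ~1e-10 of the optimum, which the tests verify by grid search over
the admissible frequency line at 0.001 resolution.

**LD statistics.** D = f_AB − p_A p_B; D′ = D/D_max with
D_max = min(p_A p_b, p_a p_B) for D > 0 and min(p_A p_B, p_a p_b) for
D < 0 (a zero bound yields D′ = 0 when D = 0 and ±1 otherwise — a
deterministic resolution of the 0/0 case); r² = D²/(p_A p_a p_B p_b);
ρ is the composite-LD measure, the plain Pearson correlation of the two
genotype-code vectors (the natural definition for unphased data, and the
one that needs no EM). Pairs with fewer than `min_shared` complete
observations (default 10) are flagged rather than estimated, because EM
on tiny tables is unstable. Matrix cells are always evaluated with the
two loci in canonical (min, max) column order, so the (i,k) and (k,i)
cells are bit-identical no matter which block computes them. LD matrices
support an optional same-chromosome base-pair window; pairs outside it
(or across chromosomes) are left missing, which mirrors how SNP-pair
scans bound their quadratic cost in practice.

## Partitioning

**Linear (types 1–2).** M items over P processors: P contiguous ranges
of ⌊M/P⌋ items, remainder attached to the last range (801 over 4 →
200/200/200/201). P > M is a parameter error: every processor must
receive work.

**Pairwise (types 3–4).** The n×n grid is decomposed into 4^d blocks.
Stage 1 halves [0, n) (remainder to the second half), producing diagonal
quadrants Q1/Q4 and off-diagonal quadrants Q2/Q3. Each further stage
re-quadrants every diagonal block (its diagonal structure must be
preserved) and cuts every off-diagonal block into four contiguous
near-equal strips — by rows, matching the documented scheme; when a
block has fewer than 4 rows the split falls back to columns, and in the
degenerate ≤3×≤3 corner to 2×2 quadrants. The fallbacks are reachable
only for very small n (they keep the `n ≥ 2^depth` contract exact down
to n = 2^depth) and never at realistic cohort sizes. Each block carries
its lineage (the quadrant/strip label chosen at every level), which is
how the depth-2 accounting — 8 blocks descended from the diagonal
quadrants, 8 row strips from the off-diagonal ones — is measured rather
than asserted.

Tiling is exact: the test suite covers every (n ≤ 64, depth ≤ 3)
exhaustively with a cell-coverage matrix. Areas are equal up to remainder
effects; for n ≥ 16·2^depth the measured max/min block-area ratio stays
≤ 2 (the worst observed is 1.86 at depth 3), while for tiny n remainder
effects dominate and only the tiling guarantee is meaningful.

**Depth selection.** depth = max(d_mem, d_proc, 1): d_proc is the
smallest d with 4^d ≥ P (at least one block per processor), d_mem the
smallest d with ⌈n/2^d⌉ ≤ side_max. The side cap (default 7000 items)
bounds a block at about side_max² pairs and is exposed as a tuning flag;
the default maps item counts of ≤14,000 / ≤28,000 / ≤56,000 to 4 / 16 /
64 subsets. The floor of depth 1 means even a single-processor run uses
at least 4 blocks, which keeps the merge path identical across processor
counts.

## Scheduling and merging

Tasks are (block, kind, payload description) triples with dense ids.
`run_tasks` executes each exactly once: a plain loop for P = 1 or the
serial executor, otherwise a fork-based local process pool in which at
most P tasks are in flight and each completion immediately admits the
next pending task (task pull — a slow task never blocks the queue behind
it). A worker exception becomes a failed-status result carrying the
traceback; remaining tasks still run, and failed tasks are retried only
if an explicit retry budget is given (default 0, keeping runs
deterministic).

Merging is a pure function of {results, plan}: linear results
concatenate in range order (row order equals the sequential run);
pairwise block results are placed at their grid positions, symmetric
duplicates must agree within 1e-12 (a violation raises a consistency
error, since it can only mean a worker bug), and the upper-triangle copy
is kept. Blocks strictly below the diagonal may be omitted by a
symmetry-exploiting schedule (off by default; the full-square plan is
the reference behavior) and are filled by mirroring. The end-to-end
guarantee — checked for all four computation types — is that output at
nprocs ∈ {1, 2, 4} is numerically *identical*, not merely close. Two
implementation details make this exactness cheap: per-column/per-row
reductions are used instead of shape-dependent BLAS calls in the
vectorized type-1/2 paths, and pairwise cells are computed by
symmetric-by-construction pair functions.

Workers receive the dataset bound into a picklable partial plus the task
naming their slice, relying on fork-time page sharing; at the scales
this package targets in one process space, a shared on-disk handle would
add lifecycle complexity without changing the contract, and the executor
interface (serial | processes) leaves room for a message-passing backend
where a cluster deployment needs one.

**Overhead model.** For a measured serial time t₁ and parallel time t_P,
overhead(t₁, t_P, P) = t_P − t₁/P; predicted time at Q processors is
t₁/Q + overhead, holding the overhead constant at its reference value.
This is a deliberately simple model: partitioning, distribution and
merge costs in fact vary with P, so extrapolations far from the
reference processor count are indicative only.

## Synthetic data

The generator emulates a genotyped cohort, not a population-genetic
process. Each individual is the sum of two independent haplotypes; each
haplotype is a first-order Markov chain over loci — the allele at locus
j is copied from locus j−1 with probability `ld_rho`, else drawn fresh
as Bernoulli(MAF_j). Consequences used by the tests: every locus is
marginally in HWE; `ld_rho = 0` gives independent loci with null
two-locus r² ≈ 1/n; `ld_rho = 1` duplicates columns; adjacent-pair LD is
tunable through one parameter. Missing calls are i.i.d. at a fixed rate,
drawn from a stream independent of the genotype draw. Phenotypes are
linear in dosage (missing genotypes contribute 0) with Gaussian noise,
or Bernoulli through the logit link; the case/control wrapper fixes the
case count exactly with genotype-independent labels (a null cohort). One
integer seed drives named generators only — no global state.

Default simulated conditions in the validation suite: a 200 × 2,000
case/control panel (85 cases / 115 controls, MAF 0.3, 2% missingness,
`ld_rho` 0.2) for the parallel-equals-sequential checks, with the
SNP-pair analysis run on its first 100 SNPs; 2,000 null SNP tests at
n = 500 for type-I-error calibration; 200 adjacent pairs at n = 2,000
(`ld_rho` 0.7) for EM-vs-true-haplotype r² accuracy; 20 × 100 panels for
brute-force matrix oracles. These sizes exercise every partition depth
and merge path while keeping the default suite fast.

What the generator does *not* model — population structure, relatedness,
coalescent LD decay, genotyping-batch artifacts, allele-frequency
spectra — bounds what passing tests show: correctness of the statistics
and the exactness of the parallel scheme on well-behaved data, not
robustness of the estimators to structured real cohorts.

## On-disk formats

VCF is read through cyvcf2 (biallelic SNP records only; others are
counted and skipped) and written through pysam — using two independent
libraries makes the VCF round-trip test a cross-validation of both
paths. The native tabular format is deliberately minimal: tab-separated
UTF-8, `NA` for missing, floats at 6 significant digits, fixed column
order, giving byte-identical files for identical inputs (the property
the parallel-equals-sequential file checks rest on). Genotype TSVs carry
a `<stem>.snps.tsv` metadata sidecar (name/chrom/pos/alleles); if it is
absent, placeholder metadata is synthesized so matrix-only files remain
usable.

## Known limitations

* Score and regression tests are 1-df dosage (additive) tests only; no
  genotypic/dominance models, no genomic control, no multiple-testing
  correction.
* Cox and mixed-model (polygenic) association tests are out of scope.
* LD is strictly two-locus; no multi-locus haplotype phasing or tests.
* The process-pool executor targets a single machine; distributed
  clusters would need a message-passing executor behind the same
  contract.
* The overhead model assumes constant overhead across processor counts.
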