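# parallgwa

Partitioned, task-pull parallel statistics for genome-wide association
(GWA) data.

In a typical GWA study hundreds of thousands of biallelic SNPs are typed
in thousands of individuals. The routine statistics fall into four
computation types by input structure, and each type parallelizes over the
data in its own way:

| type | input unit        | examples                                   | partitioning |
|------|-------------------|--------------------------------------------|--------------|
| 1    | one SNP / trait   | genotype summary, HWE exact test, score test, per-SNP regression | linear over SNPs |
| 2    | one individual    | call rate, heterozygosity, homozygosity / inbreeding F | linear over individuals |
| 3    | individual pairs  | identity-by-state (IBS), genomic kinship matrix | recursive pair-grid blocks |
| 4    | SNP pairs         | linkage disequilibrium (D, D′, r², ρ)      | recursive pair-grid blocks |

`parallgwa` implements the statistics natively and wraps them in a
generalized parallelization scheme:

* **Linear partitioning** cuts M items into P contiguous subsets of
  ⌊M/P⌋ items, the integer-division remainder going to the last subset
  (801 items over 4 processors → 200/200/200/201).
* **Pairwise partitioning** splits the n×n pair grid recursively into
  4^d equal-area blocks: the first stage halves the index range, giving
  two diagonal and two off-diagonal quadrants; at each further stage
  diagonal blocks split into their own four quadrants and off-diagonal
  blocks into four row strips. The depth d is chosen so the block count
  reaches the processor count and every block stays below a side cap
  (default 7000 items, i.e. ≤ ~49 M pairs per block).
* A **task-pull scheduler** hands each block to the next idle worker
  (serial loop or a local process pool) and the frontend **merges** the
  results deterministically: the merged table or matrix is *numerically
  identical* to the sequential computation for every processor count.
* An **overhead model** `overhead = t_P − t_1/P` quantifies the cost of
  parallelism from one measured pair (t₁, t_P) and extrapolates run time
  to other processor counts as `t_1/P + overhead`.

The statistical definitions: HWE uses the conditional two-sided exact
test (sum of all heterozygote-count probabilities ≤ the observed one);
the score test is `χ² = n·r²` over complete pairs, identical to the
Cochran–Armitage trend statistic for binary traits; LD comes from
maximum-likelihood two-locus haplotype frequencies fitted by EM on the
unphased 3×3 genotype table, with ρ the composite genotype correlation;
kinship uses `(g_i/2−p)(g_k/2−p)/(p(1−p))` averaged over polymorphic
SNPs, diagonal `0.5(1+F)`.

A synthetic-data module generates genotype panels under marginal
Hardy–Weinberg equilibrium with tunable allele frequencies, missingness
and first-order LD (haplotype copy chains), plus quantitative or binary
phenotypes with configurable SNP effects — so everything is testable
without downloading data.

## Worked example

Simulate a 500 × 1000 panel with one causal SNP (index 17, β = 0.35) and
run the score test on 4 worker processes:

```sh
parallgwa simulate --n-ind 500 --n-snp 1000 --maf 0.3 --missing-rate 0.02 \
    --seed 11 --beta 17:0.35 --out demo
parallgwa assoc --genotypes demo/genotypes.tsv --phenotypes demo/phenotypes.tsv \
    --trait trait --model score --nprocs 4 --executor processes --out demo/assoc
```

The top of `demo/assoc/assoc.tsv`, sorted by p-value:

```
    snp  chrom    pos   n  beta  se     chi2        p status
snp0018      1  18000 491   NaN NaN 15.44670 0.000085     ok
snp0822      1 822000 487   NaN NaN  9.78926 0.001755     ok
snp0289      1 289000 494   NaN NaN  8.95856 0.002762     ok
```

The planted causal SNP (snp0018) leads with χ² = 15.4 on 491 complete
pairs (p = 8.5×10⁻⁵ on 1 df); the remaining SNPs are null and behave
accordingly. `n` counts the complete genotype–trait pairs per SNP;
`beta`/`se` are reported by the regression models (`--model linear`
or `logistic`), not by the score test. Re-running with `--nprocs 1`
writes a byte-identical table.

Planning and extrapolation without running an analysis:

```sh
parallgwa partition-plan --type pairwise --n 20000 --nprocs 4   # 16 blocks
parallgwa predict-time --t1 8.1 --overhead 0.0875 --nprocs 8    # 1.1
```

With a measured 8.1 h serial run and 0.0875 h overhead, the predicted
times at 8/16/64 processors are 1.10/0.59/0.21 h.

Other subcommands: `snp-summary`, `individual-summary`, `ibs
[--weight freq]`, `ld --stat r2|dprime|rho [--window-bp W]`. Every
analysis writes result TSVs plus a `manifest.json` recording parameters,
seed and version; all accept `--nprocs`/`--executor`.

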