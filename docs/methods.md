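# Methods

## Data model and simulation

The unit of input is a per-SNP genotype-frequency table: for each
biallelic SNP, three genotype categories (coded 1/2/3) with case and
control counts. Counts from heterogeneous sources are first normalized
to a common group size by largest-remainder (Hamilton) apportionment:
each category receives `floor(target * count / total)` and the leftover
units go to the largest fractional remainders, with category order
breaking remainder ties. The rule is deterministic, sum-exact and
idempotent. The bundled 23-SNP table ships with its published counts
verbatim; one SNP's published case counts sum to 5003 rather than 5000
and are re-apportioned to (1716, 2434, 850) on load, which leaves every
odds ratio derived from them unchanged at 3 d.p.

Individual-level matrices are simulated per column as a uniform shuffle
of the fixed genotype multiset, so the tabulated margins of every column
equal the table's counts *exactly* for every seed — the sampling
variation lives entirely in the joint arrangement of genotypes across
rows. Column j of group g draws from a child random stream keyed on
`(seed, g, j)`, so extending the table never perturbs previously
simulated columns. Columns are independent given their margins: the
simulator emulates marginal genotype frequencies only. Real genotype
data additionally carries linkage disequilibrium, Hardy–Weinberg
structure, missingness and population stratification, none of which are
modelled — tests passing on simulated data therefore validate the
search and statistics machinery, not robustness to those features.

## Fitness and search space

A size-k barcode fixes k distinct SNPs to one genotype each; carriers
match all k positions (logical AND; no wildcards). Its fitness is the
absolute difference between carrier counts in cases and controls. The
space for k of n SNPs has C(n, k)·3^k candidates (2277·9 ≈ 20k for
k = 2 at n = 23, growing super-exponentially). Exhaustive enumeration
is exact and is used (a) for the whole size-2 level, (b) as the oracle
in tests; it refuses candidate counts above a configurable budget
(default 10^7). Everywhere, ranking is by fitness descending with ties
broken lexicographically by canonical (SNP indices, genotypes) — the
published method never states a tie rule, and a deterministic one is
required for reproducible archives.

## Plain swarm

Particles hold 2k continuous dimensions (k SNP dims in [1, n], then k
genotype dims in [1, 3]) with the standard update

    v ← w·v + c1·r1·(pbest − x) + c2·r2·(gbest − x),   x ← x + v

with r1, r2 drawn independently per dimension per iteration, velocities
clamped to ±(x_max − x_min) and positions clamped to the box. Defaults
follow the published settings: 50 particles, 100 iterations,
c1 = c2 = 2. The inertia weight is scheduled linearly from 0.9 to 0.4
over the run — the source states only that w is a linear function of
time, and 0.9 → 0.4 is the canonical Shi–Eberhart choice. Decoding
rounds each dimension half-away-from-zero, clamps, and repairs
duplicate SNP picks by substituting uniformly random unused SNPs; this
preserves the continuous update equations verbatim while guaranteeing
valid barcodes (the published encoding is integer but gives no
continuous↔discrete rule; 2k separate dimensions is our reading, as is
evaluation before the first move). pbest/gbest update on strict
improvement only, so incumbents are stable under ties and the gbest
trace is non-decreasing by construction. A run is fully deterministic
given (seed, config, dataset); with `iterations=0` it returns the best
of the initial population.

## Elitist (top-5 conserving) search

Sizes iterate 2…K. Size 2 is exhaustive, never stochastic. For k ≥ 3:

1. each of the ≤ 5 conserved (k−1)-barcodes is extended by the best
   single (unused SNP, genotype) addition, found by enumerating all
   (n − k + 1)·3 extensions (identical extensions from different
   parents collapse by deduplication);
2. a swarm runs with those extensions as elite seeds: after the random
   initial population is scored, the worst `len(seeds)` particles are
   repositioned exactly at the seed barcodes with zero velocity and
   personal bests preset to the seed scores, so an elite solution can
   never be lost before evaluation;
3. the size-k archive is conserved from the final personal bests plus
   the seeds (deduplicated, fitness-sorted, truncated to 5).

Step 3's union with the seeds means the archive never regresses below
the greedy extensions, giving the invariant best(k) ≥ max greedy
extension of archive(k−1) — asserted in tests on every run. Archive
capacities other than 5 are configurable but carry no reproducibility
claim.

## Association statistics

All statistics derive from the 2×2 table of carrier status × group
under the carrier-predicts-case convention (a = case carriers = TP,
b = control carriers = FP, c/d their complements), the unique
assignment consistent with the published per-barcode score tables:

* correctness (a+d)/n, sensitivity a/(a+c), specificity d/(b+d),
  PPV a/(a+b), NPV d/(c+d); 0/0 cells return 0 with a degenerate flag;
* risk ratio = carrier prevalence in cases over controls,
  (a/(a+c))/(b/(b+d)) — equal to a/b in balanced designs, which is the
  definition that reproduces the published RR column;
* odds ratio ad/bc with Woolf 95% CI (z = 1.96); any zero cell
  triggers the Haldane–Anscombe +0.5 correction, flagged;
* p-values from the 1-df chi-square with Yates continuity correction,
  χ² = n(|ad−bc| − n/2)²/∏margins, numerator floored at zero and
  degenerate margins returning p = 1. The corrected test (not the
  uncorrected one) reproduces the published exact p-values; Fisher's
  exact test is available behind a flag. Published confidence intervals
  differ from Woolf/1.96 in the third decimal for some rows and their
  exact method is unrecoverable, so CIs are reported but not validated
  against the source.

Single-SNP reports contrast genotypes 2 and 3 against genotype 1 within
each SNP. Display rounding follows the source tables (3 d.p. for
single-SNP ORs, 2 d.p. in barcode reports); JSON output keeps full
precision. The source tables themselves appear to round through an
intermediate 3-d.p. step, and a handful of printed cells are
arithmetically inconsistent with their own printed counts; the test
suite compares only self-consistent cells.

## Benchmarking

The reliability comparison runs both optimizers 20 times with paired
seeds on one shared simulated dataset (sharing isolates optimizer
variance, which is the quantity of interest; `--resimulate` folds in
sampling variance instead for the alternative reading). Per size it
summarizes medians, quartiles and 5/10/90/95 percentiles and computes a
two-sided Wilcoxon signed-rank test on the paired per-size best
fitnesses (exact null distribution when sample size permits, normal
approximation otherwise; an all-zero difference vector reports p = 1).

## Problem sizes and runtime choices

The default study conditions are the bundled table's: 23 SNPs, 5000
cases and 5000 controls, barcode sizes 2–10, 50 particles × 100
iterations, 20 benchmark runs. The full suite, including the 20-run
paired benchmark at these conditions, completes in a few minutes on one
CPU; the acceptance script summarizes the exhaustive 2-SNP maximum over
50 simulation replicates, a stable estimate of the statistic's median.
Note that the maximum over ~20k correlated candidates is an upward-
biased statistic: its across-seed median (~190 carriers) sits about 9%
above any single realization printed from one dataset draw.

## Known limitations

* Columns are simulated independently; no LD, so the method's behaviour
  under correlated SNPs is untested here.
* The fitness is direction-agnostic; protective barcodes are flagged
  (OR < 1) but risk barcodes rank equally.
* No multiple-testing correction across barcodes is applied, matching
  the source procedure; reported p-values are per-barcode.
* Exhaustive search is practical only for small sizes; larger sizes
  rely on the swarm, which carries no optimality guarantee beyond the
  elitism chain.
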