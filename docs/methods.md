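# Methods

## The analysis

promotif implements a promoter-motif over-representation analysis for gene
sets, of the kind used to ask whether disease-risk genes (schizophrenia, ASD,
DD/ID) preferentially carry Sp1/Sp4-type GC-boxes in their proximal
promoters.

The pipeline has four statistical stages over a *promoter universe* — one
TSS-anchored promoter per gene, all sharing a coordinate frame in which
offset 0 is the TSS (the reference universe is the EPD hg38 export of 16,455
genes over [-500, +100]):

1. **Motif scan.** An exact DNA motif (e.g. the GC-box `GGGCGG`) is searched
   on both strands: plus-strand hits are positions where the promoter equals
   the pattern, minus-strand hits are plus-strand positions of its reverse
   complement. All overlapping hits count; `N` never matches. An occurrence
   is assigned to a window `[lo, hi]` iff its leftmost plus-strand offset
   lies in `[lo, hi]` (start-based membership). The default analysis window
   is the proximal promoter `(-140, -41)` — 100 nt ending just upstream of
   the core promoter, where GC-boxes are functionally bound by Sp1/Sp4.

2. **Over-representation.** With `N` universe genes of which `K` contain the
   motif (>= 1 in-window occurrence), and a matched gene set of size `n`
   containing `k` motif genes, the enrichment p-value is the upper-tail
   cumulative hypergeometric probability

   `p = P(X >= k),  X ~ Hypergeom(N, K, n)`

   computed with scipy's exact survival function. Families of tests (the six
   gene sets tested per motif) are corrected with Benjamini–Hochberg
   step-up FDR. Note that BH is *not* idempotent (e.g. `[0.25, 1.0]` adjusts
   to `[0.5, 1.0]`, which adjusts again to `[1.0, 1.0]`); the implementation
   is the standard step-up, validated against a direct evaluation of
   `adj_i = min_{j>=i} p_(j) * m / j`.

3. **Count and GC-content comparisons.** Whether motif-containing risk genes
   carry *more* copies than motif-containing genes at large is tested with a
   randomization test: the group is a subset of the universe, so the null
   resamples uniform subsets of the same size from the background and
   recomputes the mean difference. Two-sided Monte-Carlo p with the add-one
   convention, `p = (1 + #{|T*| >= |T_obs|}) / (n_perm + 1)`, default
   `n_perm = 9999`. GC content (fraction of G/C over the window's plus
   strand — provably identical to counting G-or-C on both strands and
   dividing by twice the window length) is compared with Welch's unequal
   variance t test; one-way ANOVA is available for multi-group comparisons.
   Each p-value family is BH-corrected across groups.

4. **Positional profiles.** Sliding-window tracks with 1-nt shift: either
   the fraction of genes with >= 1 occurrence starting inside a window
   (window size 100 for group-level tracks) or, with window size equal to
   the motif length, the per-position occurrence frequency (the fine-grained
   relative-abundance track that reveals the proximal peak and the drop at
   ~40 nt upstream of the TSS).

## Coordinate conventions

Offsets are integers with the TSS base at 0; the region `(-500, 100)` is the
closed interval [-500, +100], 601 nt. Interval ends are inclusive
everywhere. Source databases differ on whether the TSS is 0 or +1 and
whether window ends are inclusive; this choice is explicit, uniform, and
configurable, and affects at most a few nucleotides at window boundaries.

Gene symbols are matched between sets and the universe by exact
case-insensitive comparison; no alias or HGNC resolution is attempted (that
would import an external database and make matching irreproducible).
Selecting one representative promoter per gene is the data supplier's job.

## The synthetic generator

`synthetic_data` generates universes with known structure so every stage is
testable without external downloads:

* i.i.d. bases with `P(G) = P(C) = gc_fraction/2`;
* per gene, `Poisson(plant_rate)` motif copies written at random
  non-overlapping starts inside `plant_window` on a uniformly chosen strand,
  overwriting background in place (sequence length is invariant). Copy
  counts exceeding what fits without overlap are truncated; placements are
  drawn greedily from a random permutation of candidate starts. Because the
  count is Poisson, a fraction `exp(-plant_rate)` of genes receives no
  planted copy even at high rates;
* gene sets drawn without replacement with weight `enrichment_odds` for
  motif-containing genes versus 1 otherwise (exponential-race sampling;
  odds = 1 is the uniform null).

Defaults are the study conditions of the reference analysis: 16,455 genes
over [-500, +100], `gc_fraction = 0.5`, `plant_window = (-140, -41)`, and
`plant_rate = 0.577`. The rate is calibrated once, in closed form, so that
the motif-containing fraction matches the human baseline of ~46.5%: with 100
candidate starts and a background per-start hit rate of `2*(g/2)^6`, the
fraction without any hit is `exp(-rate) * (1 - 2*(0.25)^6)^100 = 0.535`,
giving `rate = ln(0.952/0.535) ≈ 0.577`. Generated universes land at
46.1–46.7% across seeds.

What the generator does **not** emulate: dinucleotide/CpG structure, GC
heterogeneity across promoters, motif clustering, or any coupling between a
set's GC content and its disease status. Passing tests therefore demonstrate
correctness of the statistical machinery under a known null and alternative,
not biological conclusions about real promoter data.

`gen_table1_fixture` / `gen_table2_fixture` build deterministic count-level
fixtures whose marginals equal the published GC-box (K = 7,653 of
N = 16,455) and GA-box (K = 5,485) contingency tables, including the six
risk-gene sets with their matched/unmatched and motif-containing counts.
These validate the enrichment statistics end-to-end at printed precision.

## Numerical and design choices

* **Upper vs lower tail.** "Cumulative hypergeometric" is read as the upper
  tail P(X >= k): this reproduces every published p-value from its published
  counts to the printed 3–5 decimals, which a lower-tail or two-sided
  reading does not.
* **FDR family.** BH is applied within one table's six tests (per motif);
  joint correction across tables does not reproduce the published adjusted
  columns, separate correction reproduces both.
* **Permutation background.** The default compares a group against the full
  background of motif-containing genes (the group is itself a subset); an
  "exclusive" mode removes the group first. With groups of tens against a
  background of thousands the difference is negligible.
* **Randomization statistic.** Difference of group means, two-sided — the
  simplest falsifiable statistic for boxplotted count comparisons.
* **Discreteness of the enrichment p-value.** At set size 50 the
  hypergeometric p has atoms up to ~0.11, so its null distribution is
  super-uniform (`P(p <= a) <= a` with equality only at attained values) but
  not continuous-uniform; calibration tests check super-uniformity directly
  and apply KS to the randomized PIT `P(X > k) + V * P(X = k)`, which is
  exactly U(0, 1) under the null.
* **Degenerate inputs** are hard errors: empty matched sets, windows outside
  the universe region, groups larger than the background, zero-variance
  t-test inputs, out-of-range p-values.
* **Reproducibility.** Every stochastic operation takes one integer seed;
  pipeline runs derive one independent stream per (motif, group) and record
  seeds in output metadata. Two runs with identical (inputs, config, seed)
  produce byte-identical TSVs.

## Problem sizes used in the test suite

The test suite exercises scaled-down universes chosen to keep the full suite
fast while leaving comfortable statistical resolution: 4,000-gene universes
for calibration/power checks (500 null sets, 200 enriched sets), 2,000 genes
for the closed-form background-rate check, 1,000 random sequences for
scanner/oracle equivalence, and exhaustive subset enumeration for
backgrounds up to 12. The acceptance script runs the generator at its
full-size defaults (16,455 genes).

## Known limitations

* Exact-string motifs only — no PWM or IUPAC-degenerate scanning, by design.
* Symbol matching cannot recover genes listed under aliases; the matched
  counts depend on the supplied symbol conventions agreeing with the
  universe's.
* The permutation loop draws each subset in Python/numpy per iteration;
  at n_perm = 9999 against a background of ~7,600 genes a single test takes
  a few seconds.
* GC-content comparisons treat genes as independent; promoters of paralogs
  or bidirectional pairs are not deduplicated.
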