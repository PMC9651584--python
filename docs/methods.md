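# Methods

This note documents the models and numerical choices behind pedsight, in
the spirit of the methods documentation of statsmodels or msprime: what each
statistic assumes, how it is computed, and where the design was genuinely
open.

## Pedigree model

A pedigree is a directed acyclic graph of animal records. Canonical order is
topological (every parent precedes every offspring) with input row order as
tie-break, so all downstream single-pass recursions are well defined and the
ordering is a deterministic, idempotent function of the input. Parents that
are referenced but have no row are materialised as *phantom* founders;
phantoms count as founders for gene-origin bookkeeping but as *unknown* for
completeness metrics, because they encode the absence of information rather
than a known ancestor. Gene-origin routines additionally give every single
missing parental side a phantom founder (`~U<n>`), mirroring how studbook
software treats unknown ancestors as extra founders; this leaves all
relationship values among real animals unchanged.

Dates may be calendar dates or bare years; year-only records are mapped to
1 July (mid-year convention), which is unbiased for interval arithmetic on
year-resolution studbooks and costs at most half a year per endpoint.
Animals of unknown sex are retained for every genetic computation and only
excluded from the four sexed parent–offspring demographic paths.

An open question in real studbooks is what to do with records lacking sire,
dam and sex entirely. pedsight keeps them as potential founders/ancestors
(they may still appear as parents of other records); dropping them is a
caller-side filter, not a parser default.

## Completeness

* `max_gen`: longest ancestor path (dynamic programming over the canonical
  order).
* `full_gen`: deepest generation with all `2**g` ancestor slots filled,
  via `full(i) = 1 + min(full(sire), full(dam))` when both parents are
  known, else 0.
* `cge` (complete generations equivalent): `t(i) = Σ_p (1 + t(p))/2` over
  known parents, equal to Σ (1/2)^g over known ancestor slots. The
  invariants `full_gen ≤ cge ≤ max_gen` follow directly.
* `pci`: per parental side, the proportion of known ancestor slots in
  generation *j* (parent = generation 1, denominator `2**(j-1)` per side,
  slots counted with multiplicity), averaged over generations 1..d, then
  combined as the harmonic mean of the two sides. A missing parent zeroes
  its side, hence PCI = 0 for founders and half-orphans; on a fully known
  pedigree of depth g, PCI = min(g, d)/d. Default depth d = 5.

## Inbreeding and relationships

`inbreeding_meuwissen_luo` implements the per-animal ancestor trace with
the within-family segregation variances
`d_i = 0.5 − 0.25(F_s + F_d)` (0.75 − 0.25·F with one known parent, 1 for
founders): for each animal the path coefficients L are accumulated over its
ancestor set in decreasing canonical index and `F_i = Σ L_j² d_j − 1`.
Animals with an unknown parent have F = 0 by definition (the unknown side
is assumed unrelated). Complexity is linear in the traced ancestor set per
animal, so studbook-scale pedigrees are fast without forming **A**.

The tabular (recursive) relationship matrix is kept as an independent
algorithm; tests require bit-exact agreement of `a_ii − 1` with the
Meuwissen–Luo coefficients on pedigrees up to 50 animals and use it for
explicit submatrices (guarded by an ancestor-closure cap, default 4000).

Matrix-free products `A·x` use the decomposition
`A = (I−B)⁻¹ D (I−B)⁻ᵀ` with B holding the half parent links: one backward
substitution, a diagonal scaling, one forward substitution — O(n) per
product. Average relatedness is `A·1/n`; mean coancestries are
`xᵀA x / (2 m²)` with indicator vectors, self-coancestries
`f_ii = (1+F_i)/2` included throughout (this makes f_ge = 1 for a single
non-inbred animal and keeps the diversity-loss identity exact).

The individual increase in inbreeding is
`ΔF_i = 1 − (1−F_i)^{1/(t_i−1)}` with `t_i` the animal's CGE; animals with
`t_i ≤ 1` carry no rate information and return NaN. Effective sizes:
`N_e = 1/(2b)` from the OLS slope *b* of F on CGE (or on max_gen, by flag)
and `N_e = 1/(2·mean ΔF)`. Dispersions are delta-method standard errors of
the reciprocal (for the ΔF method, the standard error of the mean of ΔF_i
divided by `2·ΔF̄²`); a non-positive slope or mean yields an explicitly
undefined estimate rather than a negative size. CGE is the default
regression predictor; max_gen is exposed as an alternative.

## Gene dropping (ancestral vs. new inbreeding)

Founders carry two uniquely labelled alleles; each transmission picks one
parental allele with probability ½. An allele copy is *exposed* when some
strict ancestor on its transmission path was autozygous in the same
realisation; exposure flags travel with the copy and are updated by each
parent's own autozygosity. Restricting exposure to strict ancestors makes
`F_new + F_a-Kal = F̂` an exact partition within every run (the focal
animal's own IBD event cannot "expose" itself). Ballou's coefficient is the
probability that a randomly chosen one of the two alleles is exposed.
A single missing parental side contributes a fresh, never-exposed allele —
equivalent to the phantom-founder convention.

Monte-Carlo mode requires an explicit seed and reports binomial standard
errors; replicates are processed in batches with per-animal arrays freed
after their last descendant, bounding memory by the pedigree's active
width. Exhaustive mode enumerates all `2**T` transmission patterns (T = one
event per known-parent link, default cap 25) and returns exact dyadic
probabilities, which double as the oracle for the Monte-Carlo path.

## Probability of gene origin

Founder contributions are exact expectations by recursive halving
(no sampling); they sum to one because every lineage terminates in a
(possibly phantom) founder. `f_e = 1/Σp_i²`.

Effective ancestors follow the greedy marginal-contribution scheme: at each
round, for the current selected set S, a candidate's marginal contribution
is `r_S(k)·(1−β_k)` where `r_S(k)` is the share of the reference gene pool
reaching k along paths free of S (one reverse topological pass computes it
for all candidates at once) and `β_k` is the fraction of k's genome already
attributed to S in the pedigree with selected ancestors' parent links cut.
Equivalently, the marginal of k is the probability that k is the
earliest-selected ancestor on a random reference gene's transmission path,
which makes Σp_k = 1 at exhaustion and the marginal sequence non-increasing.
Candidates are proper ancestors of reference animals plus founders inside
the reference set; ties break by earliest canonical position, then id;
selection stops when the unexplained share drops below 1e−9.
`f_a = 1/Σp_k²`; `n50` is the smallest ancestor count explaining half the
pool.

**A caution on f_a ≤ f_e.** The folklore inequality f_a ≤ f_e holds in
bottleneck constructions and at full studbook scale, but it is not a
theorem of the greedy scheme: when the earliest picks are admixed
non-founder ancestors, the residual mass of a dominant founder can fragment
into several flatter marginals, leaving Σp_k² < Σp_i². In simulations of
small, heavily skewed pedigrees roughly one config in six shows f_a
exceeding f_e by 0.1–5 % (occasionally more). pedsight reports both numbers
as computed; tests assert the properties the algorithm actually guarantees
(mass conservation, monotone marginals, bottleneck detection).

`f_ge = 1/(2 f̄)` with f̄ the mean reference coancestry (self-pairs
included, matrix-free). Losses: total `1/(2 f_ge)` (= f̄ by construction),
founder-imbalance `1/(2 f_e)`, drift as the difference — an exact partition.
True and phantom founders are counted separately in summaries because
unknown-ancestor records inflate the nominal founder count.

## Wright's F-statistics

From mean coancestries of a labelled reference set: `f_S` is the weighted
mean within-subpopulation coancestry (subpopulations weighted by share
n_s/n by default; equal weighting by option), `f_T` the mean coancestry
over all reference pairs, `F̄` the mean inbreeding. Then
`F_IS = (F̄−f_S)/(1−f_S)`, `F_ST = (f_S−f_T)/(1−f_T)`,
`F_IT = (F̄−f_T)/(1−f_T)`, so `(1−F_IT) = (1−F_IS)(1−F_ST)` holds
algebraically and a single subpopulation gives F_ST = 0. One
relationship-matrix product per subpopulation keeps this matrix-free.

## Synthetic pedigrees

The forward simulator emulates a closed, managed large-herbivore studbook:
17 founders by default, two lineages seeded 12:5 with matrilineal herd
membership and 97 % within-lineage sire choice, overlapping cohort breeding
(the two most recent cohorts are eligible), negative-binomial lifetime
litter sizes (mean 4.7, dispersion 1.5 — heavy-tailed), and Dirichlet-
concentration male skew (0.03) calibrated so that under 20 % of males ever
reproduce, matching the strong sire skew of such populations. Birth years
advance by parental-age draws (mean 9 y) from 1881; lifespans are drawn so
a census date defines a living reference population. Censoring of parent
links and sex is applied *after* simulation, so exact ground truth
(founder-share vectors by recursive halving; F by the tabular method up to
3000 animals, Meuwissen–Luo beyond) is always available.

What the generator does **not** emulate: wartime record loss and later
corrections, non-random culling/management decisions, mtDNA lineage
structure, and real historical census trajectories. Passing tests therefore
demonstrate algorithmic correctness and statistical calibration on
studbook-*like* structure, not agreement with any particular historical
population.

Deterministic fixtures: the repeated full-sib chain
(`F_t = (1 + 2F_{t−1} + F_{t−2})/4`, exact in floating point because all
quantities are dyadic rationals) and a constant-size discrete-generation
random-mating population whose idealised effective size is close to its
census size N (used to calibrate the ΔF estimator: 20 replicates at N = 50
over 20 generations land within a few percent of N on average).

## Problem sizes and tolerances

Default verification runs use: random pedigrees up to 50 animals for
bit-exact algorithm cross-checks; a 2000-animal pedigree for matrix-free vs
explicit average relatedness (tolerance 1e−10); gene-drop fixtures with at
most 16 transmission events for exhaustive enumeration and 1e5 Monte-Carlo
replicates (3 binomial SE agreement); 100 simulator configurations
(6–20 founders, 8–14 cohorts, 80–200 animals per cohort) for gene-origin
properties; and ~7000-animal study-scale simulations for the end-to-end
report. The F-statistics identity is checked to 1e−9; exact dyadic
quantities (chain recurrence, exhaustive gene drop) to equality.
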