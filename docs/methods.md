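# Methods

This note records the models implemented in `aquacomm`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that make results reproducible.

## Preprocessing

OTU tables are filtered by a *fractional* rarity rule: a taxon is removed
when its total count across all samples is strictly below
`threshold_fraction` (default 1e-5, i.e. 0.001 %) of the grand total.
Ties at the threshold survive. Rarefaction subsamples each sample without
replacement (multivariate hypergeometric) to a common depth, defaulting to
the smallest library. The default order is filter → rarefy, switchable
with `rarefy_first=True`; rows are never dropped silently (an explicit
`drop_empty` switch exists). The rarefaction depth of the emulated design
is 16,984 reads per sample.

## Diversity and PERMANOVA

Alpha indices use the standard definitions (Chao1 with the
`F1(F1−1)/(2(F2+1))` bias correction; Shannon and Pielou with natural
logarithms; Faith's PD including the path to the root, matching the common
implementations). PCoA reports negative eigenvalues unchanged and computes
proportions explained over the positive eigenvalue mass only.

PERMANOVA partitions the Gower-centered squared-distance matrix with
**sequential (Type-I) sums of squares** in formula order and free
permutation of whole samples. The permutation p-value uses the add-one
rule and is therefore never zero; an `exhaustive=True` mode enumerates all
n! permutations for small n and returns the exact fraction. Sequential SS
with free permutation is a documented choice — with balanced designs the
term order does not change R², and the scheme is exactly reproducible.

## Assembly null models

betaMNTD is abundance-weighted by default (switchable); the nearest taxon
in the other community may be the same taxon, so shared taxa contribute
zero. The βNTI null shuffles tip labels uniformly over the whole tree
("taxa labels" scheme) with abundances untouched — the canonical null for
betaMNTD-based indices. Pairs with a zero-spread null (identical
communities, star phylogenies) cannot be standardized; they are reported
as βNTI = 0 with a degeneracy flag rather than an error, keeping matrices
total while preserving auditability.

Raup–Crick nulls preserve each sample's observed richness and read total:
taxa are drawn without replacement with probability proportional to
metacommunity occurrence frequency, each drawn taxon receives one read,
and the remaining reads are multinomial in metacommunity relative
abundance. The metacommunity defaults to the analyzed table itself; when
groups are partitioned separately (the default in `partition_by_group`,
which excludes cross-group pairs), each group is its own metacommunity.
RC = 2·[P(null < obs) + ½·P(null = obs)] − 1 ∈ [−1, 1].

Classification thresholds are ±2 for βNTI and ±0.95 for RC. Default
replicate count is 999; the validation suites use 199, which bounds the
Monte-Carlo error of βNTI well below the ±2 decision margin.

## Environmental breadth

TITAN scans candidate change points at the midpoints of sorted unique
factor values, maximizing IndVal (abundance-weighted form: relative
abundance concentration × relative frequency × 100). Significance comes
from permuting the gradient (default 250), purity and reliability from
bootstrap resampling of samples (default 100, nested permutation count
one fifth of the main count, floor 50). Indicator taxa require purity and
reliability ≥ 0.95 and at least 3 occurrences. Because "sum of taxa
scores" admits two readings, breadth reports both: the sum of indicator
|z| scores and the 5th–95th percentile span of indicator change points.
Group comparisons default to the span width, which matches the visual
semantics of range-style breadth displays; both numbers are always
exported.

## Functional redundancy

FRI(s, f) = Σ_i p_is · sim_i over possessing taxa present in s, with
sim_i the mean of (1 − d_ij/d_max) over the other present possessors and
d_max the tree diameter. The formula realizes the verbal definition of
redundancy as "proportion of species capable of the function, weighted by
their phylogenetic relationship": it is bounded in [0, 1], zero for ≤ 1
performer, monotone under replacing a performer with a more distant one,
and invariant to padding the incidence matrix with absent taxa. Function
incidence matrices are **inputs** (the reference-database prediction
pipeline is out of scope); synthetic incidence fixtures are generated at
run time. Group ratios are log10 of group-mean FRI with a configurable
pseudocount (default 1e-6 in the pipeline, 0 in the library function).

## Networks and stability

Correlation networks use Spearman correlations over samples (consistent
with the package's other rank-based screens) after a ≥ 50 % prevalence
filter. The RMT threshold scan (0.30–0.95, step 0.01) zeroes entries
below each candidate, unfolds the eigenvalue spectrum by cubic-polynomial
smoothing of the cumulative level count (duplicate eigenvalues collapsed
first), bins nearest-neighbor spacings into 30 bins, and chi-square-tests
them against the exponential (Poisson) law; the smallest candidate that is
Poisson-consistent (p > 0.05) for two consecutive steps wins. Degenerate
spectra (identity-like matrices, over-thresholded graphs) raise a
no-transition error and the pipeline falls back to a fixed 0.8 cutoff
with a logged warning.

Topology: average degree 2E/N, density 2E/(N(N−1)), diameter by
unweighted shortest paths on the largest connected component (thresholded
graphs are usually disconnected), modularity by greedy modularity
maximization on the unweighted graph.

Robustness: interaction strength b_ij = |w_ij|·√(a_i a_j) with a the mean
relative abundances; each replicate removes ⌊fN⌋ random nodes and then
iteratively extinguishes any node whose summed |b| over surviving
neighbors reaches zero (i.e. all links lost); robustness is the mean
surviving fraction of the original N. Vulnerability is
max_i (E − E_−i)/E with E the global efficiency (mean inverse shortest
path, zero for disconnected pairs).

Cohesion corrects pairwise correlations against a taxon-shuffle null in
two steps: each ordered pair has its mean null correlation subtracted,
and each taxon's positive (negative) connectedness — the mean positive
(negative) part of its corrected correlations — additionally has the null
expectation of that same statistic subtracted, clipped to the component's
sign. The second step is necessary because the positive part of pure
sampling noise has a strictly positive mean (≈ E|r|/2, around 0.1 at 16
samples); without it, an i.i.d. community would show spurious cohesion.
Per-sample cohesion is the abundance-weighted sum of connectedness; the
N:P ratio is |negative|/positive, undefined (missing) when positive
cohesion is zero.

## Synthetic generator

The generator emulates a 2-group × 4-stage × 4-pond design (32 samples),
thousands of taxa and a depth of 16,984 reads by default. Environmental
trajectories follow field-realistic anchor profiles: temperature falls
monotonically over the culture, ammonia and nitrite peak mid-culture,
nitrate and total nitrogen dip then rise; the predator group's nitrate
stage means are rescaled about their center so its excursion is
`nitrate_amplitude_ratio` (default 2 — a free parameter, as no measured
effect size exists for predator-driven amplification) times the control
group's, exactly, before per-observation Gaussian noise (default sd
0.02 mg/L, a plausible measurement error for nutrient assays).

The phylogeny is a pure-birth tree (unit split rate, strictly positive
branch lengths). Niche optima evolve as an unbounded Brownian walk along
branches with per-branch variance `trait_rate × branch length`, rooted at
the midpoint of the driver factor's range and clipped into it. The
default `trait_rate = 0.05` puts the walk's spread at roughly one third
of the environmental range on a 500-tip tree: clipping stays rare and
clades retain distinct niches. Much larger rates push most optima onto
the range boundaries, which erases the clade–niche association that makes
selection phylogenetically detectable — an instructive failure mode, not
a useful default.

Communities are multinomial draws of `depth` reads: Gaussian niche
weights exp(−(x_s − o_i)²/2σ²) under `selection` (driver factor: nitrate,
configurable), a shared log-normal(0, 1.5) metacommunity under `neutral`
(heavy-tailed rank-abundance structure), and a single realized pool
composition under `homogenizing_dispersal`.

What the generator does **not** emulate: read-level errors, chimeras,
compositional biases of PCR, taxonomy assignment uncertainty, and
temporal autocorrelation between stages. Passing recovery tests therefore
shows that the inference machinery is correct under its own model
assumptions — not that real sequencing data meet those assumptions.

## Validation problem sizes

Parameter-recovery suites use 500 taxa, 16 samples and 199 null
replicates — large enough that βNTI Monte-Carlo error is negligible
relative to the ±2 threshold, and matching the regime where the recovery
invariants were established. PERMANOVA calibration uses 1000 null
datasets at 99 permutations; TITAN recovery uses 24–30 sample gradients
with 8–10 planted step-response taxa per replicate. The shipped demo
scenario (300 taxa, 4,000 reads, 99 nulls) is sized so a complete
pipeline run takes under a minute on one CPU.

## Known limitations

- Sequential-SS PERMANOVA gives order-dependent term R² in unbalanced
  designs; specify the formula order deliberately there.
- The RMT criterion needs enough distinct eigenvalues (≥ 60) to test a
  spacing distribution; small or highly degenerate correlation matrices
  fall back to a fixed threshold.
- RC-bray assumes integer counts (rarefied tables); relative-abundance
  inputs are rejected rather than silently rounded.
- The TITAN implementation covers taxon-level change points and breadth;
  community-level sum(z) curves are not produced.
- FRI depends on the incidence matrix supplied; no attempt is made to
  predict gene content from 16S.
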