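# aquacomm

Community-ecology analysis for aquaculture bacterioplankton surveys:
null-model partitioning of community assembly processes, environmental
breadth from threshold indicator taxa, phylogeny-aware functional
redundancy, and co-occurrence-network stability — together with a
synthetic-community generator that provides ground truth for all of it.

## Who this is for

Microbial ecologists analysing 16S OTU tables from designed pond or
mesocosm experiments (groups × stages × replicates) who want to ask: *is
community assembly driven by environmental selection or by stochastic
processes, and how do disturbances shift that balance?* The motivating
system is crustacean aquaculture ponds with and without an apex predator
(groups `MC` / `PC`), sampled across four culture stages, but nothing in
the library is specific to that design.

## The statistics at the core

**Assembly partitioning.** For every sample pair the phylogenetic turnover
is measured by the abundance-weighted β-mean-nearest-taxon distance,

    betaMNTD(A,B) = ½ [ Σ_{i∈A} f_iA · min_{j∈B} d_ij  +  Σ_{j∈B} f_jB · min_{i∈A} d_ij ],

with `d` the patristic distance. Its standardized effect size against a
tip-shuffling null (βNTI = (obs − mean_null)/sd_null) classifies pairs:
βNTI < −2 homogeneous selection, βNTI > +2 variable selection. Pairs not
explained by selection are ranked by the Raup–Crick metric on Bray–Curtis
against nulls that preserve each sample's richness and read total
(RC < −0.95 homogenizing dispersal, RC > 0.95 dispersal limitation,
the remainder drift). The five fractions sum to one; selection terms form
the deterministic fraction, the rest the stochastic fraction.

**Environmental breadth.** Threshold indicator taxa analysis locates each
taxon's change point along an environmental gradient (the split maximizing
IndVal = abundance concentration × occurrence frequency × 100), with
permutation z-scores and bootstrap purity/reliability. A community's
breadth for a factor is the 5th–95th percentile span of its indicator
change points (and, as a second reading, the sum of indicator |z| scores).

**Functional redundancy.** FRI(s, f) = Σ_i p_is · sim_i over the taxa
possessing function `f` in sample `s`, where `sim_i` is the mean
phylogenetic similarity (1 − d/d_max) to the other present possessors —
zero when at most one present taxon can perform the function.

**Network stability.** Co-occurrence networks are thresholded correlation
graphs, with the cutoff chosen by the random-matrix-theory criterion
(smallest threshold whose unfolded eigenvalue spacing distribution turns
Poisson). Stability is summarized by robustness (surviving fraction under
random node removal with extinction cascades), vulnerability (largest
single-node drop in global efficiency), and positive/negative cohesion
(abundance-weighted, null-corrected taxon connectedness).

## Worked example

The shipped demo simulates a selection-driven community (300 taxa, 32
samples = 2 groups × 4 stages × 4 ponds, 4,000 reads/sample, predator
group nitrate excursion doubled) and runs every stage:

```bash
aquacomm run --config configs/demo.yaml --outdir demo_out
```

It finishes in well under a minute and `demo_out/summary.json` contains,
among others (seed 42):

```
assembly.MC.deterministic  = 0.467      assembly.PC.deterministic  = 0.725
envadapt.breadth MC.nitrate span_width = 0.281
envadapt.breadth PC.nitrate span_width = 0.488
diversity.permanova stage R2 = 0.634 (p = 0.005)
```

Read: within-group sample pairs in the predator group are classified as
deterministically assembled more often than in the control group (0.725
vs 0.467), because the amplified nitrate excursion pushes more pairs past
the |βNTI| > 2 selection threshold; the predator group's indicator taxa
also spread their nitrate change points over a 1.7× wider span — a
broader environmental breadth. Culture stage explains most of the
community variance in the two-way PERMANOVA. All of this mirrors what the
generator planted, which is the point: every downstream statistic is
validated by parameter recovery against known regimes.

The same pipeline runs on real data by replacing the `scenario` block
with an `inputs` block (OTU table TSV, rooted newick tree, metadata TSV,
environment TSV); `aquacomm simulate` writes synthetic datasets in
exactly those formats.

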