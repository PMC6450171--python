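# Methods

This note documents the models, numerical choices, and design
decisions behind the package, and what the synthetic-data tests do and
do not demonstrate about real data.

## Abundance model and transforms

OTU tables are dense matrices of non-negative counts, OTUs × samples.
All multivariate analyses (correlation networks, spanning trees,
Bray–Curtis/PCoA, PERMANOVA) run on Hellinger-transformed values
`√(x_is / Σ_i x_is)`: the square root of relative abundances makes
Euclidean geometry ecologically meaningful for sparse count data and
down-weights dominant taxa.  All-zero sample columns (failed samples)
transform to all-zero rather than raising, so such samples remain
representable and can be excluded explicitly downstream.  Exact tests
(Fisher enrichment) always run on raw integer counts — exact
hypergeometric probabilities are undefined on transformed values.

Rarefaction uses the analytic hypergeometric expectation
`E[S(d)] = Σ_i 1 − C(N−n_i, d)/C(N, d)` rather than Monte-Carlo
subsampling; the unit suite verifies it against 10,000 subsamples.

## Networks

Networks are `networkx.Graph` objects with a `role` attribute per node
(otu / sample / genotype-bin / property) and `weight` + `sign` per
edge.

*Sample similarity.* Pearson correlation between Hellinger columns,
and Proportional Similarity `PS = Σ min(p_i, q_i)` on proportions.
Constant vectors get correlation 0 (with a warning) instead of NaN so
spanning trees stay connected; this is conservative — it never
fabricates similarity.  Maximum spanning trees convert similarity `s`
to distance `1 − s` and run Kruskal with lexicographic edge-label tie
breaking, so trees are reproducible across platforms.  Totals are
verified against brute-force Prüfer enumeration on 6-node instances.

*Enrichment hypergraphs.* For OTU *i* and analysis unit *u* the 2×2
table is the read-mass partition (a = reads of *i* in *u*, b = reads
of *i* elsewhere, c = other reads in *u*, d = other reads elsewhere).
The one-sided (greater) Fisher exact test expresses "enrichment"; the
two-sided variant is available.  Zero-margin tables return p = 1 by
convention.  FDR families follow the analysis structure: all pairs of
one matrix form one Benjamini–Hochberg family; in genotype-binned mode
binning, testing, and FDR run independently within each soil.  Control
samples are analyzed as a separate family from treatment samples.
The quotient coefficient divides an OTU's enrichment degree by the
number of distinct genotypes its enriched samples span; OTUs spanning
≤ 2 genotypes with quotient ≥ 2 are flagged genotype-specific.

*Co-occurrence and MCL.* OTUs seen in < 3 samples are removed; edges
require |Pearson| ≥ 0.6 across all samples of the experiment.  MCL is
implemented from scratch: self-loops (weight 1.0), column-stochastic
normalization, then alternating expansion (matrix power 2) and
inflation (elementwise power 2.5, renormalize) with pruning of entries
< 1e-6, to a fixed point (max column change < 1e-8, ≤ 200 iterations).
Rows holding positive diagonal mass in the limit matrix seed clusters;
each node joins the seed with maximal limit mass in its column, and
seeds sharing any column's support are merged (ties to the lowest
index), which resolves MCL's rare overlapping attractors
deterministically.  Nodes left alone keep background label 0.  MCL
requires non-negative weights, so it runs on |r|; the sign of each
correlation is retained only as edge metadata.  Correctness is checked
by exact clique recovery, an inflation→granularity trend, and ≥ 95 %
pairwise agreement with an independently written reference
implementation on two-block graphs.

*Topology.* Degree; clustering coefficient `2·e_N / k(k−1)`;
topological coefficient `T(n) = mean_m J(n,m)/k(n)` over nodes *m*
sharing ≥ 1 neighbor, where `J` counts shared neighbors plus 1 when
*n*, *m* are adjacent; unnormalized betweenness with even splitting
over equal-length shortest paths.  Coefficients are defined 0 for
degree < 2.  Betweenness is validated against exhaustive path
enumeration on all ≤ 7-node test graphs.

*Soil-property links.* Property–property Pearson across soils plus an
MST, reusing the spanning-tree machinery.  Property→OTU correlations
are computed at sample resolution (each soil's value broadcast to its
samples) because OTU abundances vary per sample; a soil-mean
alternative is provided (`resolution="soil-mean"`).  Edges at
|r| ≥ 0.6 are annotated with the OTU's community label.

## Differential abundance (FCROS)

OTUs present in < 3 samples are dropped; the variance-stabilizing
transform is log2(x+1) — the pseudocount keeps zeros at zero and the
transform monotone.  Quantile normalization maps every column onto the
mean-of-order-statistics reference; ties receive the mean of their
reference span, making the operation idempotent.  For each of the
n_a·n_b cross-class pairs, per-OTU log fold changes are ranked
(average ranks on ties) and normalized by (m+1); averaged ranks r̄ are
standardized over OTUs and mapped through the normal CDF to the
f-value (probability of over-abundance), with p = 2·min(f, 1−f).
Over-abundant: f ≥ 0.9 and p ≤ 0.05; under-abundant mirrored at
f ≤ 0.1.  The f-values are anti-symmetric under class swap
(f → 1 − f), which the suite asserts to 1e-9.

## Community statistics

Bray–Curtis `Σ|p−q| / Σ(p+q)`; PCoA by Gower double-centering and
eigendecomposition, axes with non-positive eigenvalues dropped (all
eigenvalues reported), axis signs fixed by making the
largest-magnitude loading positive.  One-way PERMANOVA computes
`SS_total = Σ d²/n` and within-group analogues; pseudo-F =
`(SS_b/(k−1)) / (SS_w/(N−k))`; p from label permutations with the
stated seed, `(hits+1)/(B+1)`.  Only one-way designs are supported:
the target study design tests single factors after finding no
significant interactions.  PERMDISP embeds samples by PCoA keeping
negative axes (their squared contributions are subtracted — the
standard imaginary-part handling), measures distances to group
centroids, and permutes *labels with full recomputation* of centroids
and distances: permuting only the observed distances is
anticonservative because each group's centroid is fitted to its own
points (measured empirical type-I error ≈ 0.17 at α = 0.05 under that
scheme, vs ≈ 0.05 with recomputation).  Centroids (not spatial
medians) are used, documented as the simpler default.

Indicator analysis scores each OTU for each group — and optionally
each non-trivial union of groups — with IndVal `√(A·B)`: specificity
A = target mean abundance over the sum of per-group means (group-size
uncorrected), fidelity B = occurrence fraction in target samples.  The
best-scoring target is tested by permuting sample labels (counting
permuted best-stat ≥ observed), then BH-corrected across OTUs.  The
singleton-target path is vectorized over OTUs so 999+ permutations are
cheap.

## Synthetic data generator

The generator emulates the processed-OTU-table stage of a two-locus
(fungal ITS + bacterial 16S) 454 amplicon study; it does not simulate
reads, chimeras, or PCR bias.  Per sample, a latent log-abundance
vector is drawn and counts follow a single multinomial draw at a
library size uniform in 346–4065 reads (use 68–1950 to mimic a
shallower run); the log-normal-latent + multinomial scheme produces
the compositional coupling and block-correlation structure the
network stage consumes, unlike independent per-OTU negative binomials.

Structure planted (defaults in parentheses; all configurable):

- **Communities** (5, sizes 6–12, mixed fungal–bacterial): members
  load positively (λ ∈ [0.7, 1.3]) on a shared factor
  `z_{c,s} = soil shift + genotype shift + sample noise (sd 0.3)`.
  Soil-shift vectors of distinct communities are Gram–Schmidt
  decorrelated (projections use an orthonormalized copy of the basis)
  so the planted factors stay identifiable with only 8 soils; two
  communities instead ride on generated soil properties chosen to be
  mutually independent.  Member baselines are N(1.5, 0.5) on the log
  scale — moderately abundant, detectable taxa.
- **Background** (the rest): independent log-normal baselines
  (sd 1.0) with per-sample noise sd 1.0.
- **Soil effects**: soil_effect_sd 1.2 by default.  This value keeps
  the planted communities' share of each library moderate; with much
  larger shifts the communities capture most of the reads and
  compositional closure correlates every background OTU with every
  other, which is a property of the simulation rather than of the
  analysis.  "Strong effect" checks use soil_effect_sd 2.0, where
  ≥ 90 % of within-community pairs exceed |r| = 0.6.
- **Differential OTUs** (20, log2 fold change ±2 between the two soil
  halves): consistently present (baseline N(1.5, 0.5)) with replicate
  noise at the community-member level (sd 0.3) — a 4-fold shift is
  only a testable signal when replicate noise is below it.
- **Soil specialists** (16, 2 per soil): present only in their soil,
  boosted 3.5 log units there — the generative meaning of a
  soil-specific indicator taxon.
- **Controls** (3 samples): drawn from a disjoint 12-taxon pool,
  emulating low-diversity uninoculated substrate.

Soil properties are correlated Gaussians with deliberately collinear
adjacent pairs to exercise the property-MST stage.

**Recovery scoring.** Planted truth labels background OTUs 0 meaning
"no community", not "one community".  `planted_recovery_ari` therefore
computes the Adjusted Rand Index over planted OTUs by default;
`include_background=True` scores each background OTU as its own
singleton on both sides.  The background null edge rate is tested
separately (< 1 % at |r| ≥ 0.6, n = 30 samples).

**What passing tests show — and don't.** The generator reproduces the
statistical structure the analyses assume (compositional counts,
soil-blocked factors, sparse detection at realistic library sizes),
so green tests demonstrate the pipeline recovers structure of the
planted kind at the planted strength.  They do not demonstrate
robustness to features the generator omits: taxon-specific PCR/primer
bias, chimeras and OTU-clustering artifacts, phylogenetic correlation
among OTUs, or gradient (non-block) environmental structure.

## Problem sizes and determinism

Simulated experiments in the tests and the acceptance script use 300
OTUs (100 fungal + 200 bacterial) across 8 soils × 4 replicates, and
smaller nulls (80 OTUs, 4 soils × 4) for 1,000-replicate calibration
runs; these sizes preserve the structure of the full design while
keeping every check quick on a laptop.  Permutation counts: 199 for
calibration sweeps, 999 for single-dataset inference.  All randomness
flows from explicit seeds; the pipeline expands one global seed into
independent per-stage substreams (SHA-256 of `seed:stage`), so adding
a stage never perturbs another stage's stream, and identical
config + seed reruns are byte-identical (the run manifest records
content hashes and no timings).

## Known limitations

- One-way PERMANOVA only; no interaction or nested designs.
- The enrichment contingency layout is the standard read-mass
  partition; alternative layouts (e.g. presence-based) are not
  implemented.
- MCL is dense (O(n³) per iteration) — fine for hundreds of OTUs,
  not for tens of thousands.
- Indicator analysis with group combinations enumerates all unions;
  practical only for modest group counts.
- The FCROS under-abundance cutoff mirrors the over-abundance
  threshold (f ≤ 1 − 0.9); this symmetric reading is a documented
  interpretation.
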