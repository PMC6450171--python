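# rhizonet

Network analysis of fungal–bacterial root microbiomes ("rhizobiomes")
from amplicon OTU tables.  The package targets the common-garden /
trap-plant study design: plant cuttings rooted in field soils act as
bait for compatible root microbiota, and the question is how much of
the assembled community is structured by soil origin, soil chemistry,
and host genotype.

It is written for microbial ecologists who have a processed OTU count
table (OTUs × samples), a taxonomy table with fungal/bacterial domain
tags, and sample/soil metadata — and who want the full downstream
workflow as tested, scriptable functions rather than a chain of GUI
tools.

## What it computes

Given an OTU table **X** (rows = OTUs *i*, columns = samples *s*) the
pipeline provides:

- **Hellinger transform** — `x̃_is = √(x_is / Σ_i x_is)`, applied ahead
  of all multivariate analyses.
- **Sample similarity** — Pearson *r* and Proportional Similarity
  `PS(p,q) = Σ_i min(p_i, q_i)`, summarized as maximum spanning trees
  (distance `1 − s`), plus raw bipartite OTU–sample presence networks.
- **Enrichment hypergraphs** — per OTU × sample (or per soil×genotype
  bin) 2×2 contingency tables on read counts, one-sided Fisher exact
  tests, Benjamini–Hochberg FDR at 0.01; enriched pairs become edges.
  Genotype specificity via the quotient coefficient
  `degree / #genotypes spanned` with the "≤ 2 genotypes, quotient ≥ 2"
  selection rule.
- **Co-occurrence communities** — OTUs with ≥ 3 non-zero samples,
  pairwise Pearson on Hellinger values, absolute threshold 0.6, and a
  from-scratch **Markov Cluster (MCL)** implementation (expansion 2,
  inflation 2.5) yielding hard OTU communities; per-node degree,
  clustering coefficient, topological coefficient, and betweenness;
  per-community fungal/bacterial composition (mixed / fungal-only /
  bacterial-only).
- **Soil-property links** — property–property correlation MST and
  |r| ≥ 0.6 property→OTU edges mapped onto communities.
- **Differential abundance (FCROS)** — log2(x+1), quantile
  normalization, fold-change rank-order statistic: per cross-class
  sample pair, OTUs are ranked by fold change; averaged normalized
  ranks give the probability of over-abundance
  `f = Φ((r̄ − μ_r̄)/σ_r̄)`, flagged at f ≥ 0.9 (or ≤ 0.1) and
  p = 2·min(f, 1−f) ≤ 0.05.
- **Community statistics** — Bray–Curtis, PCoA, one-way PERMANOVA
  (pseudo-F, R², permutation p), PERMDISP dispersion homogeneity,
  IndVal-style indicator-species analysis (`stat = √(A·B)` with
  specificity A, fidelity B, permutation p, BH FDR), chi-square
  OTU-detection tests.
- **Synthetic data** — a generator that emulates the processed-OTU
  stage of a 454 amplicon study (library sizes 346–4065 reads/sample,
  soil-structured planted communities, property-linked communities,
  exclusive soil specialists, 4-fold differential OTUs, low-diversity
  control samples) with full planted ground truth.

## Worked example

```python
import rhizonet as rz

# simulate a soil-origin experiment: 8 soils x 4 replicates, 300 OTUs,
# 5 planted mixed fungal-bacterial communities
cfg = rz.SimConfig(seed=11, n_soils=8, replicates_per_soil=4,
                   n_fungal_otus=100, n_bacterial_otus=200,
                   n_planted_communities=5)
table, frame, taxonomy, truth = rz.generate_dataset(cfg)

treatment = table.select_samples(frame.noncontrol_ids())
net = rz.correlation_network(treatment, threshold=0.6, min_nonzero=3)
part = rz.mcl_cluster(net, inflation=2.5)
comp = rz.community_composition(part, taxonomy)
print(part.n_communities, int((comp["class"] == "mixed").sum()))

d = rz.bray_curtis_matrix(rz.hellinger_transform(treatment))
res = rz.permanova(d, {s: frame.soil_of(s) for s in treatment.sample_ids},
                   n_permutations=999, seed=1)
print(round(res.R_squared, 3), res.p_value)
```

prints

```
29 17
0.544 0.001
```

i.e. MCL finds 29 co-occurrence communities of which 17 mix fungi and
bacteria, and soil origin explains ~54 % of the community sums of
squares (p = 0.001) — soil, not noise, structures the simulated
rhizobiome, as it does in the real system.

A full run from one config file:

```bash
rhizonet run-all config.yaml --out results/
```

emits per-stage TSV tables, GraphML/edge-TSV network exports, and a
`manifest.json` with content hashes; identical config + seed gives
byte-identical outputs.

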