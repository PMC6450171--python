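"""Synthetic OTU-table generator with planted ground truth.

Emulates the processed-OTU-table stage of a trap-plant common-garden
amplicon study: cuttings rooted in field soils act as bait for
compatible root microbiota, so community composition is structured
primarily by soil origin, with weaker genotype effects that are
conditional on soil.  The generator plants co-abundant OTU
communities driven by shared latent factors, links some of them to
generated soil physicochemical properties, spikes differential OTUs
between two designated sample classes, and adds low-diversity control
samples drawn from a disjoint taxon pool — so that the network,
enrichment, differential and indicator stages can all be tested
against known truth.

Counts are drawn multinomially per sample from the softmax of latent
log-abundances, at a library size uniform in the configured range.
The log-normal-latent + multinomial scheme (rather than independent
per-OTU negative binomials) induces the compositional coupling and
block correlation structure the co-occurrence stage consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rhizonet.data_model import (
    CONTROL_SOIL,
    OtuTable,
    SampleFrame,
    TaxonomyTable,
    write_otu_table,
)

SOIL_PROPERTY_POOL = [
    ("Ca", "ppm"), ("Mg", "ppm"), ("K", "ppm"), ("P", "ppm"),
    ("pH", "pH units"), ("organic_matter", "%"), ("clay", "%"),
    ("sand", "%"), ("distance_to_river", "cm"), ("CEC", "meq/100g"),
]


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the generative model.

    Defaults mirror the soil-origin experiment design: 8 soils with
    replicated single-genotype plantings, ~160 fungal plus a larger
    bacterial OTU pool, and per-sample-per-locus library sizes
    uniform in 346-4065 reads (the processed-read range of that
    experiment; use 68-1950 for a genotype-experiment-like run).
    """

    n_soils: int = 8
    replicates_per_soil: int = 4
    n_genotypes: int = 0            # 0 => single-genotype design
    n_fungal_otus: int = 161
    n_bacterial_otus: int = 300
    n_planted_communities: int = 5
    community_size_range: tuple[int, int] = (6, 12)
    soil_effect_sd: float = 1.2
    genotype_effect_sd: float = 0.0
    genotype_effect_is_soil_conditional: bool = True
    n_soil_properties: int = 8
    n_property_linked_communities: int = 2
    base_log_abundance_sd: float = 1.0
    overdispersion: float = 0.3     # per-sample latent noise sd (community members)
    background_noise_sd: float = 1.0  # per-sample latent noise sd (background OTUs)
    community_abundance_boost: float = 1.5  # added to members' baseline log abundance
    library_size_range: tuple[int, int] = (346, 4065)
    n_control_samples: int = 3
    control_taxa_count: int = 12
    n_differential_otus: int = 20
    differential_log2_fc: float = 2.0
    n_indicator_otus: int = 16
    indicator_effect: float = 3.5   # log-unit boost inside the preferred soil (absent outside)
    loading_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0

    def __post_init__(self):
        if self.library_size_range[0] <= 0 or self.library_size_range[1] < self.library_size_range[0]:
            raise ConfigError("library_size_range must be positive and ordered")
        for name in ("n_soils", "replicates_per_soil", "n_fungal_otus", "n_bacterial_otus",
                     "n_planted_communities", "n_control_samples", "control_taxa_count"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.seed is None:
            raise ConfigError("seed is mandatory")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of one generated dataset.

    community: otu_id -> planted community label (0 = background).
    linked_property: community label -> soil property name driving it.
    soil_shifts: per-community, per-soil latent mean shift.
    differential: otu_id -> planted log2 fold change between the two
    designated classes (first half vs second half of soils).
    control_taxa: OTUs reserved for control samples.
    """

    community: dict[str, int]
    linked_property: dict[int, str]
    soil_shifts: dict[int, dict[str, float]]
    differential: dict[str, float]
    control_taxa: list[str]
    indicator_soil: dict[str, str] = field(default_factory=dict)

    def members(self, label: int) -> list[str]:
        return [o for o, c in self.community.items() if c == label]


def _soil_properties(cfg: SimConfig, rng: np.random.Generator, soil_ids: list[str]) -> tuple[pd.DataFrame, dict[str, str]]:
    """Correlated Gaussian soil properties with a few collinear pairs."""
    k = min(cfg.n_soil_properties, len(SOIL_PROPERTY_POOL))
    names = [n for n, _ in SOIL_PROPERTY_POOL[:k]]
    units = {n: u for n, u in SOIL_PROPERTY_POOL[:k]}
    n = len(soil_ids)
    base = rng.normal(size=(n, k))
    # make adjacent property pairs collinear-ish to exercise the MST stage
    for j in range(1, k, 3):
        base[:, j] = 0.9 * base[:, j - 1] + 0.1 * base[:, j]
    vals = 100 + 30 * base
    return pd.DataFrame(vals, index=soil_ids, columns=names), units


def generate_dataset(config: SimConfig):
    """Simulate one experiment.

    Returns ``(OtuTable, SampleFrame, TaxonomyTable, PlantedTruth)``,
    deterministic under the configured seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_otus = cfg.n_fungal_otus + cfg.n_bacterial_otus
    fungal = [f"F_OTU_{i+1}" for i in range(cfg.n_fungal_otus)]
    bacterial = [f"B_OTU_{i+1}" for i in range(cfg.n_bacterial_otus)]
    otus = fungal + bacterial
    domain = {o: "fungal" for o in fungal} | {o: "bacterial" for o in bacterial}

    soil_ids = [f"S{i+1}" for i in range(cfg.n_soils)]
    genotypes = [f"G{i+1}" for i in range(cfg.n_genotypes)] or ["G1"]

    # --- sample layout -----------------------------------------------------
    rows = []
    for soil in soil_ids:
        for g in genotypes:
            for r in range(cfg.replicates_per_soil):
                sid = f"{soil}.{g}.r{r+1}" if cfg.n_genotypes else f"{soil}.r{r+1}"
                rows.append((sid, soil, g, False, "exp1"))
    for c in range(cfg.n_control_samples):
        rows.append((f"CTRL.r{c+1}", CONTROL_SOIL, genotypes[0], True, "exp1"))
    samples = pd.DataFrame(
        rows, columns=["sample_id", "soil_id", "genotype_id", "is_control", "experiment_id"]
    ).set_index("sample_id")

    soils_df, units = _soil_properties(cfg, rng, soil_ids)
    frame = SampleFrame(samples=samples, soils=soils_df, units=units)

    # --- planted communities ----------------------------------------------
    # control taxa first, from the bacterial tail; disjoint from treatment pool
    control_taxa = bacterial[-cfg.control_taxa_count:] if cfg.control_taxa_count else []
    assignable = [o for o in otus if o not in control_taxa]
    sizes = rng.integers(cfg.community_size_range[0], cfg.community_size_range[1] + 1,
                         size=cfg.n_planted_communities)
    if sizes.sum() > len(assignable):
        raise ConfigError("planted community sizes exceed the available OTU pool")
    community: dict[str, int] = {o: 0 for o in otus}
    cursor_f, cursor_b = 0, 0
    for c, size in enumerate(sizes, start=1):
        # mixed fungal-bacterial membership: alternate pools
        n_f = max(1, int(round(size * cfg.n_fungal_otus / n_otus)))
        n_f = min(n_f, size - 1)  # keep >=1 bacterium -> mixed class
        members = fungal[cursor_f:cursor_f + n_f]
        cursor_f += n_f
        n_b = size - len(members)
        pool_b = [b for b in bacterial if b not in control_taxa]
        members += pool_b[cursor_b:cursor_b + n_b]
        cursor_b += n_b
        for o in members:
            community[o] = c

    # property links: community c driven by property p
    linked_property: dict[int, str] = {}
    props = frame.property_names
    # step by 3: properties are generated with collinear adjacent pairs,
    # so linked communities must ride on mutually independent properties
    for c in range(1, min(cfg.n_property_linked_communities, cfg.n_planted_communities) + 1):
        linked_property[c] = props[(3 * (c - 1)) % len(props)]

    # per-community per-soil mean shifts; shift vectors of distinct
    # communities are decorrelated (Gram-Schmidt) so the planted
    # factors stay identifiable at a handful of soils
    soil_shifts: dict[int, dict[str, float]] = {}
    ortho_basis: list[np.ndarray] = []  # orthonormalized copies used for projection

    def _orthogonalize(vec: np.ndarray) -> np.ndarray:
        for q in ortho_basis:
            vec = vec - (vec @ q) * q
        return vec

    for c in range(1, cfg.n_planted_communities + 1):
        if c in linked_property:
            p = soils_df[linked_property[c]].to_numpy()
            z = (p - p.mean()) / (p.std() or 1.0)
        else:
            z = _orthogonalize(rng.normal(0, 1.0, cfg.n_soils))
            sd = z.std()
            if sd > 1e-6:
                z = (z - z.mean()) / sd
            else:
                z = rng.normal(0, 1.0, cfg.n_soils)
        q = _orthogonalize(z.copy())
        norm = np.linalg.norm(q)
        if norm > 1e-8:
            ortho_basis.append(q / norm)
        soil_shifts[c] = dict(zip(soil_ids, (cfg.soil_effect_sd * z).tolist()))

    # genotype shifts (soil-conditional or global)
    geno_shift: dict[int, dict[tuple[str, str], float]] = {}
    for c in range(1, cfg.n_planted_communities + 1):
        d = {}
        if cfg.genotype_effect_is_soil_conditional:
            for soil in soil_ids:
                for g in genotypes:
                    d[(soil, g)] = rng.normal(0, cfg.genotype_effect_sd)
        else:
            per_g = {g: rng.normal(0, cfg.genotype_effect_sd) for g in genotypes}
            for soil in soil_ids:
                for g in genotypes:
                    d[(soil, g)] = per_g[g]
        geno_shift[c] = d

    # differential OTUs between class A (first half of soils) and class B
    half = cfg.n_soils // 2
    class_a = set(soil_ids[:half])
    background = [o for o in assignable if community[o] == 0]
    diff_otus = background[: cfg.n_differential_otus]
    differential = {o: cfg.differential_log2_fc * (1 if i % 2 == 0 else -1)
                    for i, o in enumerate(diff_otus)}

    # soil-specific indicator taxa: strong preference for one soil,
    # assigned round-robin from the background pool after the
    # differential block
    ind_otus = background[cfg.n_differential_otus:
                          cfg.n_differential_otus + cfg.n_indicator_otus]
    indicator_soil = {o: soil_ids[i % len(soil_ids)] for i, o in enumerate(ind_otus)}

    # --- latent log abundances --------------------------------------------
    otu_index = {o: i for i, o in enumerate(otus)}
    mu = rng.normal(0, cfg.base_log_abundance_sd, n_otus)
    # planted members are moderately abundant co-varying taxa: narrower
    # baseline spread centred on the boost keeps them detectable without
    # letting community mass swings dominate the library (which would
    # couple every background OTU through compositional closure)
    for o in otus:
        if community[o]:
            mu[otu_index[o]] = cfg.community_abundance_boost + 0.5 * rng.standard_normal()
    for o in indicator_soil:
        # specialists are reliably detectable where they occur: moderate
        # baseline, the preference itself comes from indicator_effect
        mu[otu_index[o]] = 0.5 * rng.standard_normal()
    for o in differential:
        # differential taxa are consistently present, moderately abundant:
        # a 4-fold shift is only testable when replicate noise is below it
        mu[otu_index[o]] = 1.5 + 0.5 * rng.standard_normal()
    loadings = rng.uniform(*cfg.loading_range, n_otus)  # positive: co-abundant groups
    treatment_ids = frame.noncontrol_ids()
    lat = np.zeros((n_otus, len(treatment_ids)))
    for j, sid in enumerate(treatment_ids):
        soil = frame.soil_of(sid)
        g = frame.genotype_of(sid)
        z = {c: soil_shifts[c][soil] + geno_shift[c][(soil, g)] + rng.normal(0, cfg.overdispersion)
             for c in range(1, cfg.n_planted_communities + 1)}
        col = mu + rng.normal(0, cfg.background_noise_sd, n_otus)
        for o in otus:
            c = community[o]
            i = otu_index[o]
            if c:
                col[i] = mu[i] + loadings[i] * z[c] + rng.normal(0, cfg.overdispersion)
        for o, lfc in differential.items():
            # planted log2 fold change: +lfc/2 in class A, -lfc/2 in class B,
            # replicate noise at the community-member level
            i = otu_index[o]
            col[i] = (mu[i] + rng.normal(0, cfg.overdispersion)
                      + (lfc / 2 if soil in class_a else -lfc / 2) * np.log(2))
        for o, pref in indicator_soil.items():
            # exclusive specialists: boosted in their soil, absent elsewhere
            if soil == pref:
                col[otu_index[o]] += cfg.indicator_effect
            else:
                col[otu_index[o]] = -np.inf
        # control taxa absent from treatment samples
        for o in control_taxa:
            col[otu_index[o]] = -np.inf
        lat[:, j] = col

    # --- multinomial sampling ---------------------------------------------
    lo, hi = cfg.library_size_range
    counts = np.zeros((n_otus, len(frame.sample_ids)), dtype=np.int64)
    col_of = {s: j for j, s in enumerate(frame.sample_ids)}
    for j, sid in enumerate(treatment_ids):
        logits = lat[:, j]
        w = np.exp(logits - np.max(logits[np.isfinite(logits)]))
        w[~np.isfinite(logits)] = 0.0
        p = w / w.sum()
        depth = int(rng.integers(lo, hi + 1))
        counts[:, col_of[sid]] = rng.multinomial(depth, p)
    ctrl_idx = [otu_index[o] for o in control_taxa]
    for sid in frame.control_ids():
        if not ctrl_idx:
            continue
        logits = mu[ctrl_idx] + rng.normal(0, cfg.overdispersion, len(ctrl_idx))
        w = np.exp(logits - logits.max())
        p = w / w.sum()
        depth = int(rng.integers(lo, hi + 1))
        counts[ctrl_idx, col_of[sid]] = rng.multinomial(depth, p)

    table = OtuTable(
        data=pd.DataFrame(counts, index=otus, columns=frame.sample_ids),
        marker="ITS", scale="counts",
    )
    tax = TaxonomyTable(data=pd.DataFrame(
        {r: ["" for _ in otus] for r in
         ("kingdom", "phylum", "class", "order", "family", "genus", "species")}
        | {"domain": [domain[o] for o in otus]},
        index=pd.Index(otus, name="otu_id"),
    ).assign(kingdom=lambda d: np.where(d["domain"] == "fungal", "Fungi", "Bacteria")))
    truth = PlantedTruth(
        community=community,
        linked_property=linked_property,
        soil_shifts=soil_shifts,
        differential=differential,
        control_taxa=control_taxa,
        indicator_soil=indicator_soil,
    )
    return table, frame, tax, truth


def write_fixture(dataset, directory, overwrite: bool = False) -> dict[str, Path]:
    """Write the four TSV artifacts plus the planted-truth file.

    Layout: otu_table.tsv (dense), samples.tsv, soils.tsv,
    taxonomy.tsv, truth.tsv (otu_id, community, lfc, is_control_taxon)
    and truth.json (property links, soil shifts).
    """
    table, frame, tax, truth = dataset
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} is not empty (pass overwrite=True)")
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu_table": directory / "otu_table.tsv",
        "samples": directory / "samples.tsv",
        "soils": directory / "soils.tsv",
        "taxonomy": directory / "taxonomy.tsv",
        "truth": directory / "truth.tsv",
        "truth_meta": directory / "truth.json",
    }
    write_otu_table(table, paths["otu_table"], dialect="tsv-dense")
    frame.samples.to_csv(paths["samples"], sep="\t", index_label="sample_id")
    frame.soils.to_csv(paths["soils"], sep="\t", index_label="soil_id")
    tax.data.to_csv(paths["taxonomy"], sep="\t", index_label="otu_id")
    rows = [
        (o, truth.community[o], truth.differential.get(o, 0.0), o in truth.control_taxa)
        for o in table.otu_ids
    ]
    pd.DataFrame(rows, columns=["otu_id", "community", "lfc", "is_control_taxon"]).to_csv(
        paths["truth"], sep="\t", index=False
    )
    with open(paths["truth_meta"], "w") as fh:
        json.dump(
            {
                "linked_property": {str(k): v for k, v in truth.linked_property.items()},
                "soil_shifts": {str(k): v for k, v in truth.soil_shifts.items()},
                "indicator_soil": truth.indicator_soil,
            },
            fh, indent=1, sort_keys=True,
        )
    return paths


def planted_recovery_ari(truth: PlantedTruth, labels: dict[str, int],
                         include_background: bool = False) -> float:
    """Adjusted Rand Index between planted communities and a clustering.

    ``labels`` maps otu_id -> cluster label (0 = unclustered), e.g.
    ``CommunityPartition.labels``.  By default the score is computed
    over the planted OTUs only — background OTUs are independent by
    construction, not a community, so their pairings measure the null
    edge rate rather than recovery.  With ``include_background=True``
    every background OTU counts as its own singleton class on both
    sides.
    """
    from sklearn.metrics import adjusted_rand_score

    tl, pl = [], []
    next_t = next_p = 10 ** 6
    for otu, pred in labels.items():
        c = truth.community.get(otu, 0)
        if c == 0 and not include_background:
            continue
        if c == 0:
            next_t += 1
            tl.append(next_t)
        else:
            tl.append(c)
        if pred == 0:
            next_p += 1
            pl.append(next_p)
        else:
            pl.append(pred)
    return float(adjusted_rand_score(tl, pl))
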