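"""End-to-end pipeline orchestration and network exports.

``run_pipeline`` reads one declarative YAML config (either pointing
at input TSVs or carrying a ``simulate`` block), runs the requested
stages in dependency order, and writes per-stage TSV tables, network
exports and a run manifest.  A single global seed is expanded into
independent per-stage substreams so inserting a stage never perturbs
another stage's randomness.  Identical config + seed produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

import rhizonet
from rhizonet.data_model import (
    read_otu_table, read_metadata, read_taxonomy,
    hellinger_transform, filter_min_occurrence,
)
from rhizonet.synthetic_data import SimConfig, generate_dataset, write_fixture
from rhizonet.similarity_networks import (
    pearson_similarity_matrix, proportional_similarity_matrix,
    maximum_spanning_tree, bipartite_presence_network,
)
from rhizonet.enrichment import build_enrichment_network, genotype_quotient_selection
from rhizonet.cooccurrence import (
    correlation_network, mcl_cluster, topology_measures, community_composition,
)
from rhizonet.environment_links import soil_property_network, property_otu_community_map
from rhizonet.differential import differential_pipeline
from rhizonet.community_stats import bray_curtis_matrix, permanova, permdisp, indicator_analysis

log = logging.getLogger("rhizonet")

STAGES = ("simulate", "transform", "networks", "enrich", "communities",
          "envlinks", "differential", "indicators", "stats")

EXPORT_FORMATS = ("graphml", "edge-tsv", "sif-like")


def export_network(net: nx.Graph, path, fmt: str = "edge-tsv") -> None:
    """Write a network with deterministic node/edge ordering.

    GraphML keeps node role/domain/community attributes and edge
    weight/sign; edge-TSV is (source, target, weight, sign); sif-like
    is the three-column interaction format of common graph viewers.
    """
    path = Path(path)
    nodes = sorted(net.nodes)
    edges = sorted((min(str(u), str(v)), max(str(u), str(v))) for u, v in net.edges)
    if fmt == "graphml":
        h = nx.Graph(**net.graph)
        for u in nodes:
            h.add_node(u, **net.nodes[u])
        for u, v in edges:
            h.add_edge(u, v, **net.edges[u, v])
        nx.write_graphml(h, path)
    elif fmt == "edge-tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\tsign\n")
            for u, v in edges:
                d = net.edges[u, v]
                fh.write(f"{u}\t{v}\t{d.get('weight', 1.0):.10g}\t{d.get('sign', 'none')}\n")
    elif fmt == "sif-like":
        with open(path, "w") as fh:
            for u, v in edges:
                d = net.edges[u, v]
                fh.write(f"{u}\t{d.get('sign', 'none')}\t{v}\n")
    else:
        raise ValueError(f"unsupported format {fmt!r}; supported: {EXPORT_FORMATS}")


def _stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage substream below 2**31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config_path, out_dir=None) -> Path:
    """Run the configured stages; return the artifact directory."""
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    out = Path(out_dir or cfg.get("output_dir", "rhizonet_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", list(STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage name(s): {sorted(unknown)}; valid: {STAGES}")
    thresholds = {
        "correlation_threshold": 0.6, "inflation": 2.5, "enrichment_fdr": 0.01,
        "indicator_alpha": 0.05, "fcros_f": 0.9, "fcros_p": 0.05, "min_nonzero": 3,
    } | cfg.get("thresholds", {})

    handler = logging.StreamHandler(sys.stderr)
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict = {
        "config_sha256": _hash_file(config_path),
        "seed": seed,
        "version": rhizonet.__version__,
        "stages": {},
        "outputs": {},
    }

    def emit(name: str, writer) -> None:
        p = out / name
        writer(p)
        manifest["outputs"][name] = _hash_file(p)

    table = frame = tax = None
    if "simulate" in stages:
        t0 = time.time()
        sim = dict(cfg.get("simulate", {}))
        sim.setdefault("seed", _stage_seed(seed, "simulate"))
        for key in ("library_size_range", "community_size_range", "loading_range"):
            if key in sim:
                sim[key] = tuple(sim[key])
        table, frame, tax, truth = generate_dataset(SimConfig(**sim))
        fixture_dir = out / "fixture"
        write_fixture((table, frame, tax, truth), fixture_dir, overwrite=True)
        for f in sorted(fixture_dir.iterdir()):
            manifest["outputs"][f"fixture/{f.name}"] = _hash_file(f)
        manifest["stages"]["simulate"] = {"n_otus": table.shape[0], "n_samples": table.shape[1]}
    else:
        inputs = cfg["inputs"]
        table = read_otu_table(inputs["otu_table"], dialect=inputs.get("dialect", "tsv-dense"))
        frame = read_metadata(inputs["samples"], inputs["soils"])
        tax = read_taxonomy(inputs["taxonomy"]) if "taxonomy" in inputs else None

    hell = hellinger_transform(table)
    if "transform" in stages:
        t0 = time.time()
        emit("hellinger.tsv", lambda p: hell.data.to_csv(p, sep="\t", index_label="otu_id"))
        manifest["stages"]["transform"] = {"n_otus": hell.shape[0]}

    treatment = [s for s in frame.noncontrol_ids() if s in table.sample_ids]
    soil_groups = {s: frame.soil_of(s) for s in treatment}

    if "networks" in stages:
        t0 = time.time()
        sim_mat = pearson_similarity_matrix(hell.select_samples(treatment), axis="samples",
                                            transform=None)
        ps = proportional_similarity_matrix(table.select_samples(treatment))
        emit("sample_pearson.tsv", lambda p: sim_mat.to_csv(p, sep="\t"))
        emit("sample_proportional_similarity.tsv", lambda p: ps.to_csv(p, sep="\t"))
        emit("sample_mst_pearson.tsv",
             lambda p: export_network(maximum_spanning_tree(sim_mat), p, "edge-tsv"))
        emit("sample_mst_ps.tsv",
             lambda p: export_network(maximum_spanning_tree(ps), p, "edge-tsv"))
        emit("bipartite_presence.tsv",
             lambda p: export_network(bipartite_presence_network(table), p, "edge-tsv"))
        manifest["stages"]["networks"] = {"n_samples": len(treatment)}

    partition = None
    if "communities" in stages:
        t0 = time.time()
        corr_net = correlation_network(table, threshold=thresholds["correlation_threshold"],
                                       min_nonzero=thresholds["min_nonzero"])
        partition = mcl_cluster(corr_net, inflation=thresholds["inflation"])
        topo = topology_measures(corr_net)
        emit("correlation_network.tsv", lambda p: export_network(corr_net, p, "edge-tsv"))
        emit("correlation_network.graphml", lambda p: export_network(corr_net, p, "graphml"))
        emit("topology.tsv", lambda p: topo.to_csv(p, sep="\t"))
        emit("communities.tsv", lambda p: pd.DataFrame(
            sorted(partition.labels.items()), columns=["otu_id", "community"]
        ).to_csv(p, sep="\t", index=False))
        if tax is not None:
            comp = community_composition(partition, tax)
            emit("community_composition.tsv", lambda p: comp.to_csv(p, sep="\t", index=False))
        manifest["stages"]["communities"] = {
            "n_edges": corr_net.number_of_edges(),
            "n_communities": partition.n_communities,
        }

    if "enrich" in stages:
        t0 = time.time()
        enet, eres = build_enrichment_network(table, frame, mode="per-sample",
                                              level=thresholds["enrichment_fdr"])
        emit("enrichment_network.tsv", lambda p: export_network(enet, p, "edge-tsv"))
        emit("enrichment_results.tsv", lambda p: pd.DataFrame(
            [(r.otu_id, r.unit_id, r.a, r.b, r.c, r.d, r.raw_p, r.adjusted_p, r.enriched)
             for r in eres],
            columns=["otu_id", "unit_id", "a", "b", "c", "d", "raw_p", "adjusted_p", "enriched"],
        ).to_csv(p, sep="\t", index=False))
        quot = genotype_quotient_selection(enet, frame)
        emit("genotype_quotient.tsv", lambda p: quot.to_csv(p, sep="\t", index=False))
        manifest["stages"]["enrich"] = {"n_edges": enet.number_of_edges()}

    if "envlinks" in stages:
        t0 = time.time()
        corr, mst = soil_property_network(frame)
        emit("soil_property_corr.tsv", lambda p: corr.to_csv(p, sep="\t"))
        emit("soil_property_mst.tsv", lambda p: export_network(mst, p, "edge-tsv"))
        if partition is None:
            cn = correlation_network(table, threshold=thresholds["correlation_threshold"],
                                     min_nonzero=thresholds["min_nonzero"])
            partition = mcl_cluster(cn, inflation=thresholds["inflation"])
        _, edge_table = property_otu_community_map(
            table, frame, partition, threshold=thresholds["correlation_threshold"])
        emit("property_otu_map.tsv", lambda p: edge_table.to_csv(p, sep="\t", index=False))
        manifest["stages"]["envlinks"] = {"n_links": len(edge_table)}

    if "differential" in stages:
        t0 = time.time()
        diff_cfg = cfg.get("differential", {})
        soils = sorted({frame.soil_of(s) for s in treatment})
        class_a = diff_cfg.get("class_a") or [s for s in treatment
                                              if frame.soil_of(s) in soils[: len(soils) // 2]]
        class_b = diff_cfg.get("class_b") or [s for s in treatment
                                              if frame.soil_of(s) in soils[len(soils) // 2:]]
        diff = differential_pipeline(table, class_a, class_b,
                                     alpha=thresholds["fcros_p"],
                                     f_threshold=thresholds["fcros_f"])
        emit("differential.tsv", lambda p: diff.to_csv(p, sep="\t", index=False))
        manifest["stages"]["differential"] = {
            "n_flagged": int((diff["flagged"] != "none").sum()),
        }

    if "indicators" in stages:
        t0 = time.time()
        ind = indicator_analysis(
            filter_min_occurrence(table.select_samples(treatment), thresholds["min_nonzero"]),
            soil_groups, n_permutations=int(cfg.get("indicator_permutations", 199)),
            alpha=thresholds["indicator_alpha"], seed=_stage_seed(seed, "indicators"))
        emit("indicators.tsv", lambda p: pd.DataFrame(
            [(r.otu_id, "+".join(r.best_combination), r.stat, r.A, r.B, r.p_value, r.adjusted_p)
             for r in ind],
            columns=["otu_id", "group", "stat", "A", "B", "p", "adjusted_p"],
        ).to_csv(p, sep="\t", index=False))
        manifest["stages"]["indicators"] = {"n_otus": len(ind)}

    if "stats" in stages:
        t0 = time.time()
        bc = bray_curtis_matrix(hell.select_samples(treatment))
        res = permanova(bc, soil_groups,
                        n_permutations=int(cfg.get("permanova_permutations", 999)),
                        seed=_stage_seed(seed, "stats"))
        f_disp, p_disp = permdisp(bc, soil_groups,
                                  n_permutations=int(cfg.get("permanova_permutations", 999)),
                                  seed=_stage_seed(seed, "stats-disp"))
        emit("bray_curtis.tsv", lambda p: bc.to_csv(p, sep="\t"))
        emit("permanova.tsv", lambda p: pd.DataFrame(
            [("soil", res.pseudo_F, res.R_squared, res.p_value, res.n_permutations,
              f_disp, p_disp)],
            columns=["factor", "pseudo_F", "R2", "p", "n_perm", "permdisp_F", "permdisp_p"],
        ).to_csv(p, sep="\t", index=False))
        manifest["stages"]["stats"] = {"R2": res.R_squared, "p": res.p_value}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.removeHandler(handler)
    return out
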