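from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from rhizonet import (
    OtuTable,
    SampleFrame,
    sample_contingency,
    fisher_exact_test,
    bh_fdr,
    build_enrichment_network,
    genotype_quotient_selection,
)


def enumerate_fisher(a, b, c, d, alternative):
    """Exact-rational hypergeometric enumeration oracle."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    probs = {}
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[x] = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
    if alternative == "greater":
        return sum(p for x, p in probs.items() if x >= a)
    obs = probs[a]
    return sum(p for p in probs.values() if p <= obs)


class TestContingency:
    def test_direct_partition_and_conservation(self, tiny_table):
        cells = sample_contingency(tiny_table, "otu1", "s1")
        assert cells == (3, 0, 1, 2)
        assert sum(cells) == tiny_table.values.sum()

    def test_absent_otu_gives_p_one(self):
        t = OtuTable(data=pd.DataFrame([[0, 0], [1, 2]], index=["gone", "there"],
                                       columns=["s1", "s2"]))
        cells = sample_contingency(t, "gone", "s1")
        assert cells[0] == cells[1] == 0
        assert fisher_exact_test(cells) == 1.0

    def test_non_integer_table_rejected(self):
        t = OtuTable(data=pd.DataFrame([[0.5, 1.0]], index=["o"], columns=["s1", "s2"]))
        with pytest.raises(ValueError, match="integer"):
            sample_contingency(t, "o", "s1")


class TestFisher:
    @pytest.mark.parametrize("cells,alt,expected", [
        ((3, 0, 0, 3), "greater", 1 / 20),
        ((2, 0, 0, 2), "greater", 1 / 6),
        ((1, 1, 1, 1), "greater", 5 / 6),
        ((1, 1, 1, 1), "two-sided", 1.0),
    ])
    def test_known_tables(self, cells, alt, expected):
        assert fisher_exact_test(cells, alternative=alt) == pytest.approx(expected)

    @pytest.mark.parametrize("alt", ["greater", "two-sided"])
    def test_matches_enumeration_on_small_tables(self, alt):
        rng = np.random.default_rng(4)
        for _ in range(50):
            cells = tuple(int(x) for x in rng.integers(0, 8, 4))
            if 0 in (cells[0] + cells[1], cells[2] + cells[3],
                     cells[0] + cells[2], cells[1] + cells[3]):
                continue
            oracle = float(enumerate_fisher(*cells, alternative=alt))
            assert fisher_exact_test(cells, alternative=alt) == pytest.approx(oracle, abs=1e-12)


class TestBH:
    def test_step_up_oracle(self):
        adj, flags = bh_fdr([0.01, 0.02, 0.03, 0.5], level=0.05)
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.5])
        assert list(flags) == [True, True, True, False]

    def test_all_ones_no_discoveries_and_single_p(self):
        _, flags = bh_fdr([1.0, 1.0, 1.0], level=0.05)
        assert not flags.any()
        adj, flags = bh_fdr([0.005], level=0.01)
        assert adj[0] == 0.005 and flags[0]

    def test_adjusted_at_least_raw_and_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        p = rng.random(40)
        adj, flags = bh_fdr(p, level=0.1)
        assert np.all(adj >= p - 1e-15)
        _, sm_adj, _, _ = multipletests(p, alpha=0.1, method="fdr_bh")
        assert np.allclose(adj, sm_adj)

    def test_discoveries_monotone_in_level(self):
        rng = np.random.default_rng(1)
        p = rng.random(60) ** 2
        counts = [bh_fdr(p, level)[1].sum() for level in (0.2, 0.1, 0.05, 0.01)]
        assert counts == sorted(counts, reverse=True)


def toy_frame(sample_ids, genotypes, soils=None):
    soils = soils or ["NC1"] * len(sample_ids)
    samples = pd.DataFrame(
        {"soil_id": soils, "genotype_id": genotypes,
         "is_control": [False] * len(sample_ids),
         "experiment_id": ["e1"] * len(sample_ids)},
        index=pd.Index(sample_ids, name="sample_id"))
    soil_df = pd.DataFrame({"Ca": [1.0] * len(set(soils))},
                           index=pd.Index(sorted(set(soils)), name="soil_id"))
    return SampleFrame(samples=samples, soils=soil_df)


class TestEnrichmentNetwork:
    def test_concentrated_otu_found_by_manual_fisher_bh(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(5, 10, size=(10, 6))
        counts[0, :] = 0
        counts[0, 0] = 400  # OTU 0 massively concentrated in sample u0
        t = OtuTable(data=pd.DataFrame(
            counts, index=[f"o{i}" for i in range(10)],
            columns=[f"u{j}" for j in range(6)]))
        frame = toy_frame([f"u{j}" for j in range(6)], ["g1"] * 6)
        net, results = build_enrichment_network(t, frame, level=0.01)
        assert net.has_edge("o0", "u0")
        # manual oracle: recompute each raw p and BH over the same family
        raws = []
        for r in results:
            raws.append(float(enumerate_fisher(r.a, r.b, r.c, r.d, "greater")))
            assert r.raw_p == pytest.approx(raws[-1], abs=1e-12)
        m = len(raws)
        order = np.argsort(raws, kind="stable")
        adj = np.minimum.accumulate(
            (np.array(raws)[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        manual = np.empty(m)
        manual[order] = np.minimum(adj, 1)
        for r, a in zip(results, manual):
            assert r.adjusted_p == pytest.approx(a, abs=1e-12)
            assert r.enriched == (a <= 0.01)

    def test_uniform_table_yields_no_edges(self):
        t = OtuTable(data=pd.DataFrame(np.full((4, 4), 5),
                                       index=list("abcd"), columns=["u1", "u2", "u3", "u4"]))
        frame = toy_frame(["u1", "u2", "u3", "u4"], ["g1"] * 4)
        net, _ = build_enrichment_network(t, frame)
        assert net.number_of_edges() == 0

    def test_binned_mode_fdr_independent_per_soil(self):
        # identical sub-matrices in two soils -> identical per-soil edge sets
        block = np.array([[40, 0], [0, 40], [5, 5]])
        counts = np.hstack([block, block])
        t = OtuTable(data=pd.DataFrame(
            counts, index=["x", "y", "z"], columns=["a1", "a2", "b1", "b2"]))
        frame = toy_frame(["a1", "a2", "b1", "b2"],
                          ["g1", "g2", "g1", "g2"],
                          soils=["NC1", "NC1", "NC2", "NC2"])
        net, results = build_enrichment_network(t, frame, mode="binned-by-genotype")
        per_soil = {
            soil: {(r.otu_id, r.unit_id.split(":")[1]) for r in results
                   if r.enriched and r.unit_id.startswith(soil)}
            for soil in ("NC1", "NC2")
        }
        assert per_soil["NC1"] == per_soil["NC2"]
        assert net.number_of_edges() == len(per_soil["NC1"]) + len(per_soil["NC2"])

    def test_single_genotype_soil_skipped_with_warning(self):
        t = OtuTable(data=pd.DataFrame([[3, 4]], index=["o"], columns=["u1", "u2"]))
        frame = toy_frame(["u1", "u2"], ["g1", "g1"])
        with pytest.warns(UserWarning, match="single genotype"):
            net, results = build_enrichment_network(t, frame, mode="binned-by-genotype")
        assert not results


class TestQuotientSelection:
    def build_net(self, edges, genotype_of):
        import networkx as nx
        g = nx.Graph(bipartite=True)
        for otu, samp in edges:
            g.add_node(otu, role="otu")
            g.add_node(samp, role="sample")
            g.add_edge(otu, samp)
        return g

    def test_hand_enumerated_rule(self):
        # 12 OTUs, 4 genotypes x 3 samples, exhaustive hand enumeration
        samples = [f"{g}_{r}" for g in "ABCD" for r in range(3)]
        genotypes = {s: s.split("_")[0] for s in samples}
        frame = toy_frame(samples, [genotypes[s] for s in samples])
        edges = []
        expectations = {}
        # degree 4 over 2 genotypes -> q=2, selected
        edges += [("o1", "A_0"), ("o1", "A_1"), ("o1", "B_0"), ("o1", "B_1")]
        expectations["o1"] = (4, 2, 2.0, True)
        # degree 3 over 3 genotypes -> q=1, rejected twice over
        edges += [("o2", "A_0"), ("o2", "B_0"), ("o2", "C_0")]
        expectations["o2"] = (3, 3, 1.0, False)
        # degree 2 over 1 genotype -> q=2, selected
        edges += [("o3", "D_0"), ("o3", "D_1")]
        expectations["o3"] = (2, 1, 2.0, True)
        # degree 1 over 1 genotype -> q=1, fails quotient
        edges += [("o4", "C_2")]
        expectations["o4"] = (1, 1, 1.0, False)
        # degree 6 over 3 genotypes -> q=2 but spans >2 genotypes
        edges += [("o5", s) for s in ["A_0", "A_1", "B_0", "B_1", "C_0", "C_1"]]
        expectations["o5"] = (6, 3, 2.0, False)
        # degree 4 over 1 genotype -> q=4, selected
        edges += [("o6", s) for s in ["A_0", "A_1", "A_2", "B_0"]]
        expectations["o6"] = (4, 2, 2.0, True)
        for i in range(7, 13):  # degree-0 OTUs are excluded entirely
            pass
        net = self.build_net(edges, genotypes)
        for i in range(7, 13):
            net.add_node(f"o{i}", role="otu")
        out = genotype_quotient_selection(net, frame).set_index("otu_id")
        assert len(out) == 6
        for otu, (deg, ngen, q, sel) in expectations.items():
            row = out.loc[otu]
            assert (row["degree"], row["n_genotypes"]) == (deg, ngen)
            assert row["quotient"] == pytest.approx(q)
            assert bool(row["selected"]) is sel

    def test_quotient_invariant_to_edge_free_sample(self):
        samples = ["A_0", "A_1", "B_0"]
        frame = toy_frame(samples, ["A", "A", "B"])
        net = self.build_net([("o1", "A_0"), ("o1", "A_1")], None)
        net.add_node("B_0", role="sample")  # carries no enrichment edges
        out = genotype_quotient_selection(net, frame)
        assert out.loc[0, "quotient"] == pytest.approx(2.0)
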