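"""OTU-sample and genotype-binned enrichment hypergraphs.

For each OTU x analysis-unit pair (a unit is a single sample, or the
summed counts of one genotype within one soil), a 2x2 contingency
table partitions the total read mass:

    a = reads of the OTU in the unit
    b = reads of the OTU in all other units
    c = reads of all other OTUs in the unit
    d = reads of all other OTUs elsewhere

A one-sided Fisher exact test (alternative "greater": the OTU claims
more of the unit's reads than expected at fixed margins) gives a raw
p per pair; Benjamini-Hochberg FDR over each analysis family flags
enriched pairs, which become edges of the enrichment hypergraph.
Exact tests require raw integer counts — never run this stage on
Hellinger-scale data.

Genotype specificity is summarized by the quotient coefficient: the
OTU's degree in the per-sample enrichment network divided by the
number of distinct genotypes its enriched samples span.  An OTU
enriched in many samples of few genotypes scores high.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import networkx as nx
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher

from rhizonet.data_model import OtuTable, SampleFrame


@dataclass(frozen=True)
class EnrichmentResult:
    otu_id: str
    unit_id: str
    a: int
    b: int
    c: int
    d: int
    raw_p: float
    adjusted_p: float
    enriched: bool


def _require_integer(table: OtuTable) -> np.ndarray:
    vals = table.values
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("enrichment needs raw integer counts; use the untransformed table")
    return np.round(vals).astype(np.int64)


def sample_contingency(table: OtuTable, otu: str, unit: str) -> tuple[int, int, int, int]:
    """2x2 reads-in-unit vs reads-elsewhere partition for one OTU."""
    vals = _require_integer(table)
    i = table.otu_ids.index(otu)
    j = table.sample_ids.index(unit)
    a = int(vals[i, j])
    b = int(vals[i, :].sum() - a)
    c = int(vals[:, j].sum() - a)
    d = int(vals.sum() - a - b - c)
    return a, b, c, d


def fisher_exact_test(cells: tuple[int, int, int, int], alternative: str = "greater") -> float:
    """Fisher exact p for a 2x2 table (a, b, c, d).

    ``greater`` sums the upper hypergeometric tail P(X >= a) at fixed
    margins; ``two-sided`` sums all tables with point probability <=
    the observed one.  Any zero margin means no association is
    testable and returns p = 1.
    """
    a, b, c, d = (int(x) for x in cells)
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"alternative must be 'greater' or 'two-sided', got {alternative!r}")
    return float(_scipy_fisher([[a, b], [c, d]], alternative=alternative).pvalue)


def bh_fdr(p_values, level: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and discovery flags.

    adjusted_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1;
    a test is a discovery when its adjusted p <= level.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out, out <= level


def _enrich_family(vals: np.ndarray, otu_ids, unit_ids, level: float,
                   alternative: str) -> list[EnrichmentResult]:
    """Fisher + BH over every OTU x unit pair of one analysis matrix."""
    total = int(vals.sum())
    row = vals.sum(axis=1)
    col = vals.sum(axis=0)
    raw = []
    cells = []
    for i in range(vals.shape[0]):
        for j in range(vals.shape[1]):
            a = int(vals[i, j])
            b = int(row[i] - a)
            c = int(col[j] - a)
            d = total - a - b - c
            cells.append((a, b, c, d))
            raw.append(fisher_exact_test((a, b, c, d), alternative=alternative))
    adj, flags = bh_fdr(raw, level)
    out = []
    k = 0
    for i, otu in enumerate(otu_ids):
        for j, unit in enumerate(unit_ids):
            a, b, c, d = cells[k]
            out.append(EnrichmentResult(otu, unit, a, b, c, d,
                                        float(raw[k]), float(adj[k]), bool(flags[k])))
            k += 1
    return out


def build_enrichment_network(table: OtuTable, frame: SampleFrame,
                             mode: str = "per-sample", level: float = 0.01,
                             alternative: str = "greater") -> tuple[nx.Graph, list[EnrichmentResult]]:
    """Enrichment hypergraph: edge (otu, unit) wherever adjusted p <= level.

    ``per-sample``: non-control samples form one FDR family; control
    samples, when present, are analyzed as a second separate family.
    ``binned-by-genotype``: within each soil, sample columns are
    summed per genotype and enrichment + FDR run independently per
    soil; soils with a single genotype bin are skipped with a warning.
    """
    if table.scale != "counts":
        raise ValueError("enrichment runs on the counts-scale table")
    results: list[EnrichmentResult] = []
    g = nx.Graph(bipartite=True)
    for o in table.otu_ids:
        g.add_node(o, role="otu")

    if mode == "per-sample":
        families = []
        noncontrol = [s for s in frame.noncontrol_ids() if s in table.sample_ids]
        controls = [s for s in frame.control_ids() if s in table.sample_ids]
        if noncontrol:
            families.append(noncontrol)
        if controls:
            families.append(controls)
        for fam in families:
            sub = table.select_samples(fam)
            vals = _require_integer(sub)
            results.extend(_enrich_family(vals, sub.otu_ids, fam, level, alternative))
        unit_role = "sample"
    elif mode == "binned-by-genotype":
        vals = _require_integer(table)
        df = pd.DataFrame(vals, index=table.otu_ids, columns=table.sample_ids)
        unit_role = "genotype-bin"
        noncontrol = [s for s in frame.noncontrol_ids() if s in table.sample_ids]
        soils = sorted({frame.soil_of(s) for s in noncontrol})
        for soil in soils:
            soil_samples = [s for s in noncontrol if frame.soil_of(s) == soil]
            genos = sorted({frame.genotype_of(s) for s in soil_samples})
            if len(genos) < 2:
                warnings.warn(f"soil {soil!r} has a single genotype bin; skipped", stacklevel=2)
                continue
            binned = np.column_stack([
                df[[s for s in soil_samples if frame.genotype_of(s) == gname]].sum(axis=1).to_numpy()
                for gname in genos
            ])
            units = [f"{soil}:{gname}" for gname in genos]
            results.extend(_enrich_family(binned, table.otu_ids, units, level, alternative))
    else:
        raise ValueError(f"mode must be 'per-sample' or 'binned-by-genotype', got {mode!r}")

    for r in results:
        if r.unit_id not in g:
            g.add_node(r.unit_id, role=unit_role)
        if r.enriched:
            g.add_edge(r.otu_id, r.unit_id, weight=1.0 - r.adjusted_p, sign="+")
    return g, results


def genotype_quotient_selection(enrichment_net: nx.Graph, frame: SampleFrame,
                                max_genotypes: int = 2,
                                min_quotient: float = 2.0) -> pd.DataFrame:
    """Genotype-specific OTUs by the quotient rule.

    quotient(otu) = enrichment degree / number of distinct genotypes
    spanned by its enriched samples; selected iff the OTU spans at
    most ``max_genotypes`` genotypes and quotient >= ``min_quotient``.
    Degree-0 OTUs are excluded (quotient undefined).
    """
    rows = []
    for node, data in enrichment_net.nodes(data=True):
        if data.get("role") != "otu":
            continue
        neighbors = list(enrichment_net.neighbors(node))
        if not neighbors:
            continue
        genos = {frame.genotype_of(s) for s in neighbors}
        quotient = len(neighbors) / len(genos)
        rows.append((node, len(neighbors), len(genos), quotient,
                     len(genos) <= max_genotypes and quotient >= min_quotient))
    return pd.DataFrame(
        rows, columns=["otu_id", "degree", "n_genotypes", "quotient", "selected"]
    ).sort_values("otu_id", ignore_index=True)
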