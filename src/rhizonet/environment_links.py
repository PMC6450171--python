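"""Soil-property correlation networks and property -> OTU community maps.

Soil physicochemical variables (Ca, Mg, pH, texture, distance to
river, ...) are correlated pairwise across soils and summarized as a
maximum spanning tree, mirroring the sample-similarity construction.
Property-OTU correlations are computed at sample resolution — each
soil's property value is broadcast to its samples, since OTU
abundances vary per sample — thresholded at |r| >= 0.6, and mapped
onto the co-occurrence communities of the correlated OTUs.  Pass
``resolution="soil-mean"`` to correlate against per-soil mean
abundances instead.
"""

from __future__ import annotations

import warnings

import numpy as np
import networkx as nx
import pandas as pd

from rhizonet.data_model import OtuTable, SampleFrame, hellinger_transform
from rhizonet.cooccurrence import CommunityPartition
from rhizonet.similarity_networks import maximum_spanning_tree


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def soil_property_network(frame: SampleFrame) -> tuple[pd.DataFrame, nx.Graph]:
    """Property-property Pearson matrix across soils, plus its MST.

    Constant properties get correlation 0 with a warning.  Needs at
    least 3 soils with complete property vectors.
    """
    soils = frame.soils
    if soils.shape[0] < 3:
        raise ValueError("need at least 3 soils to correlate properties")
    props = list(soils.columns)
    vals = soils.to_numpy(dtype=float)
    sd = vals.std(axis=0)
    if (sd == 0).any():
        names = [p for p, s in zip(props, sd) if s == 0]
        warnings.warn(f"constant soil properties {names}; correlations set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(vals.T)
    r = np.where(np.isnan(r), 0.0, r)
    np.fill_diagonal(r, 1.0)
    corr = pd.DataFrame(np.clip(r, -1, 1), index=props, columns=props)
    mst = maximum_spanning_tree(corr, role="property")
    return corr, mst


def property_otu_community_map(table: OtuTable, frame: SampleFrame,
                               partition: CommunityPartition,
                               threshold: float = 0.6,
                               transform: str | None = "hellinger",
                               resolution: str = "sample") -> tuple[nx.Graph, pd.DataFrame]:
    """Property-OTU correlation edges annotated with community labels.

    Edge (property, otu) iff |Pearson| across samples >= threshold.
    OTUs missing from the partition carry the background label 0.
    Returns the annotated bipartite network and a tidy edge table
    (property, otu_id, r, community).
    """
    if transform == "hellinger" and table.scale in ("counts", "relative"):
        table = hellinger_transform(table)
    sample_ids = [s for s in frame.noncontrol_ids() if s in table.sample_ids]
    if len(sample_ids) < 3:
        raise ValueError("need at least 3 non-control samples")
    sub = table.select_samples(sample_ids)
    abund = sub.values

    g = nx.Graph(bipartite=True)
    rows = []
    for prop in frame.property_names:
        pvec = frame.property_per_sample(prop, sample_ids).to_numpy(dtype=float)
        g.add_node(prop, role="property")
        if resolution == "soil-mean":
            soils = [frame.soil_of(s) for s in sample_ids]
            soil_order = sorted(set(soils))
            pv = np.array([frame.soils.at[s, prop] for s in soil_order], dtype=float)
            av = np.column_stack([
                abund[:, [i for i, s in enumerate(soils) if s == so]].mean(axis=1)
                for so in soil_order
            ])
        elif resolution == "sample":
            pv, av = pvec, abund
        else:
            raise ValueError(f"resolution must be 'sample' or 'soil-mean', got {resolution!r}")
        for i, otu in enumerate(sub.otu_ids):
            r = _pearson(av[i], pv)
            if abs(r) >= threshold:
                comm = partition.labels.get(otu, 0)
                if otu not in g:
                    g.add_node(otu, role="otu", community=comm)
                g.add_edge(prop, otu, weight=abs(r), sign="+" if r >= 0 else "-",
                           community=comm)
                rows.append((prop, otu, r, comm))
    edge_table = pd.DataFrame(rows, columns=["property", "otu_id", "r", "community"])
    return g, edge_table
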