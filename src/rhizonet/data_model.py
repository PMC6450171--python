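"""Core data containers, file I/O and abundance transforms.

The central container is :class:`OtuTable`: a dense OTU-by-sample
matrix of non-negative values with an amplicon marker tag (ITS / 16S /
28S / 18S) and a ``scale`` recording which transform, if any, has been
applied.  Sample and soil metadata live in :class:`SampleFrame`;
fungal/bacterial identity of each OTU comes from
:class:`TaxonomyTable`, never from the marker tag, because fungal
(ITS) and bacterial (16S) OTUs are pooled into joint networks.

Tables are dense in memory: community-ecology datasets at this scale
(a few hundred OTUs by a few dozen samples) never need sparse kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

VALID_MARKERS = ("ITS", "16S", "28S", "18S")
VALID_SCALES = ("counts", "relative", "hellinger", "normalized")

#: soil_id reserved for uninoculated control samples (sterile substrate).
CONTROL_SOIL = "CONTROL"


class TableError(ValueError):
    """Malformed table: duplicate labels, negative cells, bad dialect."""


@dataclass(frozen=True)
class OtuTable:
    """Dense OTU abundance matrix (rows = OTUs, columns = samples)."""

    data: pd.DataFrame
    marker: str = "ITS"
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.marker not in VALID_MARKERS:
            raise TableError(f"unknown marker {self.marker!r}; expected one of {VALID_MARKERS}")
        if self.scale not in VALID_SCALES:
            raise TableError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise TableError(f"duplicate OTU label {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise TableError(f"duplicate sample label {dup!r}")
        vals = self.data.to_numpy(dtype=float)
        if vals.size and np.nanmin(vals) < 0:
            i, j = np.argwhere(vals < 0)[0]
            raise TableError(
                f"negative value at OTU {self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: pd.DataFrame, scale: str | None = None) -> "OtuTable":
        return OtuTable(data=data, marker=self.marker, scale=scale or self.scale)

    def select_samples(self, sample_ids) -> "OtuTable":
        return self.with_data(self.data.loc[:, list(sample_ids)])

    def select_otus(self, otu_ids) -> "OtuTable":
        return self.with_data(self.data.loc[list(otu_ids), :])


@dataclass(frozen=True)
class SampleFrame:
    """Per-sample metadata joined with per-soil physicochemical properties.

    ``samples`` is indexed by sample_id with columns soil_id,
    genotype_id, is_control (bool) and experiment_id.  ``soils`` is
    indexed by soil_id with one numeric column per property (Ca, Mg,
    pH, ...).  Control samples carry the reserved soil_id
    ``CONTROL`` and need no property row.  ``units`` records the unit
    of each property (ppm, %, cm, pH units) as plain metadata.
    """

    samples: pd.DataFrame
    soils: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"soil_id", "genotype_id", "is_control", "experiment_id"}
        missing = required - set(self.samples.columns)
        if missing:
            raise TableError(f"sample metadata missing columns: {sorted(missing)}")
        referenced = set(self.samples.loc[~self.samples["is_control"], "soil_id"])
        unknown = referenced - set(self.soils.index) - {CONTROL_SOIL}
        if unknown:
            raise TableError(f"samples reference soils absent from soil table: {sorted(unknown)}")
        if self.soils.size and self.soils.isna().any().any():
            raise TableError("soil property table contains missing values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def property_names(self) -> list[str]:
        return list(self.soils.columns)

    def soil_of(self, sample_id: str) -> str:
        return self.samples.at[sample_id, "soil_id"]

    def genotype_of(self, sample_id: str) -> str:
        return self.samples.at[sample_id, "genotype_id"]

    def noncontrol_ids(self) -> list[str]:
        return list(self.samples.index[~self.samples["is_control"]])

    def control_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["is_control"]])

    def property_per_sample(self, name: str, sample_ids=None) -> pd.Series:
        """Broadcast a soil property to samples via soil membership.

        Control samples have no soil properties and are excluded.
        """
        ids = sample_ids if sample_ids is not None else self.noncontrol_ids()
        soils = self.samples.loc[list(ids), "soil_id"]
        return pd.Series(self.soils.loc[soils, name].to_numpy(), index=list(ids), name=name)


RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class TaxonomyTable:
    """otu_id -> seven taxonomic ranks plus a fungal/bacterial domain tag."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "domain" not in self.data.columns:
            raise TableError("taxonomy table needs a 'domain' column (fungal/bacterial)")
        bad = set(self.data["domain"]) - {"fungal", "bacterial"}
        if bad:
            raise TableError(f"unknown domain tags: {sorted(bad)}")
        if self.data.index.duplicated().any():
            raise TableError("duplicate otu_id in taxonomy table")

    def domain_of(self, otu_id: str) -> str:
        try:
            return self.data.at[otu_id, "domain"]
        except KeyError:
            raise KeyError(f"OTU {otu_id!r} has no taxonomy entry") from None

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)


# ---------------------------------------------------------------------------
# I/O


def read_otu_table(path, dialect: str = "tsv-dense", marker: str = "ITS") -> OtuTable:
    """Read an OTU count table.

    ``tsv-dense``: row 1 = sample ids, column 1 = OTU ids.
    ``triplet-sparse``: three-column TSV (otu_id, sample_id, count)
    with a header line; absent cells are zero.
    """
    if dialect == "tsv-dense":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        seen = set()
        for lbl in header:  # pandas silently mangles duplicate columns
            if lbl in seen:
                raise TableError(f"{path}: duplicate sample label {lbl!r}")
            seen.add(lbl)
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        if df.index.duplicated().any():
            raise TableError(f"{path}: duplicate OTU label {df.index[df.index.duplicated()][0]!r}")
        try:
            num = df.astype(float)
        except ValueError:
            for j, col in enumerate(df.columns):
                for i, v in enumerate(df[col]):
                    try:
                        float(v)
                    except (TypeError, ValueError):
                        raise TableError(
                            f"{path}: non-numeric value {v!r} at OTU {df.index[i]!r}, sample {col!r}"
                        ) from None
            raise
        num.index = num.index.astype(str)
        num.columns = num.columns.astype(str)
        return OtuTable(data=num, marker=marker, scale="counts")
    if dialect == "triplet-sparse":
        trip = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        if trip.shape[1] != 3:
            raise TableError(f"{path}: triplet dialect needs 3 columns, found {trip.shape[1]}")
        trip.columns = ["otu_id", "sample_id", "count"]
        dup = trip.duplicated(subset=["otu_id", "sample_id"])
        if dup.any():
            r = trip[dup].iloc[0]
            raise TableError(f"{path}: duplicate cell ({r['otu_id']!r}, {r['sample_id']!r})")
        dense = trip.pivot(index="otu_id", columns="sample_id", values="count").fillna(0.0)
        dense = dense.astype(float)
        # preserve first-appearance order from the triplet stream
        otu_order = list(dict.fromkeys(trip["otu_id"]))
        samp_order = list(dict.fromkeys(trip["sample_id"]))
        dense = dense.loc[otu_order, samp_order]
        dense.index.name = None
        dense.columns.name = None
        return OtuTable(data=dense, marker=marker, scale="counts")
    raise TableError(f"unknown dialect {dialect!r}; expected 'tsv-dense' or 'triplet-sparse'")


def write_otu_table(table: OtuTable, path, dialect: str = "tsv-dense") -> None:
    """Write an OTU table in a dialect `read_otu_table` round-trips."""
    if dialect == "tsv-dense":
        df = table.data.copy()
        if table.scale == "counts" and np.allclose(df.to_numpy() % 1, 0):
            df = df.astype(int)
        df.to_csv(path, sep="\t", index_label="otu_id")
        return
    if dialect == "triplet-sparse":
        rows = []
        vals = table.values
        for i, otu in enumerate(table.otu_ids):
            for j, samp in enumerate(table.sample_ids):
                v = vals[i, j]
                if v != 0:
                    rows.append((otu, samp, int(v) if v == int(v) else v))
        pd.DataFrame(rows, columns=["otu_id", "sample_id", "count"]).to_csv(
            path, sep="\t", index=False
        )
        return
    raise TableError(f"unknown dialect {dialect!r}")


def read_metadata(sample_path, soil_path) -> SampleFrame:
    """Read sample and soil TSVs and join them into a SampleFrame."""
    samples = pd.read_csv(sample_path, sep="\t", index_col="sample_id", dtype=str)
    required = {"soil_id", "genotype_id", "is_control", "experiment_id"}
    missing = required - set(samples.columns)
    if missing:
        raise TableError(f"{sample_path}: missing columns {sorted(missing)}")
    samples["is_control"] = samples["is_control"].str.lower().isin(("true", "1", "yes"))
    soils = pd.read_csv(soil_path, sep="\t", index_col="soil_id")
    return SampleFrame(samples=samples, soils=soils)


def read_taxonomy(path) -> TaxonomyTable:
    """Read a taxonomy TSV: otu_id, seven rank columns, domain."""
    df = pd.read_csv(path, sep="\t", index_col="otu_id", dtype=str, keep_default_na=False)
    return TaxonomyTable(data=df)


# ---------------------------------------------------------------------------
# Transforms


def hellinger_transform(table: OtuTable) -> OtuTable:
    """Square root of per-sample relative abundances.

    Each cell becomes sqrt(x / column_sum), so every nonzero sample
    column has unit Euclidean norm.  All-zero columns (failed samples)
    stay all-zero rather than raising, keeping them representable.
    """
    if table.scale not in ("counts", "relative"):
        raise TableError(f"hellinger_transform expects counts or relative scale, got {table.scale!r}")
    vals = table.values
    sums = vals.sum(axis=0)
    safe = np.where(sums > 0, sums, 1.0)
    out = np.sqrt(vals / safe)
    return table.with_data(
        pd.DataFrame(out, index=table.otu_ids, columns=table.sample_ids), scale="hellinger"
    )


def relative_and_rank_abundance(table: OtuTable, group_by=None) -> pd.DataFrame:
    """Mean relative abundance per OTU, ranked within sample groups.

    ``group_by`` maps sample_id -> group label (None = one pooled
    group "all").  Output columns: group, rank, otu_id,
    mean_relative_abundance; within a group, OTUs sort by descending
    abundance with ties broken lexicographically by otu_id.
    """
    if table.scale != "counts":
        raise TableError("rank abundance expects a counts-scale table")
    if group_by is None:
        group_by = {s: "all" for s in table.sample_ids}
    groups: dict[str, list[str]] = {}
    for s in table.sample_ids:
        groups.setdefault(group_by[s], []).append(s)
    vals = table.values
    sums = vals.sum(axis=0)
    rel = np.divide(vals, np.where(sums > 0, sums, 1.0))
    rel_df = pd.DataFrame(rel, index=table.otu_ids, columns=table.sample_ids)
    records = []
    for g in sorted(groups):
        cols = groups[g]
        if not cols:
            raise TableError(f"empty sample group {g!r}")
        mean = rel_df[cols].mean(axis=1)
        order = sorted(mean.index, key=lambda o: (-mean[o], o))
        for rank, otu in enumerate(order, start=1):
            records.append((g, rank, otu, mean[otu]))
    return pd.DataFrame(records, columns=["group", "rank", "otu_id", "mean_relative_abundance"])


def filter_min_occurrence(table: OtuTable, min_nonzero: int = 3) -> OtuTable:
    """Drop OTUs observed (value > 0) in fewer than ``min_nonzero`` samples.

    Rare-OTU filter applied before building co-occurrence networks;
    correlations on near-empty rows are dominated by sampling noise.
    """
    if min_nonzero < 1:
        raise TableError("min_nonzero must be >= 1")
    keep = (table.values > 0).sum(axis=1) >= min_nonzero
    return table.with_data(table.data.loc[keep])


def rarefaction_expected_richness(column_counts, depths) -> list[float]:
    """Analytic expected richness E[S(d)] at each subsampling depth.

    For counts n_i summing to N, E[S(d)] = sum_i 1 - C(N-n_i, d)/C(N, d)
    — the expected number of taxa seen in a uniform draw of d reads
    without replacement.  Monotone non-decreasing in d.
    """
    counts = np.asarray(column_counts, dtype=np.int64)
    if counts.size and np.any(counts < 0):
        raise TableError("counts must be non-negative integers")
    counts = counts[counts > 0]
    total = int(counts.sum())
    out = []
    for d in depths:
        d = int(d)
        if d > total:
            raise TableError(f"depth {d} exceeds column total {total}")
        # P(taxon i entirely missed) is a hypergeometric zero-class prob
        miss = hypergeom.pmf(0, total, counts, d)
        out.append(float(np.sum(1.0 - miss)))
    return out
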