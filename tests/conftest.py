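import numpy as np
import pandas as pd
import pytest

from rhizonet import OtuTable, SampleFrame, TaxonomyTable, SimConfig, generate_dataset


@pytest.fixture
def tiny_table():
    """2 OTUs x 2 samples with counts {{3,0},{1,2}}."""
    return OtuTable(
        data=pd.DataFrame([[3, 0], [1, 2]], index=["otu1", "otu2"], columns=["s1", "s2"]),
    )


@pytest.fixture
def random_table():
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.integers(0, 50, size=(12, 8)),
        index=[f"o{i}" for i in range(12)],
        columns=[f"s{j}" for j in range(8)],
    )
    return OtuTable(data=data)


@pytest.fixture
def small_frame():
    samples = pd.DataFrame(
        {
            "soil_id": ["NC1", "NC1", "NC2", "NC2", "CONTROL"],
            "genotype_id": ["D110", "D117", "D110", "D117", "D110"],
            "is_control": [False, False, False, False, True],
            "experiment_id": ["exp1"] * 5,
        },
        index=pd.Index(["a1", "a2", "b1", "b2", "c1"], name="sample_id"),
    )
    soils = pd.DataFrame(
        {"Ca": [350.0, 120.0], "Mg": [80.0, 40.0], "pH": [6.1, 5.2]},
        index=pd.Index(["NC1", "NC2"], name="soil_id"),
    )
    return SampleFrame(samples=samples, soils=soils)


@pytest.fixture(scope="session")
def default_dataset():
    """One moderate synthetic experiment reused across tests."""
    cfg = SimConfig(seed=11, n_soils=4, replicates_per_soil=4, n_fungal_otus=60,
                    n_bacterial_otus=120, n_planted_communities=3,
                    n_differential_otus=10)
    return generate_dataset(cfg)


def make_taxonomy(otu_ids, domains):
    ranks = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
    df = pd.DataFrame({r: [""] * len(otu_ids) for r in ranks},
                      index=pd.Index(otu_ids, name="otu_id"))
    df["domain"] = list(domains)
    return TaxonomyTable(data=df)
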