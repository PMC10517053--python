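import numpy as np
import pandas as pd
import pytest

from planknet.preprocess import OtuTable
from planknet.synthetic_data import WorldConfig, generate_world


def make_meta(lat, lon, **overrides):
    n = len(lat)
    data = {
        "sample_id": [f"s{i}" for i in range(n)],
        "latitude": lat,
        "longitude": lon,
        "date": ["2015-06"] * n,
        "sampling_depth_m": [5.0] * n,
        "seafloor_depth_m": [3000.0] * n,
        "size_fraction": ["0.8-5um"] * n,
    }
    data.update(overrides)
    return pd.DataFrame(data)


def make_table(counts, sample_ids=None, otu_ids=None):
    counts = np.asarray(counts)
    sample_ids = sample_ids or [f"s{i}" for i in range(counts.shape[0])]
    otu_ids = otu_ids or [f"otu{j}" for j in range(counts.shape[1])]
    return OtuTable(sample_ids=sample_ids, otu_ids=otu_ids, counts=counts)


@pytest.fixture(scope="session")
def strong_world():
    """A world with strong planted structure, shared across tests."""
    config = WorldConfig(
        n_samples=120,
        n_modules=4,
        n_otus_per_module=8,
        n_noise_otus=10,
        read_depth=2000,
        gradient_strength=4.0,
        feature_noise_sd=0.02,
        spatial_cluster_km=250.0,
        seed=42,
    )
    return config, generate_world(config)
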