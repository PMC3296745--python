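import numpy as np
import pandas as pd
import pytest

from dosagescan import cna_builder, io_model, mrr_finder
from dosagescan.synthetic_data import SimConfig, generate_dataset


def make_probes(positions, chrom="chr1", offset=0):
    """Probe table at explicit positions (one chromosome)."""
    return pd.DataFrame(
        {
            "snp_id": [f"s{offset + i + 1}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": list(positions),
        }
    )


def make_dataset(positions, state_rows, chrom="chr1", log2=None):
    """SnpDataset from positions and a dict sample -> state list."""
    probes = make_probes(positions, chrom=chrom)
    states = pd.DataFrame({s: list(v) for s, v in state_rows.items()})
    lr = None
    if log2 is not None:
        lr = pd.DataFrame({s: list(v) for s, v in log2.items()}, dtype=float)
    ds = io_model.SnpDataset(probes=probes, states=states, log2=lr)
    ds.validate()
    return ds


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """Default-condition synthetic dataset shared across tests."""
    out = tmp_path_factory.mktemp("simdata")
    return generate_dataset(SimConfig(seed=11), out)


@pytest.fixture(scope="session")
def sim_cnas(sim_bundle):
    return cna_builder.build_all_cnas(sim_bundle["dataset"])


@pytest.fixture(scope="session")
def sim_mrrs(sim_bundle, sim_cnas):
    return mrr_finder.find_mrrs(sim_cnas, sim_bundle["dataset"])
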