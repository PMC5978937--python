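"""Shared fixtures: a small synthetic study generated once per session."""

import numpy as np
import pandas as pd
import pytest

import hmcpipe as h


@pytest.fixture(scope="session")
def small_cfg():
    return h.SimulationConfig(
        n_probes=2000,
        n_genes=120,
        n_planted_dhmrs=5,
        gcimp_gene_count=25,
        n_coupled_genes=16,
        n_de_extra=10,
        seed=1,
    )


@pytest.fixture(scope="session")
def dataset(small_cfg):
    return h.generate_dataset(small_cfg, with_hmedip=True)


@pytest.fixture(scope="session")
def hmc(dataset):
    return h.compute_5hmc(dataset["bs"], dataset["oxbs"])


@pytest.fixture(scope="session")
def mc(dataset):
    return h.compute_5mc(dataset["oxbs"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_beta_matrix(rng, n_probes=50, sample_ids=None, channel="BS"):
    sample_ids = sample_ids or [f"S{i}" for i in range(6)]
    v = rng.random((n_probes, len(sample_ids)))
    return h.BetaMatrix(
        pd.DataFrame(v, index=[f"cg{i:05d}" for i in range(n_probes)],
                     columns=sample_ids),
        channel,
    )
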