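import numpy as np
import pandas as pd
import pytest

import stpcover as sc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_bundle_frames(rng, n_genes=6, n_samples=8):
    """Small random mutation/CN frames sharing axes."""
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    mutation = pd.DataFrame(rng.integers(0, 2, (n_genes, n_samples)), index=genes, columns=samples)
    copy_number = pd.DataFrame(rng.integers(-2, 3, (n_genes, n_samples)), index=genes, columns=samples)
    return mutation, copy_number


@pytest.fixture(scope="session")
def toy_study():
    """A small planted toy study shared across tests (N=200, 4 planted, 8 decoys)."""
    model = sc.PlantedModel.toy_study(
        n_samples=200, n_planted=4, n_decoys=8, n_private_per_pair=6, n_crowd=150, seed=7
    )
    network = sc.generate_network(model.all_pairs, seed=7)
    bundle, truth = sc.generate_cohort(model, network)
    return model, network, bundle, truth
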