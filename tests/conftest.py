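import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from homeobias.simulate import SimulationConfig, sample_truth, simulate_gene_counts

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def counts_table(pairs, prefix="g"):
    """Build a one-sample count table from a list of (n_count, i_count)."""
    return pd.DataFrame(
        {
            "gene_id": [f"{prefix}{j}" for j in range(len(pairs))],
            "n_count": [p[0] for p in pairs],
            "i_count": [p[1] for p in pairs],
        }
    )


@pytest.fixture(scope="session")
def reference_sim():
    """A moderately sized reference simulation shared across tests.

    Equal numbers of genes per architecture at the default deep-coverage
    settings; returns (truths, config, long count table).
    """
    cfg = SimulationConfig(n_genes=600, seed=11)
    truths = sample_truth(cfg)
    counts = simulate_gene_counts(truths, cfg)
    return truths, cfg, counts


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
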