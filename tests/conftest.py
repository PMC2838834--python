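import numpy as np
import pandas as pd
import pytest

from neutroflux.de import contrast_table, group_medians
from neutroflux.normalization import normalize_pipeline
from neutroflux.synthetic import default_config, simulate_experiment


def make_spot_frame(rows):
    """Build a spot-table frame from (array, spot, probe, symbol, kind, s, r) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "array_id",
            "spot_id",
            "probe_id",
            "gene_symbol",
            "spot_kind",
            "sample_signal",
            "reference_signal",
        ],
    )


@pytest.fixture(scope="session")
def noisefree_experiment():
    config = default_config(seed=1, n_genes=400).noise_free()
    return simulate_experiment(config)


@pytest.fixture(scope="session")
def noisefree_pipeline(noisefree_experiment):
    exp = noisefree_experiment
    matrix = normalize_pipeline(exp.spots, exp.annotation)
    table = contrast_table(group_medians(matrix, exp.design))
    return exp, matrix, table


@pytest.fixture(scope="session")
def noisy_experiment():
    return simulate_experiment(default_config(seed=7, n_genes=600))


@pytest.fixture(scope="session")
def noisy_matrix(noisy_experiment):
    exp = noisy_experiment
    return normalize_pipeline(exp.spots, exp.annotation)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
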