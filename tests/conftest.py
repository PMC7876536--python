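import logging

import numpy as np
import pandas as pd
import pytest

from holonet.data_io import OmicsMatrix
from holonet.synthgen import fixture_small

logging.getLogger("holonet").setLevel(logging.ERROR)


def make_matrix(array, kingdom="host", stage="normalized_log2", prefix="g"):
    """Wrap a 2-D array as an OmicsMatrix with generated ids."""
    array = np.asarray(array, dtype=float)
    df = pd.DataFrame(
        array,
        index=[f"{prefix}{i}" for i in range(array.shape[0])],
        columns=[f"s{j}" for j in range(array.shape[1])],
    )
    return OmicsMatrix(df, kingdom=kingdom, stage=stage)


def random_matrix(seed, n_features=30, n_samples=20, **kw):
    rng = np.random.default_rng(seed)
    return make_matrix(rng.standard_normal((n_features, n_samples)), **kw)


@pytest.fixture(scope="session")
def fixture_data():
    """The bundled deterministic dataset (host, microbe, samples, truth)."""
    return fixture_small()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Fixture dataset written to disk as the pipeline's input files."""
    from holonet.pipeline import simulate_to_dir
    from holonet.synthgen import fixture_config

    out = tmp_path_factory.mktemp("fixture")
    return simulate_to_dir(fixture_config(), out)
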