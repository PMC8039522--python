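import numpy as np
import pandas as pd
import pytest

import nephronet as nn
from nephronet.network import NetworkParams, detect_modules

#: study-scale default bundle shared by recovery tests (expensive to build)
DEFAULT_SEED = 2026


@pytest.fixture(scope="session")
def default_bundle():
    """Default synthetic study: 3 modules x 150 genes, 500 background,
    100 samples, with planted disease effects on two modules."""
    return nn.simulate_expression_study(
        n_genes=950, n_samples=100, module_sizes=[150, 150, 150],
        disease_effect={"turquoise": 1.0, "blue": -0.8},
        seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_partition(default_bundle):
    """One full module-detection pass on the default bundle."""
    params = NetworkParams(seed=DEFAULT_SEED)
    return detect_modules(default_bundle.expression, params)


@pytest.fixture(scope="session")
def default_network(default_bundle, default_partition):
    """Eigengenes and kME of the detected partition."""
    X = default_bundle.expression
    ME = nn.eigengene_matrix(X, default_partition)
    K = nn.kme(X, ME)
    return ME, K


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_dge_frame(values, genes=None):
    genes = genes or [f"G{i:04d}" for i in range(len(values))]
    return pd.DataFrame({"log2FC": np.asarray(values, dtype=float)},
                        index=pd.Index(genes, name="gene"))
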