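import numpy as np
import pandas as pd
import pytest

import gliostate as gs


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset shared across read-only tests."""
    design = gs.default_design(
        seed=7,
        n_background=200,
        signature_blocks=(
            gs.SignatureBlock("acute_injury", 20, "up", 2.0, "acute"),
            gs.SignatureBlock("dam", 20, "up", 2.0, "chronic"),
            gs.SignatureBlock("homeostatic", 20, "down", 2.0, "chronic"),
        ),
    )
    counts, truth = gs.simulate_counts(design)
    return design, counts, truth


@pytest.fixture(scope="session")
def small_norm(small_sim):
    _, counts, truth = small_sim
    return gs.housekeeping_normalize(counts, truth.housekeeping_genes)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_count_matrix(values, samples=None, divs=None, conditions=None):
    """Tiny CountMatrix helper for hand-built examples."""
    values = np.asarray(values)
    n_genes, n_samples = values.shape
    genes = [f"g{i}" for i in range(n_genes)]
    samples = samples or [f"s{i}" for i in range(n_samples)]
    divs = divs if divs is not None else list(range(n_samples))
    conditions = conditions or [f"c{d}" for d in divs]
    counts = pd.DataFrame(values, index=genes, columns=samples)
    meta = pd.DataFrame(
        {"div": divs, "condition": conditions, "replicate": list(range(n_samples))},
        index=pd.Index(samples, name="sample"),
    )
    return gs.CountMatrix(counts=counts, metadata=meta)
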