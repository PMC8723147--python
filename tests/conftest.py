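import numpy as np
import pytest

import rnassist as rn


@pytest.fixture(scope="session")
def small_cfg():
    return rn.SynthConfig(
        n_genes=200,
        n_samples_per_group=30,
        n_modules=4,
        n_deg=20,
        n_planted_regulators=8,
        n_deg_modules=1,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return rn.generate(small_cfg)


@pytest.fixture(scope="session")
def small_tom(small_cohort):
    expr, _, _, _ = small_cohort
    return rn.build_tom(expr, beta=6.0)


@pytest.fixture(scope="session")
def small_modules(small_tom):
    return rn.louvain_modules(small_tom, seed=7)


@pytest.fixture(scope="session")
def small_embedding(small_tom):
    return rn.embed(small_tom, d=16, max_epoch=100, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def toy_tom(weights, ids=None):
    """TOMNetwork from a raw square array (diagonal forced to 1)."""
    w = np.asarray(weights, dtype=float)
    np.fill_diagonal(w, 1.0)
    ids = ids or [f"g{i}" for i in range(w.shape[0])]
    return rn.TOMNetwork(list(ids), w)
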