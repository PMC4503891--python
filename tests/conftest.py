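from dataclasses import replace

import pytest

from myofilquant.lcms import default_ground_truth, simulate_design
from myofilquant.pipeline import RunConfig, default_config
from myofilquant.species import load_fixture


def small_run_config() -> RunConfig:
    """Default study config shrunk for fast end-to-end runs."""
    cfg = default_config()
    cfg.lcms["n_replicates"] = 2
    cfg.motility["n_filaments"] = 8
    cfg.motility["n_frames"] = 40
    cfg.motility["pca_grid"] = [6.8, 6.5, 6.2, 6.0, 5.5, 4.0]
    return cfg


@pytest.fixture
def small_config():
    return small_run_config()


@pytest.fixture(scope="session")
def fixture_table():
    return load_fixture()


@pytest.fixture(scope="session")
def noiseless_truth():
    """Study ground truth with all stochastic nuisances off."""
    return replace(default_ground_truth(), noise_cv=0.0, loading_sigma=0.0)


@pytest.fixture(scope="session")
def noiseless_design(noiseless_truth):
    """One full noiseless design: 3 groups x 3 replicates x {untreated, treated}."""
    return simulate_design(noiseless_truth, master_seed=42)
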