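import numpy as np
import pytest

from ecocycler.pipeline import run_pipeline, validate_config
from ecocycler.synthetic_foodweb import ScenarioSpec, default_config, simulate_biomass


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def small_run(config):
    """3-member ensemble for one scenario (fast, deterministic)."""
    return simulate_biomass(config, ScenarioSpec("RCP45", "BSAP", "SQ"), members=3, seed=11)


@pytest.fixture(scope="session")
def full_pipeline(tmp_path_factory):
    """One full default run (16 scenarios, 20 members, 2000-2090), shared by
    the pipeline and acceptance tests."""
    out = tmp_path_factory.mktemp("fullrun")
    cfg = validate_config({"seed": 7, "out_dir": str(out)})
    manifest = run_pipeline(cfg)
    return cfg, manifest, out


def random_flow_matrix(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """Sparse-ish nonnegative random flow matrix with at least one positive entry."""
    if n is None:
        n = int(rng.integers(2, 11))
    T = rng.random((n, n)) * (rng.random((n, n)) < 0.6)
    if T.sum() == 0:
        T[rng.integers(n), rng.integers(n)] = rng.random() + 0.1
    return T
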