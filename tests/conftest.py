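import numpy as np
import pytest

from canopyhsm import synthetic_forest as sf
from canopyhsm.pipeline import RunConfig, run_pipeline


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default-scale pipeline run shared across tests."""
    out = tmp_path_factory.mktemp("run")
    return run_pipeline(RunConfig(out_dir=str(out), seed=1))


@pytest.fixture(scope="session")
def separated_stand():
    """100 trees on a jittered grid with spacing > 2 crown radii, plus the
    0.25-m canopy surface they render to."""
    rng = np.random.default_rng(7)
    spacing = 16.0
    gx, gy = np.meshgrid(np.arange(10), np.arange(10))
    x = 10.0 + gx.ravel() * spacing + rng.uniform(-1.5, 1.5, 100)
    y = 10.0 + gy.ravel() * spacing + rng.uniform(-1.5, 1.5, 100)
    h = rng.uniform(30.0, 60.0, 100)   # crown radius 3-6 m < spacing/2
    stems = sf.StemMap(x, y, h)
    extent = (0.0, 0.0, 165.0, 165.0)
    dsm = sf.render_dsm(stems, extent, resolution=0.25, crown_radius_coeff=0.1)
    return stems, dsm
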