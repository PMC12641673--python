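import numpy as np
import pytest

from phagometry.volumes import StackGeometry


@pytest.fixture
def iso2_geometry():
    """Small 2 µm isotropic geometry used across unit tests."""
    return StackGeometry(voxel_size_um=(2.0, 2.0, 2.0), shape=(32, 32, 32))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def default_phantom_run():
    """One noise-free default phantom pipeline run, shared across tests."""
    import tempfile

    from phagometry.pipeline import default_phantom_run_config, run_pipeline

    with tempfile.TemporaryDirectory() as tmp:
        cfg = default_phantom_run_config(seed=7, output_dir=tmp)
        report = run_pipeline(cfg)
        yield cfg, report
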