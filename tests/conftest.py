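import numpy as np
import pytest

from pact_recon.geometry import ArrayGeometry, ScanTrajectory, build_grid


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_geometry():
    """A 4-element focused array with a 3-line scan: cheap but non-trivial."""
    geometry = ArrayGeometry(n_elements=4, pitch=1.0, focal_length=8.0)
    trajectory = ScanTrajectory(step_size=1.0, n_positions=3)
    grid = build_grid(6.0, 4.0, 3.0, rf=1.0)
    return geometry, trajectory, grid
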