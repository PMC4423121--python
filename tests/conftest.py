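import numpy as np
import pytest

from mtarray import CellGeometry, SynthConfig


@pytest.fixture
def geometry() -> CellGeometry:
    """Elongated 100 × 12 μm cell with the axis along x."""
    outline = np.array([[-50.0, -6.0], [50.0, -6.0], [50.0, 6.0], [-50.0, 6.0]])
    return CellGeometry(outline=outline, axis=np.array([[-50.0, 0.0], [50.0, 0.0]]))


@pytest.fixture
def small_config() -> SynthConfig:
    """Down-scaled generator config for fast unit tests."""
    return SynthConfig(seed=42, n_filaments=40, n_tracks=40, n_marks=10,
                       n_encounters=40, n_singles=10, n_bundles=20, n_cells=100)
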