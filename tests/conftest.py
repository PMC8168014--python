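import numpy as np
import pytest

from lhamap.atlas import load_atlas
from lhamap.counting import train_density_model
from lhamap.synth import default_design, simulate_brain, simulate_training_set


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


@pytest.fixture(scope="session")
def tile_pool():
    """Shared pool of annotated tiles: 60 training + 30 evaluation."""
    return simulate_training_set(90, seed=1)


@pytest.fixture(scope="session")
def density_model(tile_pool):
    """A modest density counter shared by counting tests."""
    return train_density_model(tile_pool[:60], seed=1)


@pytest.fixture(scope="session")
def small_rendered_brain(atlas):
    """One rendered brain at a count-scaled desk resolution.

    Coarser pixels (20 µm) with the brain total scaled by the squared
    resolution ratio keep the per-pixel soma density at the calibrated
    5 µm/px level.
    """
    design = default_design(
        atlas,
        total_neurons=50_000.0 * (0.005 / 0.02) ** 2,
        pixel_size_mm=0.02,
        injection_backflow=0.2,
        landmark_noise_px=0.0,
    )
    return design, simulate_brain(atlas, design, "WT", brain_seed=7)
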