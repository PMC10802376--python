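"""Shared fixtures: synthetic spot libraries, movies, and trained classifiers."""

import numpy as np
import pytest

from ms2quant import synthdata as sd
from ms2quant.classification import LogisticSpotClassifier, VoxelDataset


@pytest.fixture(scope="session")
def operating_point():
    """(amplitude, gradient) calibrated to the experimental operating point
    (signal:background 0.35, structuredness 40)."""
    return sd.operating_point_amplitudes(0.35, 40.0)


@pytest.fixture(scope="session")
def operating_point_library(operating_point):
    """120 noisy spots at the experimental operating point."""
    amp, grad = operating_point
    rng = np.random.default_rng(1)
    c0 = (np.asarray(sd.VOXEL_SHAPE) - 1) / 2
    lib = []
    for _ in range(120):
        spec = sd.SpotSpec(amplitude=amp, gradient_amplitude=grad,
                           gradient_direction=sd.random_unit_vector(rng),
                           true_center=tuple(c0 + rng.uniform(-0.5, 0.5, 3)))
        voxel, truth = sd.generate_spot_voxel(
            spec, seed=int(rng.integers(2**31)))
        lib.append({"spec": spec, "voxel": voxel, "truth": truth})
    return lib


@pytest.fixture(scope="session")
def square_wave():
    return sd.square_wave_promoter(period=20, duty=0.5, amplitude=1000.0)


@pytest.fixture(scope="session")
def synthetic_movie(square_wave):
    """5-nucleus, 40-frame movie with square-wave promoter traces."""
    return sd.generate_synthetic_movie(n_nuclei=5, n_timepoints=40, seed=3,
                                       promoter_model=square_wave)


@pytest.fixture(scope="session")
def movie_classifier(square_wave):
    """Logistic fallback classifier trained on a separate synthetic movie."""
    mcp, _, truth = sd.generate_synthetic_movie(
        n_nuclei=5, n_timepoints=20, seed=21, promoter_model=square_wave)
    x, y = sd.label_voxels_from_movie(mcp, truth, seed=22)
    return LogisticSpotClassifier().fit(VoxelDataset(x, y))
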