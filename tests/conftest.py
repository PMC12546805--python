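import warnings

import numpy as np
import pytest

from ciliametry.io_formats import CiliaTable, ImageStack, RunMetadata
from ciliametry.phantom import (
    CenterlineSpec,
    GroupSpec,
    PhantomTruth,
    generate_centerline,
    generate_grouped_tables,
    rasterize_scene,
)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    # user-facing warnings (version mismatch, empty masks) are expected in
    # many scenarios exercised here; tests that care assert them explicitly
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def straight_centerline():
    return CenterlineSpec(np.array([[1.0, 1.0, 1.0], [6.0, 1.0, 1.0]]))


@pytest.fixture
def small_stack(rng):
    """A 2-channel 8-bit stack with known voxel size."""
    voxels = rng.integers(0, 200, size=(2, 6, 32, 32)).astype(np.uint8)
    return ImageStack(voxels=voxels, voxel_size_um=(0.1, 0.1, 0.5), bit_depth=8)


@pytest.fixture
def noisefree_phantom():
    """One straight tube, no noise/PSF: exactly recoverable by thresholding."""
    cl = CenterlineSpec(np.array([[2.0, 5.0, 3.0], [9.0, 5.0, 3.0]]),
                        radius_um=0.3, intensity=200.0)
    truth = PhantomTruth(centerlines=[cl], voxel_size_um=(0.1, 0.1, 0.5),
                         snr=np.inf, background_level=0.0,
                         psf_sigma_um=(0.0, 0.0, 0.0), seed=1)
    stack = rasterize_scene(truth, (12, 110, 110))
    return truth, stack


@pytest.fixture
def grouped_dataset_dirs(tmp_path):
    """Two-condition grouped tables with a planted length effect."""
    specs = [
        GroupSpec("control", n_replicates=3, cilia_per_replicate=30,
                  distribution="normal",
                  location={"cilia_length_um": 3.0, "volume_um3": 0.5},
                  scale={"cilia_length_um": 0.5, "volume_um3": 0.1}),
        GroupSpec("treated", n_replicates=3, cilia_per_replicate=30,
                  distribution="normal",
                  location={"cilia_length_um": 3.0, "volume_um3": 0.5},
                  scale={"cilia_length_um": 0.5, "volume_um3": 0.1},
                  effect={"cilia_length_um": 1.5}),
    ]
    result = generate_grouped_tables(
        specs, ["cilia_length_um", "volume_um3"], seed=99, root=tmp_path)
    return [result.group_folders["control"], result.group_folders["treated"]]
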