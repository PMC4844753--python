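import numpy as np
import pytest

from alveoquant import (
    SceneSpec,
    SegmentationParams,
    VoxelSpacing,
    find_seeds,
    generate_scene,
    interior_distance,
    membrane_mask,
    size_filter,
    watershed_cells,
)

#: default fixture scene of the package: one alveolus, ~40 cells, seed 42
FIXTURE_SEED = 42


@pytest.fixture(scope="session")
def default_scene():
    """The default fixture scene: channels + ground truth."""
    return generate_scene(SceneSpec(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def segmented_default(default_scene):
    """Membrane-pipeline segmentation of the default scene at default params."""
    channels, truth = default_scene
    membrane = channels[0]
    params = SegmentationParams()
    mask = membrane_mask(membrane, params)
    distance = interior_distance(mask, membrane.spacing)
    seeds = find_seeds(distance, params, membrane.spacing)
    cells = watershed_cells(membrane, mask, seeds, params)
    filtered, removed = size_filter(cells, params)
    return filtered, removed, truth


@pytest.fixture(scope="session")
def small_spec():
    """A desk-sized alveolus for fast unit tests (~12 cells, ~0.4 s)."""
    return SceneSpec(
        alveolus_radius=22.0,
        lumen_radius=13.0,
        n_cells=12,
        nucleus_radius=3.0,
        p_binucleated=0.5,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_scene(small_spec):
    return generate_scene(small_spec)


def digitize_sphere(
    center: tuple[float, float, float],
    radius: float,
    shape: tuple[int, int, int],
    spacing: VoxelSpacing,
) -> np.ndarray:
    """Boolean mask of a sphere given in physical coordinates."""
    zz = np.arange(shape[0])[:, None, None] * spacing.dz
    yy = np.arange(shape[1])[None, :, None] * spacing.dy
    xx = np.arange(shape[2])[None, None, :] * spacing.dx
    return (
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    ) <= radius**2
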