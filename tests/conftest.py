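import numpy as np
import pytest

import focusq
from focusq.segmentation import (
    SegmentationConfig,
    equalize_intensity,
    segment_cells,
    segment_structures,
    subtract_background,
)


@pytest.fixture(scope="session")
def default_config():
    return SegmentationConfig()


def analyze_fov(fov, mode, config=None):
    """Background-subtract and segment one field of view.

    Returns (subtracted FieldOfView, cell label map, StructureLabelMap).
    """
    config = config or SegmentationConfig()
    primary = subtract_background(fov.primary, config)
    channels = {"primary": primary}
    if fov.secondary is not None:
        channels["secondary"] = subtract_background(fov.secondary, config)
    sub = focusq.FieldOfView(
        channels=channels, condition=fov.condition, well=fov.well, site=fov.site
    )
    cells = segment_cells(sub, config)
    equalized = equalize_intensity(primary, config)
    structures = segment_structures(primary, equalized, cells, mode, config)
    return sub, cells, structures


def analyze_scene(spec, mode, config=None):
    """Full single-scene analysis chain used across the suite."""
    fov, truth = focusq.generate_scene(spec)
    sub, cells, structures = analyze_fov(fov, mode, config)
    return fov, truth, sub, cells, structures


@pytest.fixture(scope="session")
def dispersed_scene():
    """One analyzed dispersed scene shared by read-only tests."""
    return analyze_scene(focusq.SceneSpec(seed=3), "punctum")


@pytest.fixture(scope="session")
def clustered_scene():
    return analyze_scene(focusq.SceneSpec(pattern="clustered", seed=3), "focus")
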