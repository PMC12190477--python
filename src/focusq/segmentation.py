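"""Preprocessing and two-level segmentation.

Stages, in pipeline order:

1. :func:`subtract_background` -- morphological-opening (rolling-ball-like)
   background estimate subtracted from every channel before any analysis.
2. :func:`segment_cells` -- foreground by intensity threshold on the primary
   channel, small components removed, then split into single cells by a
   watershed on a Gaussian-blurred image (primary alone, or a merge of the
   primary and nuclear channels).
3. :func:`equalize_intensity` -- divide the background-subtracted image by a
   heavy Gaussian blur of itself, yielding a dimensionless image with roughly
   equal contrast between dim and bright cells.
4. :func:`segment_structures` -- bright pixels in BOTH the raw and equalized
   images (two manual thresholds, held constant across images and
   conditions), intersected with the cell mask, then size exclusion: minimum
   component area 5 px for puncta, 35 px for foci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk, opening, remove_small_objects
from skimage.segmentation import relabel_sequential, watershed

from .io import FieldOfView

logger = logging.getLogger(__name__)

MIN_AREA_FOCUS = 35
MIN_AREA_PUNCTUM = 5


@dataclass(frozen=True)
class SegmentationConfig:
    """All segmentation parameters; thresholds are manual and held constant
    across images and conditions within a run.

    Attributes
    ----------
    background_radius : structuring-element radius (px) of the opening used
        as background estimate.  Must exceed the half-width of any feature to
        keep (cells included): default 50 px, larger than a typical cell
        radius but below its diameter.
    cell_intensity_threshold : foreground threshold on the background-
        subtracted primary channel (intensity units).
    cell_min_area / cell_max_area : area filter for candidate cell components
        (max filter optional, off by default).
    watershed_blur_sigma : Gaussian sigma for the image the watershed runs on.
    use_nuclear_channel_in_watershed : seed the watershed from nuclei found in
        the nuclear channel instead of distance-transform peaks.
    marker_min_distance / marker_smooth_sigma : peak separation and smoothing
        of the distance transform when seeding without nuclei.
    equalization_blur_sigma : Gaussian sigma of the blur-divide equalization;
        should be at least a cell radius so only cell-scale intensity is
        flattened.
    raw_bright_threshold / equalized_bright_threshold : the two manual
        structure thresholds (intensity units / ratio units).
    min_area_focus / min_area_punctum : size-exclusion minima, 35 and 5 px.
    """

    background_radius: int = 50
    cell_intensity_threshold: float = 30.0
    cell_min_area: int = 400
    cell_max_area: int | None = None
    watershed_blur_sigma: float = 4.0
    use_nuclear_channel_in_watershed: bool = False
    marker_min_distance: int = 20
    marker_smooth_sigma: float = 4.0
    equalization_blur_sigma: float = 40.0
    raw_bright_threshold: float = 300.0
    equalized_bright_threshold: float = 1.8
    min_area_focus: int = MIN_AREA_FOCUS
    min_area_punctum: int = MIN_AREA_PUNCTUM

    def __post_init__(self) -> None:
        if not self.min_area_focus > self.min_area_punctum > 0:
            raise ValueError("need min_area_focus > min_area_punctum > 0")
        if self.background_radius <= 0 or self.equalization_blur_sigma <= 0:
            raise ValueError("radii and sigmas must be positive")

    def min_area(self, mode: str) -> int:
        if mode == "focus":
            return self.min_area_focus
        if mode == "punctum":
            return self.min_area_punctum
        raise ValueError(f"mode must be 'punctum' or 'focus', got {mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SegmentationConfig":
        return cls(**dict(d))


@dataclass
class StructureLabelMap:
    """Labeled puncta/foci with their owning cells.

    ``labels`` is a 2D int array (0 = background); ``cell_ids`` maps each
    structure label to the id of the cell holding the majority of its pixels.
    """

    labels: np.ndarray
    mode: str
    cell_ids: dict[int, int]

    @property
    def n_structures(self) -> int:
        return len(self.cell_ids)

    def mask(self) -> np.ndarray:
        return self.labels > 0


def _check_finite(channel: np.ndarray) -> np.ndarray:
    channel = np.asarray(channel, dtype=np.float64)
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite pixels")
    return channel


def subtract_background(channel: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Remove slowly varying background by subtracting a morphological opening.

    The opening with a disk of ``background_radius`` flattens everything
    narrower than the disk onto the local background surface; subtracting it
    maps flat regions near zero while leaving the contrast of cells and
    structures intact.  Output is clipped at 0.
    """
    config = config or SegmentationConfig()
    channel = _check_finite(channel)
    footprint = disk(config.background_radius, decomposition="sequence")
    background = opening(channel, footprint)
    return np.clip(channel - background, 0.0, None)


def equalize_intensity(channel: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Blur-divide equalization: ``channel / blur(channel)``.

    A Gaussian blur at ``equalization_blur_sigma`` removes detail smaller
    than a cell; dividing the original by it yields a dimensionless image in
    which a spot of given relative contrast peaks at the same value in a dim
    cell and a bright one.  Pixels whose blurred value falls below
    ``eps = 1e-6 * max(channel)`` (true background) map to 0.
    """
    config = config or SegmentationConfig()
    channel = _check_finite(channel)
    peak = float(channel.max())
    if peak <= 0:
        return np.zeros_like(channel)
    blurred = gaussian(channel, sigma=config.equalization_blur_sigma, preserve_range=True)
    eps = 1e-6 * peak
    out = channel / (blurred + eps)
    out[blurred < eps] = 0.0
    return out


def _watershed_markers(fg: np.ndarray, blur_basis: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    """Seed markers from smoothed distance-transform peaks, one per blob minimum."""
    distance = ndi.distance_transform_edt(fg)
    smoothed = gaussian(distance, sigma=config.marker_smooth_sigma, preserve_range=True)
    coords = peak_local_max(
        smoothed,
        min_distance=config.marker_min_distance,
        labels=cc_label(fg, connectivity=2),
        exclude_border=False,
    )
    markers = np.zeros(fg.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    # guarantee every foreground component owns at least one marker
    comps = cc_label(fg, connectivity=2)
    next_id = markers.max() + 1
    for comp in range(1, comps.max() + 1):
        sel = comps == comp
        if not markers[sel].any():
            flat = np.where(sel.ravel())[0][np.argmax(distance[sel])]
            markers.ravel()[flat] = next_id
            next_id += 1
    return markers


def _nuclear_markers(nuclear: np.ndarray, fg: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    blurred = gaussian(nuclear, sigma=config.watershed_blur_sigma, preserve_range=True)
    if blurred.max() <= 0:
        return np.zeros(fg.shape, dtype=np.int32)
    nuclei = blurred > threshold_otsu(blurred)
    nuclei = remove_small_objects(nuclei, max_size=max(config.min_area_punctum * 4, 20) - 1)
    markers = cc_label(nuclei, connectivity=2).astype(np.int32)
    markers[~fg] = 0
    return markers


def segment_cells(fov: FieldOfView, config: SegmentationConfig | None = None) -> np.ndarray:
    """Single-cell segmentation of the background-subtracted primary channel.

    Foreground = primary intensity above ``cell_intensity_threshold`` with
    components below ``cell_min_area`` removed, partitioned into cells by a
    watershed on the Gaussian-blurred primary image (or on a primary+nuclear
    merge when ``use_nuclear_channel_in_watershed`` is set).  Returns a label
    map with consecutive positive labels; an empty foreground yields an
    all-zero map.
    """
    config = config or SegmentationConfig()
    primary = _check_finite(fov.primary)
    fg = primary > config.cell_intensity_threshold
    fg = remove_small_objects(fg, max_size=config.cell_min_area - 1)
    if config.cell_max_area is not None:
        comps = cc_label(fg, connectivity=2)
        areas = np.bincount(comps.ravel())
        too_big = np.where(areas > config.cell_max_area)[0]
        for lbl in too_big:
            if lbl:
                fg[comps == lbl] = False
    if not fg.any():
        return np.zeros(primary.shape, dtype=np.int32)

    basis = primary
    if config.use_nuclear_channel_in_watershed:
        if fov.nuclear is None:
            raise ValueError("nuclear channel required by configuration but absent")
        basis = primary + fov.nuclear
        markers = _nuclear_markers(fov.nuclear, fg, config)
        if not markers.any():
            markers = _watershed_markers(fg, basis, config)
    else:
        markers = _watershed_markers(fg, basis, config)

    blurred = gaussian(basis, sigma=config.watershed_blur_sigma, preserve_range=True)
    labels = watershed(-blurred, markers=markers, mask=fg)
    labels = remove_small_objects(labels, max_size=config.cell_min_area - 1)
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def segment_structures(
    channel: np.ndarray,
    equalized: np.ndarray,
    cells: np.ndarray,
    mode: str = "punctum",
    config: SegmentationConfig | None = None,
) -> StructureLabelMap:
    """Detect puncta or foci by dual thresholding plus size exclusion.

    A pixel is a candidate when it is bright in the raw (background-
    subtracted) image AND bright in the equalized image AND inside a cell.
    8-connected components smaller than the mode's minimum area (5 px for
    puncta, 35 px for foci) are removed; each survivor is assigned to the
    cell containing the majority of its pixels (ties broken by lower id).
    """
    config = config or SegmentationConfig()
    channel = _check_finite(channel)
    if channel.shape != equalized.shape or channel.shape != cells.shape:
        raise ValueError("channel, equalized and cells must share one shape")
    min_area = config.min_area(mode)

    mask = (
        (channel > config.raw_bright_threshold)
        & (equalized > config.equalized_bright_threshold)
        & (cells > 0)
    )
    labels = cc_label(mask, connectivity=2)
    areas = np.bincount(labels.ravel())
    keep = np.zeros(areas.size, dtype=bool)
    keep[1:] = areas[1:] >= min_area
    labels[~keep[labels]] = 0
    labels, _, _ = relabel_sequential(labels)
    labels = labels.astype(np.int32)

    cell_ids: dict[int, int] = {}
    for lbl in range(1, labels.max() + 1):
        owners = cells[labels == lbl]
        counts = np.bincount(owners)
        counts[0] = 0  # cell-mask intersection guarantees some nonzero owner
        cell_ids[lbl] = int(counts.argmax())
    return StructureLabelMap(labels=labels, mode=mode, cell_ids=cell_ids)
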