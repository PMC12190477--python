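"""Synthetic multi-channel fields of view with planted ground truth.

The generator emulates the imaging setup the pipeline targets: a field of
view containing several cells whose primary channel (a punctate fluorescent
reporter such as tagged LC3B) shows either many small dispersed perinuclear
puncta or one large clustered focus per cell, a secondary channel carrying
signal on a controllable fraction of structures, an optional nuclear channel,
plus a slow background gradient and additive Gaussian noise.

Cells are rendered as ellipses with bounded eccentricity so the watershed
stage faces non-circular objects; structures are isotropic 2D Gaussian spots
(sigma = radius / 2), matching the diffraction-limited appearance of real
puncta and giving the thresholding stages soft edges to work against.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .io import FieldOfView, PlateLayout, save_fov

logger = logging.getLogger(__name__)

PATTERNS = ("dispersed", "clustered", "none")


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic field of view.

    Intensities are in arbitrary camera units; lengths in pixels.  Identical
    specs (including ``seed``) render bit-identical images and ground truth.

    Attributes
    ----------
    image_shape : (H, W) of every channel.
    n_cells : number of non-overlapping cells to place.
    cell_radius_range : (min, max) of the major semi-axis of the elliptical cell.
    eccentricity_max : maximum major/minor axis ratio.
    nucleus_radius_fraction : nucleus radius as a fraction of the minor semi-axis.
    pattern : ``dispersed`` (n_puncta_per_cell small puncta in a perinuclear
        annulus), ``clustered`` (one large focus adjacent to the nucleus) or
        ``none`` (no structures).
    cluster_offset : distance of the focus centre from the nucleus edge.
    coloc_fraction : fraction of structures that carry secondary signal.
    structure_amplitude / secondary_amplitude : peak height of a structure's
        Gaussian spot in the primary / secondary channel.
    cytoplasm_amplitude / secondary_cytoplasm_amplitude : diffuse fill level
        inside cells in each channel.
    noise_sd : sigma of the additive Gaussian noise (clipped at 0).
    background_gradient_amplitude : peak-to-trough of a linear ramp across the
        field, emulating uneven illumination.
    """

    image_shape: tuple[int, int] = (256, 256)
    n_cells: int = 6
    cell_radius_range: tuple[float, float] = (24.0, 34.0)
    eccentricity_max: float = 1.5
    nucleus_radius_fraction: float = 0.35
    pattern: str = "dispersed"
    n_puncta_per_cell: int = 8
    punctum_radius: float = 2.5
    focus_radius: float = 8.0
    cluster_offset: float = 2.0
    coloc_fraction: float = 0.5
    structure_amplitude: float = 600.0
    cytoplasm_amplitude: float = 60.0
    secondary_amplitude: float = 400.0
    secondary_cytoplasm_amplitude: float = 60.0
    nuclear_amplitude: float = 300.0
    background_level: float = 80.0
    noise_sd: float = 6.0
    background_gradient_amplitude: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("punctum_radius", "focus_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.cell_radius_range
        if not 0 < lo <= hi:
            raise ValueError("cell_radius_range must satisfy 0 < min <= max")
        if not 0 < self.nucleus_radius_fraction < 1:
            raise ValueError("nucleus_radius_fraction must lie in (0, 1)")
        if self.eccentricity_max < 1:
            raise ValueError("eccentricity_max must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        d["cell_radius_range"] = list(self.cell_radius_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SceneSpec":
        d = dict(d)
        if "image_shape" in d:
            d["image_shape"] = tuple(d["image_shape"])
        if "cell_radius_range" in d:
            d["cell_radius_range"] = tuple(d["cell_radius_range"])
        return cls(**d)


@dataclass
class StructureRecord:
    """Planted structure: owning cell, centre (row, col), radius, mode, flag."""

    cell: int
    center: tuple[float, float]
    radius: float
    mode: str  # "punctum" | "focus"
    has_secondary: bool


@dataclass
class GroundTruth:
    """The generator's planted truth for one scene."""

    cell_masks: np.ndarray
    nucleus_masks: np.ndarray
    structure_records: list[StructureRecord]
    pattern_class: dict[int, str]

    @property
    def n_cells(self) -> int:
        return int(self.cell_masks.max())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cell": r.cell,
                "row": r.center[0],
                "col": r.center[1],
                "radius": r.radius,
                "mode": r.mode,
                "has_secondary": r.has_secondary,
                "pattern": self.pattern_class.get(r.cell, ""),
            }
            for r in self.structure_records
        ]
        return pd.DataFrame(
            rows,
            columns=["cell", "row", "col", "radius", "mode", "has_secondary", "pattern"],
        )


# ---------------------------------------------------------------------------
# geometry helpers

def _ellipse_params(rng: np.random.Generator, spec: SceneSpec):
    lo, hi = spec.cell_radius_range
    a = rng.uniform(lo, hi)  # major semi-axis
    ecc = rng.uniform(1.0, spec.eccentricity_max)
    b = a / ecc
    theta = rng.uniform(0, math.pi)
    return a, b, theta


def _ellipse_mask(shape, center, a, b, theta) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ct, st = math.cos(theta), math.sin(theta)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _place_cells(rng: np.random.Generator, spec: SceneSpec):
    """Reject-and-resample placement of non-overlapping elliptical cells."""
    H, W = spec.image_shape
    placed: list[tuple[tuple[float, float], float, float, float]] = []
    max_tries = 200 * max(spec.n_cells, 1)
    tries = 0
    while len(placed) < spec.n_cells:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {spec.n_cells} non-overlapping cells in "
                f"{spec.image_shape} after {max_tries} attempts (spec: {spec})"
            )
        tries += 1
        a, b, theta = _ellipse_params(rng, spec)
        margin = a + 2.0
        if 2 * margin >= min(H, W):
            raise PlacementError(
                f"cell radius {a:.1f} does not fit image {spec.image_shape} (spec: {spec})"
            )
        center = (rng.uniform(margin, H - margin), rng.uniform(margin, W - margin))
        # conservative overlap test on bounding circles of the major axes
        ok = all(
            math.hypot(center[0] - c0[0], center[1] - c0[1]) > a + a0 + 2.0
            for c0, a0, _, _ in placed
        )
        if ok:
            placed.append((center, a, b, theta))
    return placed


def _gaussian_spot(img: np.ndarray, center, sigma: float, amplitude: float) -> None:
    """Add an isotropic 2D Gaussian of peak ``amplitude`` in place."""
    H, W = img.shape
    half = max(int(math.ceil(4 * sigma)), 2)
    r0 = max(int(center[0]) - half, 0)
    r1 = min(int(center[0]) + half + 1, H)
    c0 = max(int(center[1]) - half, 0)
    c1 = min(int(center[1]) + half + 1, W)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    img[r0:r1, c0:c1] += amplitude * np.exp(-d2 / (2.0 * sigma**2))


def _structure_centers(rng, spec: SceneSpec, cell_geom, nucleus_radius):
    """Sample structure centres for one cell, inside the cell mask.

    Dispersed puncta are scattered uniformly in an elliptical annulus between
    the nucleus edge and 85 % of the cell boundary; a clustered focus sits at
    ``cluster_offset`` pixels from the nucleus edge, emulating the perinuclear
    placement of real LC3B foci.
    """
    center, a, b, theta = cell_geom
    ct, st = math.cos(theta), math.sin(theta)
    out = []
    if spec.pattern == "dispersed":
        t_min = min(spec.nucleus_radius_fraction + 0.10, 0.8)
        # puncta are distinct objects: keep centres a diameter apart so every
        # planted record renders as its own connected structure
        min_sep = 2.0 * spec.punctum_radius + 1.0
        tries = 0
        max_tries = 200 * max(spec.n_puncta_per_cell, 1)
        while len(out) < spec.n_puncta_per_cell:
            if tries >= max_tries:
                raise PlacementError(
                    f"could not place {spec.n_puncta_per_cell} puncta with "
                    f"separation {min_sep:.1f} px in one cell (spec: {spec})"
                )
            tries += 1
            t = math.sqrt(rng.uniform(t_min**2, 0.85**2))
            phi = rng.uniform(0, 2 * math.pi)
            u = t * a * math.cos(phi)
            v = t * b * math.sin(phi)
            p = (center[0] + u * ct - v * st, center[1] + u * st + v * ct)
            if all(math.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep for q in out):
                out.append(p)
    elif spec.pattern == "clustered":
        d = nucleus_radius + spec.cluster_offset
        d = min(d, 0.85 * b)  # keep the focus inside even a small cell
        phi = rng.uniform(0, 2 * math.pi)
        out.append((center[0] + d * math.cos(phi), center[1] + d * math.sin(phi)))
    return out


# ---------------------------------------------------------------------------
# public API

def generate_scene(spec: SceneSpec) -> tuple[FieldOfView, GroundTruth]:
    """Render one field of view and its ground truth from a scene spec.

    The primary channel is background level + linear gradient + cytoplasmic
    fill inside cells + Gaussian structures + Gaussian noise, clipped at 0.
    The secondary channel mirrors the structures flagged ``has_secondary`` on
    top of a diffuse cytoplasmic level; the nuclear channel renders nuclei.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_shape
    cells = _place_cells(rng, spec)

    cell_labels = np.zeros((H, W), dtype=np.int32)
    nucleus_labels = np.zeros((H, W), dtype=np.int32)
    primary = np.zeros((H, W), dtype=np.float64)
    secondary = np.zeros((H, W), dtype=np.float64)
    nuclear = np.zeros((H, W), dtype=np.float64)

    records: list[StructureRecord] = []
    pattern_class: dict[int, str] = {}

    for idx, geom in enumerate(cells, start=1):
        center, a, b, theta = geom
        mask = _ellipse_mask((H, W), center, a, b, theta)
        cell_labels[mask] = idx
        primary[mask] += spec.cytoplasm_amplitude
        secondary[mask] += spec.secondary_cytoplasm_amplitude

        r_nuc = spec.nucleus_radius_fraction * b
        nmask = _ellipse_mask((H, W), center, r_nuc, r_nuc, 0.0)
        nucleus_labels[nmask & mask] = idx
        nuclear[nmask & mask] += spec.nuclear_amplitude

        pattern_class[idx] = spec.pattern
        mode = "focus" if spec.pattern == "clustered" else "punctum"
        radius = spec.focus_radius if spec.pattern == "clustered" else spec.punctum_radius
        for c in _structure_centers(rng, spec, geom, r_nuc):
            records.append(StructureRecord(cell=idx, center=c, radius=radius, mode=mode, has_secondary=False))

    # flag has_secondary on round(coloc_fraction * n) structures, chosen at random
    n_total = len(records)
    n_pos = int(round(spec.coloc_fraction * n_total))
    for j in rng.permutation(n_total)[:n_pos]:
        records[j].has_secondary = True

    for rec in records:
        sigma = rec.radius / 2.0
        _gaussian_spot(primary, rec.center, sigma, spec.structure_amplitude)
        if rec.has_secondary:
            _gaussian_spot(secondary, rec.center, sigma, spec.secondary_amplitude)

    # slow illumination ramp across the field, shared by all channels
    if spec.background_gradient_amplitude > 0:
        ramp = np.linspace(0.0, 1.0, W)[None, :] * np.ones((H, 1))
        gradient = spec.background_gradient_amplitude * ramp
    else:
        gradient = 0.0

    def finish(img: np.ndarray) -> np.ndarray:
        img = img + spec.background_level + gradient
        img = img + rng.normal(0.0, spec.noise_sd, size=(H, W))
        return np.clip(img, 0.0, None)

    fov = FieldOfView(
        channels={
            "primary": finish(primary),
            "secondary": finish(secondary),
            "nuclear": finish(nuclear),
        }
    )
    truth = GroundTruth(
        cell_masks=cell_labels,
        nucleus_masks=nucleus_labels,
        structure_records=records,
        pattern_class=pattern_class,
    )
    for rec in records:
        r, c = int(round(rec.center[0])), int(round(rec.center[1]))
        assert cell_labels[r, c] == rec.cell, "structure centre escaped its cell mask"
    return fov, truth


def derive_seed(base_seed: int, index: int) -> int:
    """Counter-based per-scene seed, stable across partial re-runs."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_plate(
    layout: PlateLayout,
    base_spec: SceneSpec | None = None,
    overrides: Mapping[str, Mapping[str, object]] | None = None,
    base_seed: int = 0,
) -> list[tuple[FieldOfView, GroundTruth]]:
    """Generate one scene per (condition, well, site) of a plate layout.

    ``overrides`` maps condition name -> SceneSpec field overrides, so e.g. a
    treated condition can be rendered ``clustered`` while the control stays
    ``dispersed``.  Seeds derive deterministically from ``base_seed`` and the
    site's position in the layout.
    """
    base_spec = base_spec or SceneSpec()
    overrides = overrides or {}
    out = []
    for index, (cond, well, site) in enumerate(layout.iter_triples()):
        fields = dict(overrides.get(cond, {}))
        fields["seed"] = derive_seed(base_seed, index)
        spec = replace(base_spec, **fields)
        fov, truth = generate_scene(spec)
        fov.condition, fov.well, fov.site = cond, well, site
        out.append((fov, truth))
    return out


def save_scene(
    fov: FieldOfView,
    truth: GroundTruth,
    spec: SceneSpec,
    directory: str | Path,
) -> None:
    """Write a scene as per-channel TIFFs + ground-truth CSV + spec YAML."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_fov(fov, directory)
    stem = f"{fov.well}_{fov.site}" if fov.well else "scene"
    tifffile.imwrite(directory / f"{stem}_cell_truth.tif", truth.cell_masks.astype(np.uint16))
    tifffile.imwrite(directory / f"{stem}_nucleus_truth.tif", truth.nucleus_masks.astype(np.uint16))
    truth.to_frame().to_csv(directory / f"{stem}_structures.csv", index=False)
    with open(directory / f"{stem}_spec.yaml", "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=True)
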