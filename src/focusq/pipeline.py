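"""Config-driven orchestration: simulate -> segment -> metrics -> report.

Every stage is a pure function of (inputs, config); rerunning an identical
config reproduces all outputs byte-identically, which the run manifest's
checksums make easy to verify.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .io import FieldOfView, PlateLayout, load_plate, write_results
from .metrics import (
    aggregate_dispersion,
    aggregate_pearson,
    dispersion_profiles,
    pearson_per_cell,
    positivity_fractions,
    score_structure_positivity,
)
from .segmentation import (
    SegmentationConfig,
    equalize_intensity,
    segment_cells,
    segment_structures,
    subtract_background,
)
from .synthetic import SceneSpec, generate_plate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; fully serialisable to YAML.

    Either ``manifest`` points at a plate of TIFFs on disk, or ``layout`` +
    ``scene`` + ``overrides`` describe a synthetic plate to simulate.
    """

    layout: PlateLayout | None = None
    scene: SceneSpec = field(default_factory=SceneSpec)
    overrides: dict[str, dict] = field(default_factory=dict)
    manifest: str | None = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    structure_mode: str = "punctum"
    positivity_threshold: float = 1.25
    dilation_radius: int = 5
    min_structure_pixels: int = 5
    pool_sites: bool = False
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.structure_mode not in ("punctum", "focus"):
            raise ValueError("structure_mode must be 'punctum' or 'focus'")
        if self.layout is None and self.manifest is None:
            raise ValueError("config needs either a layout (simulate) or a manifest (load)")

    def to_dict(self) -> dict:
        return {
            "layout": self.layout.to_dict() if self.layout else None,
            "scene": self.scene.to_dict(),
            "overrides": self.overrides,
            "manifest": self.manifest,
            "segmentation": self.segmentation.to_dict(),
            "structure_mode": self.structure_mode,
            "positivity_threshold": self.positivity_threshold,
            "dilation_radius": self.dilation_radius,
            "min_structure_pixels": self.min_structure_pixels,
            "pool_sites": self.pool_sites,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if d.get("layout"):
            d["layout"] = PlateLayout.from_dict(d["layout"])
        if "scene" in d and d["scene"] is not None:
            d["scene"] = SceneSpec.from_dict(d["scene"])
        if "segmentation" in d and d["segmentation"] is not None:
            d["segmentation"] = SegmentationConfig.from_dict(d["segmentation"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Hash of the computational parameters (output location excluded)."""
        d = self.to_dict()
        d.pop("output_dir")
        canonical = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    """Outputs of one pipeline run."""

    tables: dict[str, pd.DataFrame]
    paths: dict[str, Path]
    manifest_path: Path
    qc: pd.DataFrame


def _analyze_fov(fov: FieldOfView, config: RunConfig):
    """Segment one field of view and compute its per-cell/structure tables."""
    seg = config.segmentation
    primary = subtract_background(fov.primary, seg)
    channels = {"primary": primary}
    if fov.secondary is not None:
        channels["secondary"] = subtract_background(fov.secondary, seg)
    if fov.nuclear is not None:
        channels["nuclear"] = fov.nuclear
    sub = FieldOfView(channels=channels, condition=fov.condition, well=fov.well, site=fov.site)

    cells = segment_cells(sub, seg)
    equalized = equalize_intensity(primary, seg)
    structures = segment_structures(primary, equalized, cells, config.structure_mode, seg)

    pearson = positivity = None
    if sub.secondary is not None:
        pearson = pearson_per_cell(sub, cells)
        positivity = score_structure_positivity(
            sub, cells, structures,
            threshold=config.positivity_threshold,
            dilation_radius=config.dilation_radius,
        )
    profiles = dispersion_profiles(
        sub, cells, structures, min_structure_pixels=config.min_structure_pixels
    )
    n_cells = int(cells.max())
    return pearson, positivity, profiles, n_cells, structures.n_structures


def run_pipeline(config: RunConfig, write: bool = True) -> RunResult:
    """Run simulate/load -> segment -> metrics and write the result bundle.

    Outputs (long-format CSVs with a config-hash metadata header) land under
    ``config.output_dir``; ``run_manifest.json`` lists every file with its
    SHA-256 checksum.
    """
    if config.manifest is not None:
        fovs = load_plate(config.manifest)
        logger.info("loaded %d fields of view from %s", len(fovs), config.manifest)
    else:
        plate = generate_plate(
            config.layout, config.scene, config.overrides, base_seed=config.seed
        )
        fovs = [fov for fov, _ in plate]
        logger.info("simulated %d fields of view", len(fovs))

    pearson_frames, positivity_frames, profile_frames, qc_rows = [], [], [], []
    for fov in fovs:
        try:
            pearson, positivity, profiles, n_cells, n_structures = _analyze_fov(fov, config)
        except Exception as exc:
            raise RuntimeError(
                f"stage 'analyze' failed for (well={fov.well!r}, site={fov.site!r}): {exc}"
            ) from exc
        logger.info(
            "%s/%s/%s: %d cells, %d structures", fov.condition, fov.well, fov.site,
            n_cells, n_structures,
        )
        qc_rows.append(
            {
                "condition": fov.condition,
                "well": fov.well,
                "site": fov.site,
                "n_cells": n_cells,
                "n_structures": n_structures,
                "n_cells_profiled": 0 if profiles.empty else profiles["cell"].nunique(),
            }
        )
        if pearson is not None:
            pearson_frames.append(pearson)
        if positivity is not None:
            positivity_frames.append(positivity)
        profile_frames.append(profiles)

    tables: dict[str, pd.DataFrame] = {}
    qc = pd.DataFrame(qc_rows)
    tables["qc_sites"] = qc

    if pearson_frames:
        pearson_all = pd.concat(pearson_frames, ignore_index=True)
        tables["pearson_cells"] = pearson_all
        if not pearson_all.empty:
            well, cond = aggregate_pearson(pearson_all, pool_sites=config.pool_sites)
            tables["pearson_wells"] = well
            tables["pearson_conditions"] = cond
    if positivity_frames:
        structure_table = pd.concat(positivity_frames, ignore_index=True)
        tables["structures"] = structure_table
        site, cond = positivity_fractions(structure_table)
        tables["positivity_sites"] = site
        tables["positivity_conditions"] = cond
    profiles_all = pd.concat(profile_frames, ignore_index=True)
    tables["dispersion_cells"] = profiles_all
    well_prof, cond_prof = aggregate_dispersion(profiles_all)
    tables["dispersion_wells"] = well_prof
    tables["dispersion_conditions"] = cond_prof

    out = Path(config.output_dir)
    paths: dict[str, Path] = {}
    manifest_path = out / "run_manifest.json"
    if write:
        metadata = {"config_hash": config.config_hash(), "focusq_version": __version__}
        paths = write_results(tables, out, metadata)
        checksums = {
            name: hashlib.sha256(path.read_bytes()).hexdigest()
            for name, path in sorted(paths.items())
        }
        manifest = {
            "config_hash": config.config_hash(),
            "version": __version__,
            "files": {name: {"path": str(p), "sha256": checksums[name]} for name, p in sorted(paths.items())},
        }
        manifest_path.parent.mkdir(parents=True, exist_ok=True)
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return RunResult(tables=tables, paths=paths, manifest_path=manifest_path, qc=qc)
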