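"""Plate-organised image ingest and result-table I/O.

Conventions fixed package-wide: pixel coordinates are 0-based ``(row, column)``,
all distances are in pixel units, and integer pixel types are converted to
float64 on ingest without rescaling.  No intensity normalisation happens at
load time -- background subtraction and equalization are pipeline stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger(__name__)

CHANNEL_ROLES = ("primary", "secondary", "nuclear")


@dataclass
class FieldOfView:
    """A registered set of same-shape 2D channel images from one imaging site.

    Parameters
    ----------
    channels
        Mapping of channel role (``primary``, ``secondary``, ``nuclear``) to a
        2D float array.  ``primary`` is mandatory (the punctate reporter, e.g.
        mScarletI-LC3B); ``secondary`` (immunostained marker) and ``nuclear``
        (Hoechst) are optional.
    condition, well, site
        Plate coordinates of the field of view.
    """

    channels: dict[str, np.ndarray]
    condition: str = ""
    well: str = ""
    site: str = ""

    def __post_init__(self) -> None:
        if "primary" not in self.channels:
            raise ValueError(
                f"FieldOfView {self.key} has no 'primary' channel"
            )
        unknown = set(self.channels) - set(CHANNEL_ROLES)
        if unknown:
            raise ValueError(f"unknown channel roles: {sorted(unknown)}")
        shapes = {role: arr.shape for role, arr in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shape mismatch in {self.key}: {shapes}")
        for role, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {role!r} is not 2D: shape {arr.shape}")
            self.channels[role] = np.asarray(arr, dtype=np.float64)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.condition, self.well, self.site)

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels["primary"].shape

    @property
    def primary(self) -> np.ndarray:
        return self.channels["primary"]

    @property
    def secondary(self) -> np.ndarray | None:
        return self.channels.get("secondary")

    @property
    def nuclear(self) -> np.ndarray | None:
        return self.channels.get("nuclear")


@dataclass
class PlateLayout:
    """Plate structure: which wells belong to which condition, and the sites
    imaged per well.

    ``wells`` maps condition -> list of well ids; ``sites`` maps well id ->
    list of site ids.  Well ids must be unique across conditions so that a
    ``(well, site)`` pair identifies one field of view.
    """

    wells: dict[str, list[str]]
    sites: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.wells:
            raise ValueError("layout must name at least one condition")
        seen: dict[str, str] = {}
        for cond, wlist in self.wells.items():
            if not wlist:
                raise ValueError(f"condition {cond!r} has no wells")
            for w in wlist:
                if w in seen:
                    raise ValueError(
                        f"well {w!r} assigned to both {seen[w]!r} and {cond!r}"
                    )
                seen[w] = cond
        for w in seen:
            site_list = self.sites.get(w, [])
            if not site_list:
                raise ValueError(f"well {w!r} has no sites")
            if len(set(site_list)) != len(site_list):
                raise ValueError(f"duplicate site ids in well {w!r}")

    @classmethod
    def uniform(
        cls,
        conditions: Sequence[str],
        n_wells: int = 3,
        n_sites: int = 1,
    ) -> "PlateLayout":
        """Regular layout: ``n_wells`` wells per condition, ``n_sites`` sites each."""
        wells = {
            c: [f"{c}-W{i + 1}" for i in range(n_wells)] for c in conditions
        }
        sites = {w: [f"s{j + 1}" for j in range(n_sites)] for ws in wells.values() for w in ws}
        return cls(wells=wells, sites=sites)

    def iter_triples(self):
        """Yield (condition, well, site) in deterministic layout order."""
        for cond, wlist in self.wells.items():
            for w in wlist:
                for s in self.sites[w]:
                    yield cond, w, s

    @classmethod
    def from_dict(cls, d: Mapping) -> "PlateLayout":
        wells = {c: list(v) for c, v in d["wells"].items()}
        raw_sites = d.get("sites", 1)
        if isinstance(raw_sites, int):
            sites = {
                w: [f"s{j + 1}" for j in range(raw_sites)]
                for ws in wells.values()
                for w in ws
            }
        elif isinstance(raw_sites, Mapping):
            sites = {w: list(v) for w, v in raw_sites.items()}
        else:  # one site list shared by every well
            sites = {w: list(raw_sites) for ws in wells.values() for w in ws}
        return cls(wells=wells, sites=sites)

    def to_dict(self) -> dict:
        return {"wells": self.wells, "sites": self.sites}


def _read_channel(path: Path, page: int | None = None) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 3:
        arr = arr[0 if page is None else page]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D image, got shape {arr.shape}")
    return np.asarray(arr, dtype=np.float64)


def load_plate(manifest: str | Path, root: str | Path | None = None) -> list[FieldOfView]:
    """Read a plate of multi-channel TIFFs described by a YAML manifest.

    The manifest names the layout and maps each channel role to a filename
    pattern with ``{condition}``, ``{well}`` and ``{site}`` placeholders::

        channels:
          primary: "{condition}/{well}_{site}_lc3b.tif"
          secondary: {pattern: "{condition}/{well}_{site}_ab.tif", optional: true}
        wells:
          untreated: [U1, U2, U3]
          diABZI: [D1, D2, D3]
        sites: [s1, s2]

    A missing primary file raises :class:`FileNotFoundError` naming the
    (condition, well, site) triple; a missing optional channel is skipped.
    """
    manifest = Path(manifest)
    root = Path(root) if root is not None else manifest.parent
    with open(manifest) as fh:
        doc = yaml.safe_load(fh)
    if "channels" not in doc or "primary" not in doc["channels"]:
        raise ValueError("manifest must map a 'primary' channel pattern")
    layout = PlateLayout.from_dict(doc)

    specs: dict[str, tuple[str, bool, int | None]] = {}
    for role, entry in doc["channels"].items():
        if role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel role {role!r} in manifest")
        if isinstance(entry, str):
            specs[role] = (entry, False, None)
        else:
            specs[role] = (entry["pattern"], bool(entry.get("optional", False)), entry.get("page"))

    fovs: list[FieldOfView] = []
    for cond, well, site in layout.iter_triples():
        channels: dict[str, np.ndarray] = {}
        for role, (pattern, optional, page) in specs.items():
            path = root / pattern.format(condition=cond, well=well, site=site)
            if not path.exists():
                if optional:
                    continue
                raise FileNotFoundError(
                    f"missing {role} channel for ({cond}, {well}, {site}): {path}"
                )
            channels[role] = _read_channel(path, page)
        fovs.append(FieldOfView(channels=channels, condition=cond, well=well, site=site))
    return fovs


def save_fov(fov: FieldOfView, directory: str | Path) -> dict[str, Path]:
    """Write each channel of a field of view as a 32-bit float TIFF."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for role, arr in fov.channels.items():
        path = directory / f"{fov.well}_{fov.site}_{role}.tif"
        tifffile.imwrite(path, arr.astype(np.float32))
        out[role] = path
    return out


# ---------------------------------------------------------------------------
# result tables

def write_table(df: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None) -> Path:
    """Write a result table as CSV with a ``# key: value`` metadata header.

    Floats are serialised with ``repr`` so that a read-back reproduces every
    numeric field exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# {k}: {v}" for k, v in (metadata or {}).items()]
    body = df.to_csv(index=False)
    path.write_text("\n".join(lines) + ("\n" if lines else "") + body)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, skipping the metadata header."""
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def read_table_metadata(path: str | Path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            meta[key.strip()] = value.strip()
    return meta


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> dict[str, Path]:
    """Write every result table under ``out`` with a shared metadata header."""
    out = Path(out)
    paths = {}
    for name, df in tables.items():
        if df is None:
            raise ValueError(f"table {name!r} is None")
        paths[name] = write_table(df, out / f"{name}.csv", metadata)
    return paths
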