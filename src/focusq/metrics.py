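"""Quantitative readouts: per-cell Pearson colocalization, per-structure
positivity scoring, and the weighted-centroid radial dispersion profile.

All three follow the same hierarchical aggregation: a statistic per cell, the
median over cells for each imaging site, the median over sites for each well,
and the mean +/- sample SD over (typically three) wells per condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.morphology import dilation, disk

from .io import FieldOfView
from .segmentation import StructureLabelMap

logger = logging.getLogger(__name__)

SITE_COLS = ["condition", "well", "site"]


# ---------------------------------------------------------------------------
# Pearson colocalization

def pearson_per_cell(fov: FieldOfView, cells: np.ndarray) -> pd.DataFrame:
    """Pearson correlation between primary and secondary channels, per cell.

    For each labeled cell, ``r`` is computed over all pixels inside the cell
    mask on the (background-subtracted) intensities.  Cells in which either
    channel is constant carry no correlation and are skipped with a log
    message.

    Returns a frame with columns condition, well, site, cell, r, n_pixels.
    """
    if fov.secondary is None:
        raise ValueError(f"secondary channel required for Pearson in {fov.key}")
    primary, secondary = fov.primary, fov.secondary
    rows = []
    for lbl in range(1, int(cells.max()) + 1):
        sel = cells == lbl
        n = int(sel.sum())
        if n < 2:
            continue
        x = primary[sel]
        y = secondary[sel]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("cell %d in %s has a constant channel; skipped", lbl, fov.key)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append(
            {
                "condition": fov.condition,
                "well": fov.well,
                "site": fov.site,
                "cell": lbl,
                "r": r,
                "n_pixels": n,
            }
        )
    return pd.DataFrame(rows, columns=SITE_COLS + ["cell", "r", "n_pixels"])


def _aggregate_site_values(
    site_values: pd.DataFrame, value_col: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site values -> well median -> condition mean +/- sample SD."""
    well = (
        site_values.groupby(["condition", "well"], sort=True)[value_col]
        .median()
        .reset_index()
    )
    cond_rows = []
    for cond, grp in well.groupby("condition", sort=True):
        vals = grp[value_col].to_numpy(dtype=float)
        mean = float(np.mean(vals))
        if len(vals) >= 2:
            sd = float(np.std(vals, ddof=1))
        else:
            sd = np.nan
            logger.warning(
                "condition %r has %d well(s); SD undefined", cond, len(vals)
            )
        cond_rows.append(
            {"condition": cond, "mean": mean, "sd": sd, "n_wells": len(vals)}
        )
    condition = pd.DataFrame(cond_rows, columns=["condition", "mean", "sd", "n_wells"])
    return well, condition


def aggregate_pearson(
    records: pd.DataFrame, pool_sites: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-cell Pearson records cell -> site -> well -> condition.

    Per site the median over cells; per well the median over site medians
    (or, with ``pool_sites``, the median over all the well's cells pooled);
    per condition the mean and sample SD over wells.

    Returns ``(well_table, condition_table)``.
    """
    if records.empty:
        raise ValueError("no Pearson records to aggregate")
    if pool_sites:
        site = records.rename(columns={"r": "value"})[SITE_COLS + ["value"]]
    else:
        site = (
            records.groupby(SITE_COLS, sort=True)["r"].median().reset_index(name="value")
        )
    well, condition = _aggregate_site_values(site, "value")
    well = well.rename(columns={"value": "pearson_median"})
    return well, condition


# ---------------------------------------------------------------------------
# structure positivity

def score_structure_positivity(
    fov: FieldOfView,
    cells: np.ndarray,
    structures: StructureLabelMap,
    threshold: float = 1.25,
    dilation_radius: int = 5,
) -> pd.DataFrame:
    """Score each structure for secondary-channel positivity.

    The local cellular region of a structure is its morphological dilation by
    a disk of ``dilation_radius``, minus every structure pixel in the image
    and minus background (outside-cell) pixels, restricted to the structure's
    own cell.  ``ratio`` is the mean secondary intensity over the structure
    divided by the mean over that region; a structure is positive when the
    ratio STRICTLY exceeds ``threshold`` (default 1.25).

    Structures whose region is empty after the exclusions are flagged
    unscorable (``scorable = False``) and must be excluded from fractions.
    """
    if fov.secondary is None:
        raise ValueError(f"secondary channel required for positivity in {fov.key}")
    secondary = fov.secondary
    labels = structures.labels
    all_structures = labels > 0
    footprint = disk(dilation_radius)
    rows = []
    for lbl in range(1, int(labels.max()) + 1):
        struct = labels == lbl
        cell_id = structures.cell_ids[lbl]
        region = dilation(struct, footprint)
        region &= cells == cell_id
        region &= ~all_structures
        structure_mean = float(secondary[struct].mean())
        area = int(struct.sum())
        if region.any() and secondary[region].mean() > 0:
            region_mean = float(secondary[region].mean())
            ratio = structure_mean / region_mean
            scorable = True
            positive = ratio > threshold
        else:
            logger.warning(
                "structure %d in %s has an empty/zero region; unscorable", lbl, fov.key
            )
            region_mean, ratio, scorable, positive = np.nan, np.nan, False, False
        rows.append(
            {
                "condition": fov.condition,
                "well": fov.well,
                "site": fov.site,
                "cell": cell_id,
                "structure": lbl,
                "mode": structures.mode,
                "area": area,
                "structure_mean": structure_mean,
                "region_mean": region_mean,
                "ratio": ratio,
                "positive": bool(positive),
                "scorable": bool(scorable),
            }
        )
    return pd.DataFrame(
        rows,
        columns=SITE_COLS
        + [
            "cell",
            "structure",
            "mode",
            "area",
            "structure_mean",
            "region_mean",
            "ratio",
            "positive",
            "scorable",
        ],
    )


def positivity_fractions(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fractions of positive structures and of positive cells, aggregated.

    Per site two statistics: ``fraction_structures_positive`` = positive
    structures / scorable structures, and ``fraction_cells_positive`` = cells
    with at least one positive structure / cells with at least one structure.
    Sites with zero scorable structures are excluded with a warning.
    Aggregation site -> well (median) -> condition (mean +/- SD) as for
    Pearson.

    Returns ``(site_table, condition_table)``; the site table carries both
    statistics in long format (columns statistic, value).
    """
    site_rows = []
    for key, grp in table.groupby(SITE_COLS, sort=True):
        scorable = grp[grp["scorable"]]
        if scorable.empty:
            logger.warning("site %s has no scorable structures; excluded", key)
            continue
        frac_structures = scorable["positive"].mean()
        per_cell = scorable.groupby("cell")["positive"].any()
        frac_cells = per_cell.mean()
        for name, value in (
            ("fraction_structures_positive", frac_structures),
            ("fraction_cells_positive", frac_cells),
        ):
            site_rows.append(dict(zip(SITE_COLS, key)) | {"statistic": name, "value": float(value)})
    site = pd.DataFrame(site_rows, columns=SITE_COLS + ["statistic", "value"])
    cond_frames = []
    for stat, grp in site.groupby("statistic", sort=True):
        _, condition = _aggregate_site_values(grp, "value")
        condition.insert(1, "statistic", stat)
        cond_frames.append(condition)
    condition = (
        pd.concat(cond_frames, ignore_index=True)
        if cond_frames
        else pd.DataFrame(columns=["condition", "statistic", "mean", "sd", "n_wells"])
    )
    return site, condition


# ---------------------------------------------------------------------------
# radial dispersion profile

def dispersion_profile_cell(
    channel: np.ndarray,
    cell_mask: np.ndarray,
    structure_mask: np.ndarray,
    min_structure_pixels: int = 5,
) -> pd.Series | None:
    """Normalized radial intensity profile of one cell around its weighted centroid.

    The centroid is the intensity-weighted mean pixel coordinate of the
    channel within the cell mask.  Every in-cell pixel is assigned the ring
    ``round(d)`` of its Euclidean distance ``d`` to the centroid; a ring's
    value is the mean intensity of its pixels, and the whole profile is
    divided by the mean intensity over the cell mask, so that the pixel-count
    weighted mean of ring values is exactly 1.  Rings with no pixels are
    absent from the index, not zero.

    Cells whose structure mask holds fewer than ``min_structure_pixels``
    nonzero pixels, or whose total intensity is zero, are skipped (``None``).
    """
    in_cell = cell_mask.astype(bool)
    n_struct = int(np.count_nonzero(structure_mask[in_cell]))
    if n_struct < min_structure_pixels:
        return None
    w = channel[in_cell].astype(np.float64)
    total = w.sum()
    if total <= 0:
        logger.warning("cell with zero total intensity; skipped")
        return None
    rr, cc = np.nonzero(in_cell)
    cy = float((w * rr).sum() / total)
    cx = float((w * cc).sum() / total)
    dist = np.hypot(rr - cy, cc - cx)
    ring = np.rint(dist).astype(np.int64)
    counts = np.bincount(ring)
    sums = np.bincount(ring, weights=w)
    present = counts > 0
    values = sums[present] / counts[present]
    values = values / w.mean()
    return pd.Series(values, index=np.nonzero(present)[0], name="value").rename_axis("distance")


def dispersion_profiles(
    fov: FieldOfView,
    cells: np.ndarray,
    structures: StructureLabelMap,
    min_structure_pixels: int = 5,
) -> pd.DataFrame:
    """Cell-level dispersion profiles for every qualifying cell of one site.

    Only cells whose puncta/foci mask has at least ``min_structure_pixels``
    nonzero pixels enter.  Long-format output: condition, well, site, cell,
    distance, value.
    """
    primary = fov.primary
    smask = structures.mask()
    frames = []
    for lbl in range(1, int(cells.max()) + 1):
        profile = dispersion_profile_cell(
            primary, cells == lbl, smask, min_structure_pixels=min_structure_pixels
        )
        if profile is None:
            continue
        df = profile.reset_index()
        df.insert(0, "cell", lbl)
        for col, val in zip(reversed(SITE_COLS), (fov.site, fov.well, fov.condition)):
            df.insert(0, col, val)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=SITE_COLS + ["cell", "distance", "value"])
    return pd.concat(frames, ignore_index=True)


def aggregate_dispersion(
    profiles: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate cell profiles to well and condition level.

    Per well and distance ring: the median over the well's cells that possess
    that ring (no zero padding of short profiles).  Per condition and ring:
    mean +/- sample SD over wells.  Empty wells are dropped with a warning.
    """
    if profiles.empty:
        logger.warning("no dispersion profiles to aggregate")
        empty_w = pd.DataFrame(columns=["condition", "well", "distance", "value"])
        empty_c = pd.DataFrame(columns=["condition", "distance", "mean", "sd", "n_wells"])
        return empty_w, empty_c
    well = (
        profiles.groupby(["condition", "well", "distance"], sort=True)["value"]
        .median()
        .reset_index()
    )
    grouped = well.groupby(["condition", "distance"], sort=True)["value"]
    condition = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n_wells="count").reset_index()
    return well, condition


def profile_peak_stats(profile) -> tuple[float, int, int]:
    """Peak value, peak ring and full-width-at-half-maximum of a profile.

    The peak is the maximum ring value (ties broken toward the smallest
    ring); the width counts the contiguous run of rings around the peak whose
    value is at least half the peak.
    """
    if isinstance(profile, pd.Series):
        values = profile.to_numpy(dtype=float)
        index = profile.index.to_numpy()
    else:
        values = np.asarray(profile, dtype=float)
        index = np.arange(len(values))
    if values.size == 0:
        raise ValueError("empty profile")
    peak_pos = int(np.argmax(values))
    peak_value = float(values[peak_pos])
    half = peak_value / 2.0
    lo = peak_pos
    while lo > 0 and values[lo - 1] >= half:
        lo -= 1
    hi = peak_pos
    while hi < len(values) - 1 and values[hi + 1] >= half:
        hi += 1
    return peak_value, int(index[peak_pos]), hi - lo + 1
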