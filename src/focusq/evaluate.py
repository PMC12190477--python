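"""Evaluation of segmentation output against a synthetic scene's ground truth.

Used by the test-bench side of the package: recall/precision of detected
puncta/foci against planted structure records, and per-cell IoU of the cell
segmentation against planted cell masks.
"""

from __future__ import annotations

import numpy as np

from .segmentation import StructureLabelMap
from .synthetic import GroundTruth


def match_structures(truth: GroundTruth, structures: StructureLabelMap) -> dict:
    """Match planted structures to detected components by their centre pixel.

    A planted structure is recovered when a detected component covers its
    (rounded) centre.  Returns recall, precision (detected components claimed
    by at least one planted centre / all detected), and the planted-record ->
    detected-label mapping (0 = missed).
    """
    labels = structures.labels
    assignment: list[int] = []
    for rec in truth.structure_records:
        r, c = int(round(rec.center[0])), int(round(rec.center[1]))
        assignment.append(int(labels[r, c]))
    n_records = len(truth.structure_records)
    matched = [a for a in assignment if a > 0]
    recall = len(matched) / n_records if n_records else 1.0
    n_detected = structures.n_structures
    precision = len(set(matched)) / n_detected if n_detected else 1.0
    return {"recall": recall, "precision": precision, "assignment": assignment}


def cell_ious(truth: GroundTruth, cells: np.ndarray) -> list[float]:
    """Best-overlap IoU of every planted cell against the detected label map."""
    out = []
    for t in range(1, truth.n_cells + 1):
        tmask = truth.cell_masks == t
        owners, counts = np.unique(cells[tmask], return_counts=True)
        counts = counts[owners > 0]
        owners = owners[owners > 0]
        if owners.size == 0:
            out.append(0.0)
            continue
        best = owners[np.argmax(counts)]
        dmask = cells == best
        inter = np.count_nonzero(tmask & dmask)
        union = np.count_nonzero(tmask | dmask)
        out.append(inter / union)
    return out
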