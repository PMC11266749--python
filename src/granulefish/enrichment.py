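"""Per-cell RNA concentration and germline-founder (P4 vs P1) enrichment.

The concentration of a P blastomere is measured on the single z-slice
centered on its nucleus:

    [P] = (integrated intensity over cell mask / cell area)
        - (integrated intensity over nucleus mask / nucleus area)

The nuclear term serves as the in-cell background control (the nucleus
contains no mature cytoplasmic mRNA), so a uniform offset over the whole
slice cancels exactly.  Enrichment of the germline founder cell is
[P4] / mean([P1]) over a cohort of at least three two-cell-stage P1 cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .imaging_io import CellROI, ImageStack

log = logging.getLogger("granulefish")

__all__ = [
    "ConcentrationRecord",
    "mid_nucleus_slice",
    "cell_concentration",
    "p4_enrichment",
    "stage_concentration",
]


@dataclass
class ConcentrationRecord:
    lineage: str
    concentration: float
    slice_index: int | None
    cell_area_px: int
    nucleus_area_px: int


def mid_nucleus_slice(roi: CellROI) -> int:
    """The z-slice with the largest nucleus cross-section ("centered on the
    nucleus")."""
    if not roi.is_3d:
        raise ValueError("mid_nucleus_slice requires a 3D ROI")
    areas = roi.nucleus_mask.sum(axis=(1, 2))
    if areas.max() == 0:
        raise ValueError("nucleus mask is empty")
    return int(np.argmax(areas))


def cell_concentration(
    slice_image: np.ndarray,
    roi: CellROI,
    slice_index: int | None = None,
) -> ConcentrationRecord:
    """Background-corrected RNA concentration of one cell on one z-slice.

    ``roi`` may be 2D (matching ``slice_image``) or 3D, in which case the
    masks at ``slice_index`` are used.  A negative concentration (nucleus
    brighter than cytoplasm) is returned as-is but logged.
    """
    img = np.asarray(slice_image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("slice_image must be 2D")
    if roi.is_3d:
        if slice_index is None:
            slice_index = mid_nucleus_slice(roi)
        plane = roi.plane(slice_index)
    else:
        plane = roi
    cell, nuc = plane.cell_mask, plane.nucleus_mask
    if cell.shape != img.shape:
        raise ValueError("mask and slice shapes differ")
    a_cell = int(cell.sum())
    a_nuc = int(nuc.sum())
    if a_nuc == 0 or a_cell <= a_nuc:
        raise ValueError("need cell area > nucleus area > 0")
    conc = float(img[cell].sum()) / a_cell - float(img[nuc].sum()) / a_nuc
    if conc < 0:
        log.warning(
            "negative concentration (%.3g) in %s: nucleus brighter than cytoplasm",
            conc,
            plane.lineage,
        )
    return ConcentrationRecord(
        lineage=plane.lineage,
        concentration=conc,
        slice_index=slice_index,
        cell_area_px=a_cell,
        nucleus_area_px=a_nuc,
    )


def stage_concentration(stack: ImageStack, roi: CellROI) -> ConcentrationRecord:
    """Convenience: concentration of a cell from its full stack and 3D ROI,
    measured on the mid-nucleus slice of the raw image."""
    z = mid_nucleus_slice(roi)
    return cell_concentration(stack.astype_float()[z], roi, slice_index=z)


def p4_enrichment(
    conc_p4: ConcentrationRecord | float,
    conc_p1: Sequence[ConcentrationRecord | float],
    min_p1_records: int = 3,
) -> float:
    """Germline-founder enrichment: [P4] divided by the mean [P1].

    Requires at least ``min_p1_records`` P1 measurements; a non-positive
    mean P1 concentration has no meaningful ratio and raises.
    """
    p4 = conc_p4.concentration if isinstance(conc_p4, ConcentrationRecord) else float(conc_p4)
    p1_vals = [
        c.concentration if isinstance(c, ConcentrationRecord) else float(c)
        for c in conc_p1
    ]
    if len(p1_vals) < min_p1_records:
        raise ValueError(
            f"need >= {min_p1_records} P1 concentration records, got {len(p1_vals)}"
        )
    denom = float(np.mean(p1_vals))
    if denom <= 0:
        raise ValueError("mean P1 concentration is non-positive; ratio undefined")
    return p4 / denom
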