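"""Germ-granule segmentation in the marker channel and 3D geometry.

Pipeline: per-slice rolling-ball background subtraction -> 3D Gaussian blur
-> Kapur maximum-entropy threshold -> per-slice distance-transform watershed
to split touching objects -> 3D connected components -> per-granule
measurements.  Each granule's membership region for spot assignment is an
axis-aligned bounding cube: full x/y extents of ``(minor_radius + pad) * 2``
and a z extent of ``major_radius * 2`` (granules are tallest along z).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import pi, sqrt

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .imaging_io import (
    CellROI,
    ImageStack,
    PipelineConfig,
    empty_granule_table,
)
from .spot_detection import subtract_background

log = logging.getLogger("granulefish")

__all__ = [
    "max_entropy_threshold",
    "segment_granules",
    "granule_bounding_cube",
    "cytoplasm_fraction",
    "BoundingCube",
]


# ---------------------------------------------------------------------------
# Kapur maximum-entropy threshold
# ---------------------------------------------------------------------------


def max_entropy_threshold(histogram: np.ndarray) -> int:
    """Kapur maximum-entropy threshold of an intensity histogram.

    Splits the normalized histogram at bin ``t`` (background: bins ``<= t``,
    foreground: bins ``> t``) and returns the ``t`` maximizing the sum of the
    background and foreground Shannon entropies.  Ties break toward the lower
    threshold.  A histogram with fewer than two populated bins cannot be
    split and raises ``ValueError``.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.ndim != 1 or len(hist) < 2:
        raise ValueError("histogram must be a 1D array with >= 2 bins")
    if np.any(hist < 0):
        raise ValueError("histogram counts must be >= 0")
    nonzero = np.flatnonzero(hist)
    if len(nonzero) < 2:
        raise ValueError("histogram has a single populated bin; nothing to separate")
    p = hist / hist.sum()
    plogp = np.where(p > 0, p * np.log(p, where=p > 0, out=np.zeros_like(p)), 0.0)
    P = np.cumsum(p)
    S = np.cumsum(plogp)
    total_S = S[-1]
    # candidate thresholds leave populated bins on both sides (integer
    # logic: between the first and last nonzero bins)
    t_vals = np.arange(len(p) - 1)
    Pb = P[t_vals]
    valid = (t_vals >= nonzero[0]) & (t_vals < nonzero[-1])
    obj = np.full(len(t_vals), -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        Hb = np.log(Pb[valid]) - S[t_vals[valid]] / Pb[valid]
        Hf = np.log1p(-Pb[valid]) - (total_S - S[t_vals[valid]]) / (1.0 - Pb[valid])
    obj[valid] = Hb + Hf
    if not valid.any():
        raise ValueError("histogram cannot be split with mass on both sides")
    # ties (e.g. symmetric histograms) break toward the lower threshold;
    # tolerance absorbs float noise between equivalent formulations
    best = obj.max()
    return int(np.flatnonzero(obj >= best - 1e-9 * (1.0 + abs(best)))[0])


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def _split_touching_per_slice(binary: np.ndarray, min_distance: int) -> np.ndarray:
    """Per-slice binary watershed: split touching objects along the
    in-plane distance-transform ridge (mirrors the 2D binary watershed of
    common image-processing suites)."""
    out = np.zeros_like(binary)
    for z in range(binary.shape[0]):
        plane = binary[z]
        if not plane.any():
            continue
        dist = ndimage.distance_transform_edt(plane)
        peaks = peak_local_max(
            dist, min_distance=min_distance, labels=plane, exclude_border=False
        )
        if len(peaks) == 0:
            out[z] = plane
            continue
        markers = np.zeros(plane.shape, dtype=int)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        ws = watershed(-dist, markers, mask=plane, watershed_line=True)
        out[z] = ws > 0
    return out


def _split_touching_3d(binary: np.ndarray, min_distance: int) -> np.ndarray:
    dist = ndimage.distance_transform_edt(binary)
    peaks = peak_local_max(
        dist, min_distance=min_distance, labels=binary, exclude_border=False
    )
    if len(peaks) == 0:
        return binary
    markers = np.zeros(binary.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    ws = watershed(-dist, markers, mask=binary, watershed_line=True)
    return ws > 0


def _refine_component_levels(smooth: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Re-threshold each component at its local mid-level.

    A global entropy threshold identifies granules but sits near the top of
    the background class, so every object carries a sub-voxel to ~1-voxel
    dilation shell whose thickness depends on contrast.  Re-cutting each
    component at the midpoint between its interior plateau (median over the
    eroded core, the voxels least contaminated by the edge ramp) and its
    local background (median of a surrounding shell) places the boundary at
    the half-edge of the blurred object, where the rendered and measured
    extents coincide.  Refinement only operates within each component's
    1-voxel dilation, so it cannot merge neighbours.
    """
    out = np.zeros_like(labels)
    next_id = 1
    for prop in regionprops(labels):
        zmin, ymin, xmin, zmax, ymax, xmax = prop.bbox
        pad = 3
        z0, y0, x0 = max(0, zmin - pad), max(0, ymin - pad), max(0, xmin - pad)
        z1 = min(labels.shape[0], zmax + pad)
        y1 = min(labels.shape[1], ymax + pad)
        x1 = min(labels.shape[2], xmax + pad)
        win = smooth[z0:z1, y0:y1, x0:x1]
        mask = labels[z0:z1, y0:y1, x0:x1] == prop.label
        shell = ndimage.binary_dilation(mask, iterations=3) & ~ndimage.binary_dilation(
            mask, iterations=1
        )
        local_bg = float(np.median(win[shell])) if shell.any() else 0.0
        core = ndimage.binary_erosion(mask)
        plateau = float(np.median(win[core] if core.any() else win[mask]))
        level = 0.5 * (local_bg + plateau)
        allowed = ndimage.binary_dilation(mask, iterations=1)
        refined = allowed & (win >= level)
        if not refined.any():
            refined = mask  # degenerate contrast: keep the original
        # keep the piece containing the component's brightest voxel
        comp, _ = ndimage.label(refined)
        flat_max = np.argmax(np.where(mask, win, -np.inf))
        keep = comp[np.unravel_index(flat_max, win.shape)]
        if keep == 0:
            refined = mask
        else:
            refined = comp == keep
        out[z0:z1, y0:y1, x0:x1][refined] = next_id
        next_id += 1
    return cc_label(out > 0, connectivity=1)


def segment_granules(
    stack: ImageStack, config: PipelineConfig
) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment granules in the marker channel.

    Returns ``(label_volume, granule_table)``.  The granule table columns are
    ``granule_id, z, y, x, minor_radius_px, major_radius_px, volume_vox,
    half_z, half_y, half_x`` where the half-extents are the bounding cube
    (pad from config).  ``minor_radius_px`` is the equivalent-circle radius
    of the largest-area z-slice; ``major_radius_px`` is the larger of the z
    half-extent and half the longest principal axis.  Components smaller than
    ``config.min_granule_volume_vox`` are suppressed as noise.
    """
    bgsub = subtract_background(stack, config.background_radius_px)
    arr = bgsub.astype_float()
    smooth = ndimage.gaussian_filter(arr, sigma=config.blur_sigma)

    vmax = float(smooth.max())
    if vmax <= 0:
        log.info("marker channel is empty after background subtraction")
        return np.zeros(arr.shape, dtype=int), empty_granule_table()
    hist, edges = np.histogram(smooth, bins=256, range=(0.0, vmax))
    try:
        t_bin = max_entropy_threshold(hist)
        thr = float(edges[t_bin + 1])
    except ValueError:
        if config.manual_granule_threshold is None:
            raise
        log.warning("max-entropy threshold failed; using manual fallback")
        thr = float(config.manual_granule_threshold)

    # an entropy split is meaningless on a granule-free image: the threshold
    # must also clear the robust noise floor of the blurred stack
    med = float(np.median(smooth))
    mad = float(np.median(np.abs(smooth - med)))
    floor = med + config.granule_noise_floor_k * mad
    thr = max(thr, floor)

    binary = smooth > thr
    if not binary.any():
        return np.zeros(arr.shape, dtype=int), empty_granule_table()

    if config.watershed_3d:
        split = _split_touching_3d(binary, config.watershed_min_distance_px)
    else:
        split = _split_touching_per_slice(binary, config.watershed_min_distance_px)

    labels = cc_label(split, connectivity=1)
    if labels.max() == 0:
        return labels, empty_granule_table()

    # suppress sub-minimum shards before boundary refinement, which can
    # only grow a component within its 1-voxel dilation
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < config.min_granule_volume_vox)
    if len(small):
        labels[np.isin(labels, small)] = 0
        labels = cc_label(labels > 0, connectivity=1)
        if labels.max() == 0:
            return labels, empty_granule_table()

    if config.refine_granule_boundaries:
        labels = _refine_component_levels(smooth, labels)
        if labels.max() == 0:
            return labels, empty_granule_table()

    rows: list[dict] = []
    props = regionprops(labels)
    for prop in props:
        vol = int(prop.area)
        if vol < config.min_granule_volume_vox:
            labels[labels == prop.label] = 0
            continue
        zmin, ymin, xmin, zmax, ymax, xmax = prop.bbox
        z_half = (zmax - zmin) / 2.0
        sub = labels[zmin:zmax, ymin:ymax, xmin:xmax] == prop.label
        slice_areas = sub.sum(axis=(1, 2))
        area_max = int(slice_areas.max())
        minor = sqrt(area_max / pi)
        try:
            principal_half = float(prop.axis_major_length) / 2.0
        except Exception:
            principal_half = 0.0
        major = max(z_half, principal_half, minor)
        cz, cy, cx = prop.centroid
        rows.append(
            {
                "z": cz,
                "y": cy,
                "x": cx,
                "minor_radius_px": minor,
                "major_radius_px": major,
                "volume_vox": vol,
            }
        )
    if not rows:
        return labels, empty_granule_table()
    table = pd.DataFrame(rows).sort_values(["z", "y", "x"]).reset_index(drop=True)
    table.insert(0, "granule_id", np.arange(len(table)))
    cubes = [
        granule_bounding_cube(row, config.cube_pad_px) for row in table.itertuples()
    ]
    table["half_z"] = [c.half_z for c in cubes]
    table["half_y"] = [c.half_y for c in cubes]
    table["half_x"] = [c.half_x for c in cubes]

    # relabel the volume to match sorted granule ids
    relabeled = np.zeros_like(labels)
    centroids = {
        (round(p.centroid[0], 6), round(p.centroid[1], 6), round(p.centroid[2], 6)): p.label
        for p in props
        if p.area >= config.min_granule_volume_vox
    }
    for row in table.itertuples():
        key = (round(row.z, 6), round(row.y, 6), round(row.x, 6))
        old = centroids[key]
        relabeled[labels == old] = row.granule_id + 1
    return relabeled, table


# ---------------------------------------------------------------------------
# bounding cube & cytoplasm fraction
# ---------------------------------------------------------------------------


@dataclass
class BoundingCube:
    """Axis-aligned membership box for one granule.

    Full extents: x = y = ``(minor_radius + pad) * 2``, z =
    ``major_radius * 2``.  The boundary test is inclusive on every axis.
    """

    granule_id: int
    center_z: float
    center_y: float
    center_x: float
    half_z: float
    half_y: float
    half_x: float

    def contains(self, z: float, y: float, x: float) -> bool:
        return (
            abs(z - self.center_z) <= self.half_z
            and abs(y - self.center_y) <= self.half_y
            and abs(x - self.center_x) <= self.half_x
        )

    @property
    def full_extents(self) -> tuple[float, float, float]:
        return (2 * self.half_z, 2 * self.half_y, 2 * self.half_x)


def granule_bounding_cube(granule, cube_pad_px: float = 2) -> BoundingCube:
    """Build a granule's bounding cube from its radii.

    Accepts a granule-table row (itertuples/Series/dict) carrying
    ``granule_id, z, y, x, minor_radius_px, major_radius_px``.
    """
    get = (
        granule.get
        if hasattr(granule, "get")
        else lambda k: getattr(granule, k)
    )
    minor = float(get("minor_radius_px"))
    major = float(get("major_radius_px"))
    if minor <= 0 or major < minor:
        raise ValueError("require major_radius >= minor_radius > 0")
    return BoundingCube(
        granule_id=int(get("granule_id")),
        center_z=float(get("z")),
        center_y=float(get("y")),
        center_x=float(get("x")),
        half_z=major,
        half_y=minor + cube_pad_px,
        half_x=minor + cube_pad_px,
    )


def cubes_from_table(granules: pd.DataFrame, cube_pad_px: float = 2) -> list[BoundingCube]:
    return [granule_bounding_cube(row, cube_pad_px) for row in granules.itertuples()]


def cytoplasm_fraction(granules: pd.DataFrame, roi: CellROI) -> float:
    """Percentage of the cytoplasmic volume occupied by granules.

    ``sum(volume_vox) / (cell_volume - nucleus_volume) * 100``; requires 3D
    masks.
    """
    if not roi.is_3d:
        raise ValueError("cytoplasm_fraction requires 3D cell/nucleus masks")
    cyto = roi.cell_volume_vox - roi.nucleus_volume_vox
    if cyto <= 0:
        raise ValueError("nucleus volume must be smaller than cell volume")
    total = float(granules["volume_vox"].sum()) if len(granules) else 0.0
    return 100.0 * total / cyto
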