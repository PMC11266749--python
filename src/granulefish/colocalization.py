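"""Spot/cluster-to-granule assignment and RNA-RNA colocalization.

A spot belongs to a granule when its (z, y, x) center falls inside the
granule's bounding cube (inclusive on all three axes); with several
candidate cubes, the granule with the nearest centroid wins.  Two clusters
of different RNA species are colocalized when they agree within ALL of the
distance tolerances (default 2 px in x and y, 2 slices in z), matched
one-to-one by nearest Euclidean distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .granule_segmentation import BoundingCube, cubes_from_table, cytoplasm_fraction
from .imaging_io import CellROI

log = logging.getLogger("granulefish")

__all__ = [
    "spot_in_granule",
    "assign_spots_to_granules",
    "pct_molecules_in_granules",
    "cluster_colocalization",
    "granule_content_summary",
    "ColocResult",
    "colocalization_report",
]


def _as_cubes(cubes) -> list[BoundingCube]:
    if isinstance(cubes, pd.DataFrame):
        return cubes_from_table(cubes)
    return list(cubes)


def spot_in_granule(spot, cubes) -> int | None:
    """Return the granule id whose cube contains the spot center, or None.

    ``spot`` is anything with z/y/x attributes or keys.  With multiple
    containing cubes the nearest granule centroid wins; exact ties go to the
    lower granule id.
    """
    get = spot.get if hasattr(spot, "get") else lambda k: getattr(spot, k)
    z, y, x = float(get("z")), float(get("y")), float(get("x"))
    best: tuple[float, int] | None = None
    for cube in _as_cubes(cubes):
        if cube.contains(z, y, x):
            d2 = (
                (z - cube.center_z) ** 2
                + (y - cube.center_y) ** 2
                + (x - cube.center_x) ** 2
            )
            cand = (d2, cube.granule_id)
            if best is None or cand < best:
                best = cand
    return None if best is None else best[1]


def assign_spots_to_granules(spots: pd.DataFrame, cubes) -> pd.DataFrame:
    """Fill the ``granule_id`` column of a spot table (NA = outside)."""
    cubes = _as_cubes(cubes)
    out = spots.copy()
    ids: list = []
    for row in out.itertuples():
        gid = spot_in_granule(row, cubes)
        ids.append(pd.NA if gid is None else gid)
    out["granule_id"] = pd.array(ids, dtype="Int64")
    return out


def pct_molecules_in_granules(spots: pd.DataFrame, cubes=None) -> float:
    """Molecule-weighted percentage of RNA inside granules.

    ``sum(n_molecules over in-granule spots) / sum(n_molecules) * 100``.
    When ``cubes`` is given the assignment is (re)computed first; otherwise
    the table's ``granule_id`` column is used as-is.
    """
    if len(spots) == 0:
        raise ValueError("empty spot table: percentage undefined")
    if spots["n_molecules"].isna().any():
        raise ValueError("assign molecule counts before computing percentages")
    df = assign_spots_to_granules(spots, cubes) if cubes is not None else spots
    n = df["n_molecules"].astype(int)
    inside = df["granule_id"].notna()
    return 100.0 * int(n[inside].sum()) / int(n.sum())


# ---------------------------------------------------------------------------
# cluster-cluster colocalization
# ---------------------------------------------------------------------------


def cluster_colocalization(
    clusters_a: pd.DataFrame,
    clusters_b: pd.DataFrame,
    tol_xy_px: float = 2,
    tol_z_slices: float = 2,
) -> tuple[pd.DataFrame, float]:
    """One-to-one nearest matching of clusters within all axis tolerances.

    A pair (a, b) is a candidate iff |dx| <= tol_xy, |dy| <= tol_xy and
    |dz| <= tol_z simultaneously.  Candidates are accepted greedily in order
    of Euclidean distance (ties by a-then-b id), each cluster matching at
    most once.  Returns ``(pairs, pct_a_not_colocalized)`` where ``pairs``
    has columns (a_id, b_id, distance).
    """
    a = clusters_a[clusters_a["is_cluster"].astype(bool)] if "is_cluster" in clusters_a else clusters_a
    b = clusters_b[clusters_b["is_cluster"].astype(bool)] if "is_cluster" in clusters_b else clusters_b
    pairs_cols = ["a_id", "b_id", "distance"]
    if len(a) == 0:
        return pd.DataFrame(columns=pairs_cols), float("nan")
    if len(b) == 0:
        return pd.DataFrame(columns=pairs_cols), 100.0

    az = a["z"].to_numpy(float)[:, None]
    ay = a["y"].to_numpy(float)[:, None]
    ax = a["x"].to_numpy(float)[:, None]
    bz = b["z"].to_numpy(float)[None, :]
    by = b["y"].to_numpy(float)[None, :]
    bx = b["x"].to_numpy(float)[None, :]
    dz, dy, dx = np.abs(az - bz), np.abs(ay - by), np.abs(ax - bx)
    ok = (dz <= tol_z_slices) & (dy <= tol_xy_px) & (dx <= tol_xy_px)
    dist = np.sqrt(dz**2 + dy**2 + dx**2)

    a_ids = a["spot_id"].to_numpy() if "spot_id" in a else np.arange(len(a))
    b_ids = b["spot_id"].to_numpy() if "spot_id" in b else np.arange(len(b))
    cand = [
        (dist[i, j], a_ids[i], b_ids[j], i, j)
        for i, j in zip(*np.nonzero(ok))
    ]
    cand.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []
    for d, aid, bid, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        rows.append({"a_id": aid, "b_id": bid, "distance": float(d)})
    pairs = pd.DataFrame(rows, columns=pairs_cols)
    pct_not = 100.0 * (len(a) - len(pairs)) / len(a)
    return pairs, pct_not


def granule_content_summary(
    granules: pd.DataFrame,
    clusters_a: pd.DataFrame,
    clusters_b: pd.DataFrame,
    cubes=None,
) -> dict:
    """Partition granules by RNA content: A-only, B-only, both, neither.

    Counts sum to the total number of granules; percentages sum to 100.
    """
    cubes = _as_cubes(cubes if cubes is not None else granules)
    a = clusters_a[clusters_a["is_cluster"].astype(bool)] if "is_cluster" in clusters_a else clusters_a
    b = clusters_b[clusters_b["is_cluster"].astype(bool)] if "is_cluster" in clusters_b else clusters_b
    with_a = {gid for row in a.itertuples() if (gid := spot_in_granule(row, cubes)) is not None}
    with_b = {gid for row in b.itertuples() if (gid := spot_in_granule(row, cubes)) is not None}
    all_ids = set(granules["granule_id"].astype(int))
    both = len(all_ids & with_a & with_b)
    a_only = len((all_ids & with_a) - with_b)
    b_only = len((all_ids & with_b) - with_a)
    neither = len(all_ids) - both - a_only - b_only
    total = max(len(all_ids), 1)
    counts = {"a_only": a_only, "b_only": b_only, "both": both, "neither": neither}
    pct = {k: 100.0 * v / total for k, v in counts.items()}
    return {"counts": counts, "percentages": pct, "n_granules": len(all_ids)}


# ---------------------------------------------------------------------------
# per-cell summary
# ---------------------------------------------------------------------------


@dataclass
class ColocResult:
    """Per-cell colocalization summary.

    ``enrichment_above_baseline`` subtracts the percentage of cytoplasm
    occupied by granules (the well-translated-control baseline) from the
    percentage of molecules in granules; transcripts that are neither
    enriched nor excluded score near zero.
    """

    pct_molecules_in_granules: float
    pct_molecules_in_clusters: float
    pct_in_clusters_inside_granules: float
    pct_in_clusters_outside_granules: float
    granule_cytoplasm_pct: float | None = None
    enrichment_above_baseline: float | None = None


def colocalization_report(
    spots: pd.DataFrame,
    granules: pd.DataFrame,
    roi: CellROI | None = None,
    cube_pad_px: float = 2,
) -> ColocResult:
    """Compute the per-cell granule/cluster percentages for one spot table."""
    cubes = cubes_from_table(granules, cube_pad_px)
    df = assign_spots_to_granules(spots, cubes)
    n = df["n_molecules"].astype(int)
    clusters = df["is_cluster"].astype(bool)
    inside = df["granule_id"].notna()
    total = int(n.sum())
    if total == 0:
        raise ValueError("no molecules in spot table")
    pct_gran = 100.0 * int(n[inside].sum()) / total
    pct_clust = 100.0 * int(n[clusters].sum()) / total
    n_in = int(n[inside].sum())
    n_out = total - n_in
    pct_in_clusters_inside = (
        100.0 * int(n[inside & clusters].sum()) / n_in if n_in else 0.0
    )
    pct_in_clusters_outside = (
        100.0 * int(n[~inside & clusters].sum()) / n_out if n_out else 0.0
    )
    cyto_pct = None
    enrich = None
    if roi is not None and roi.is_3d:
        cyto_pct = cytoplasm_fraction(granules, roi)
        enrich = pct_gran - cyto_pct
    return ColocResult(
        pct_molecules_in_granules=pct_gran,
        pct_molecules_in_clusters=pct_clust,
        pct_in_clusters_inside_granules=pct_in_clusters_inside,
        pct_in_clusters_outside_granules=pct_in_clusters_outside,
        granule_cytoplasm_pct=cyto_pct,
        enrichment_above_baseline=enrich,
    )
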