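"""Single-molecule intensity calibration and molecule-count assignment.

Somatic blastomeres contain almost exclusively single transcripts, so the
median integrated intensity of somatic spots defines the photon budget of
one mRNA molecule.  Each focus is then binned to its nearest integer
molecule count (floor at one, half-integer ratios round up); foci holding at
least ``cluster_min_molecules`` (default 4) molecules within one
diffraction-limited spot are flagged as clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging_io import SOMATIC_LINEAGES

log = logging.getLogger("granulefish")

__all__ = [
    "CalibrationResult",
    "calibrate_unit_intensity",
    "assign_molecule_counts",
    "molecule_count_summary",
    "MoleculeSummary",
]


@dataclass
class CalibrationResult:
    """Outcome of single-molecule intensity calibration.

    ``unit_intensity`` is the median somatic integrated intensity;
    ``dispersion`` is the median absolute deviation (MAD) of that
    distribution — a MAD/median ratio above ~0.5 signals a poorly calibrated
    imaging session.
    """

    unit_intensity: float
    n_spots_used: int
    source_cells: tuple[str, ...]
    dispersion: float

    @property
    def relative_dispersion(self) -> float:
        return self.dispersion / self.unit_intensity if self.unit_intensity else np.inf


def calibrate_unit_intensity(
    spots: pd.DataFrame,
    somatic_lineages: tuple[str, ...] = SOMATIC_LINEAGES,
    min_spots: int = 50,
    dispersion_warn: float = 0.5,
) -> CalibrationResult:
    """Median-of-somatic-intensities single-molecule calibration.

    Raises when fewer than ``min_spots`` somatic spots are available — the
    remedy is imaging more somatic fields of view, not lowering the minimum.
    """
    sel = spots[spots["lineage"].isin(somatic_lineages)]
    if len(sel) == 0:
        raise ValueError(
            f"no spots from somatic lineages {somatic_lineages}; cannot calibrate"
        )
    if len(sel) < min_spots:
        raise ValueError(
            f"only {len(sel)} somatic spots (< {min_spots}); acquire more somatic "
            "fields of view before calibrating"
        )
    intens = sel["intensity"].to_numpy(dtype=float)
    unit = float(np.median(intens))
    if unit <= 0:
        raise ValueError("median somatic intensity is non-positive")
    mad = float(np.median(np.abs(intens - unit)))
    if mad / unit > dispersion_warn:
        log.warning(
            "somatic intensity MAD/median = %.2f > %.2f: calibration may be poor",
            mad / unit,
            dispersion_warn,
        )
    return CalibrationResult(
        unit_intensity=unit,
        n_spots_used=int(len(sel)),
        source_cells=tuple(sorted(set(sel["lineage"]))),
        dispersion=mad,
    )


def assign_molecule_counts(
    spots: pd.DataFrame,
    unit_intensity: float | CalibrationResult,
    cluster_min_molecules: int = 4,
) -> pd.DataFrame:
    """Bin integrated intensities into molecule counts.

    ``n_molecules = max(1, round_half_up(intensity / unit))``; a focus with
    ``n_molecules >= cluster_min_molecules`` is a cluster.  Returns a copy.
    """
    unit = (
        unit_intensity.unit_intensity
        if isinstance(unit_intensity, CalibrationResult)
        else float(unit_intensity)
    )
    if unit <= 0:
        raise ValueError("unit_intensity must be > 0")
    out = spots.copy()
    ratio = out["intensity"].to_numpy(dtype=float) / unit
    n = np.maximum(1, np.floor(ratio + 0.5).astype(int))  # half-up tie rule
    out["n_molecules"] = pd.array(n, dtype="Int64")
    out["is_cluster"] = n >= cluster_min_molecules
    return out


@dataclass
class MoleculeSummary:
    per_cell: pd.DataFrame
    total_molecules: int
    pct_molecules_in_clusters: float
    max_cluster_size: int


def molecule_count_summary(spots: pd.DataFrame) -> MoleculeSummary:
    """Per-cell molecule totals, molecule-weighted % in clusters, and the
    largest cluster copy number.

    ``% in clusters = sum(n over cluster foci) / sum(n over all foci) * 100``.
    An empty table yields zero totals and 0 % in clusters.
    """
    cols = ["lineage", "n_spots", "n_molecules", "molecules_in_clusters",
            "pct_in_clusters", "max_cluster_size"]
    if len(spots) == 0:
        return MoleculeSummary(pd.DataFrame(columns=cols), 0, 0.0, 0)
    if spots["n_molecules"].isna().any():
        raise ValueError("molecule counts must be assigned before summarising")
    df = spots.copy()
    df["n_molecules"] = df["n_molecules"].astype(int)
    df["is_cluster"] = df["is_cluster"].astype(bool)

    def _cell(group: pd.DataFrame) -> pd.Series:
        n_all = int(group["n_molecules"].sum())
        n_clust = int(group.loc[group["is_cluster"], "n_molecules"].sum())
        return pd.Series(
            {
                "n_spots": len(group),
                "n_molecules": n_all,
                "molecules_in_clusters": n_clust,
                "pct_in_clusters": 100.0 * n_clust / n_all if n_all else 0.0,
                "max_cluster_size": int(group["n_molecules"].max()),
            }
        )

    per_cell = (
        df.groupby("lineage", sort=True).apply(_cell, include_groups=False).reset_index()
    )
    total = int(df["n_molecules"].sum())
    in_clusters = int(df.loc[df["is_cluster"], "n_molecules"].sum())
    pct = 100.0 * in_clusters / total if total else 0.0
    return MoleculeSummary(per_cell, total, pct, int(df["n_molecules"].max()))
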