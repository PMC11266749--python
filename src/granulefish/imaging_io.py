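"""Image/table I/O, configuration and the shared coordinate conventions.

Conventions obeyed by every module in this package:

* Axis order is ``(z, y, x)`` with 0-based voxel indices.
* Spot and granule positions are fractional **pixel** units in x/y and
  fractional **slice** units in z.  Distance thresholds are likewise mixed
  units (pixels in-plane, slices axially); physical pixel sizes are carried
  as metadata but never used for thresholds.
* Tables are plain CSV files with a fixed, documented column order.
"""

from __future__ import annotations

import logging
import sys
import warnings
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

log = logging.getLogger("granulefish")

__all__ = [
    "Lineage",
    "SOMATIC_LINEAGES",
    "ImageStack",
    "CellROI",
    "PipelineConfig",
    "SPOT_COLUMNS",
    "GRANULE_COLUMNS",
    "SCREEN_COLUMNS",
    "read_stack",
    "write_stack",
    "read_table",
    "write_table",
    "setup_logging",
    "round_half_up",
]


def setup_logging(level: str = "INFO") -> None:
    """Configure structured logging to stderr (idempotent)."""
    root = logging.getLogger("granulefish")
    if not root.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        root.addHandler(handler)
    root.setLevel(level.upper())


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (0.5 -> 1)."""
    return int(np.floor(x + 0.5))


class Lineage(str, Enum):
    """Cell identity labels for the germline (P1-P4) and somatic blastomeres."""

    P1 = "P1"
    P2 = "P2"
    P3 = "P3"
    P4 = "P4"
    SOMATIC = "somatic"


SOMATIC_LINEAGES = (Lineage.SOMATIC.value,)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class ImageStack:
    """A 3D fluorescence image in (z, y, x) order with voxel geometry.

    Parameters
    ----------
    voxels
        3D array, axis order (z, y, x).  dtype is preserved as given.
    pixel_size_xy
        In-plane pixel pitch in nanometres.
    z_step
        Axial slice spacing in nanometres.
    channel_name
        Free-text channel label (e.g. the probe or marker name).
    """

    voxels: np.ndarray
    pixel_size_xy: float = 100.0
    z_step: float = 300.0
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(
                f"ImageStack requires a 3D (z, y, x) array, got ndim={self.voxels.ndim}"
            )
        if min(self.voxels.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got {self.voxels.shape}")
        if not np.issubdtype(self.voxels.dtype, np.number):
            raise ValueError(f"non-numeric voxel data ({self.voxels.dtype})")
        if self.pixel_size_xy <= 0 or self.z_step <= 0:
            raise ValueError("pixel_size_xy and z_step must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def validate(self) -> None:
        """Check that voxel values are finite and non-negative."""
        vals = np.asarray(self.voxels, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("voxel values must be finite")
        if vals.min() < 0:
            raise ValueError("voxel values must be >= 0")

    def astype_float(self) -> np.ndarray:
        return np.asarray(self.voxels, dtype=np.float64)


@dataclass
class CellROI:
    """Cell and nucleus masks for one blastomere, plus its lineage label.

    Masks may be 3D (matching an :class:`ImageStack`) or a single 2D plane.
    The nucleus mask must be contained in the cell mask.
    """

    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    lineage: str = Lineage.SOMATIC.value

    def __post_init__(self) -> None:
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        self.nucleus_mask = np.asarray(self.nucleus_mask, dtype=bool)
        if isinstance(self.lineage, Lineage):
            self.lineage = self.lineage.value
        if self.lineage not in {m.value for m in Lineage}:
            raise ValueError(f"unknown lineage label {self.lineage!r}")
        if self.cell_mask.shape != self.nucleus_mask.shape:
            raise ValueError("cell and nucleus masks must share a shape")
        if np.any(self.nucleus_mask & ~self.cell_mask):
            raise ValueError("nucleus mask must be contained in the cell mask")

    @property
    def is_3d(self) -> bool:
        return self.cell_mask.ndim == 3

    @property
    def cell_volume_vox(self) -> int:
        return int(self.cell_mask.sum())

    @property
    def nucleus_volume_vox(self) -> int:
        return int(self.nucleus_mask.sum())

    def cell_area_px(self, z: int | None = None) -> int:
        mask = self.cell_mask if not self.is_3d else self.cell_mask[z]
        return int(mask.sum())

    def nucleus_area_px(self, z: int | None = None) -> int:
        mask = self.nucleus_mask if not self.is_3d else self.nucleus_mask[z]
        return int(mask.sum())

    def plane(self, z: int) -> "CellROI":
        """Extract the 2D ROI at slice ``z`` from a 3D ROI."""
        if not self.is_3d:
            raise ValueError("plane() requires a 3D ROI")
        return CellROI(self.cell_mask[z], self.nucleus_mask[z], self.lineage)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All tunable analysis constants, with the standard protocol values as
    defaults.

    Lengths are pixels in x/y and slices in z throughout.
    """

    # background subtraction (rolling-ball radius, per z-slice)
    background_radius_px: int = 50
    # pre-segmentation Gaussian blur
    blur_sigma: float = 1.0
    # nominal diffraction-limited spot size
    psf_width_nm: float = 150.0
    # Gaussian-mask fitting sigmas (in pixel / slice units)
    psf_sigma_xy_px: float = 1.0
    psf_sigma_z_slices: float = 1.0
    # spot detection
    detect_threshold: float | None = None  # None -> automatic (median + k*MAD)
    auto_threshold_k: float = 8.0
    min_separation_px: int = 1
    merge_radius_px: float = 1.0
    # molecule binning
    cluster_min_molecules: int = 4
    calibration_min_spots: int = 50
    calibration_dispersion_warn: float = 0.5
    # cluster-cluster colocalization tolerances
    coloc_tol_xy_px: int = 2
    coloc_tol_z_slices: int = 2
    # granule bounding-cube padding
    cube_pad_px: int = 2
    # granule segmentation
    min_granule_volume_vox: int = 4
    granule_noise_floor_k: float = 8.0
    refine_granule_boundaries: bool = True
    manual_granule_threshold: float | None = None
    watershed_3d: bool = False
    watershed_min_distance_px: int = 3
    # enrichment
    min_p1_records: int = 3
    # randomness
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = {
            "background_radius_px": self.background_radius_px,
            "blur_sigma": self.blur_sigma,
            "psf_width_nm": self.psf_width_nm,
            "psf_sigma_xy_px": self.psf_sigma_xy_px,
            "psf_sigma_z_slices": self.psf_sigma_z_slices,
            "coloc_tol_xy_px": self.coloc_tol_xy_px,
            "coloc_tol_z_slices": self.coloc_tol_z_slices,
            "cube_pad_px": self.cube_pad_px,
            "min_separation_px": self.min_separation_px,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if self.cluster_min_molecules < 2:
            raise ValueError("cluster_min_molecules must be >= 2")
        if self.detect_threshold is not None and self.detect_threshold <= 0:
            raise ValueError("detect_threshold must be > 0 when set")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# Stack I/O
# ---------------------------------------------------------------------------


def read_stack(
    path: str | Path,
    *,
    default_pixel_size_xy: float = 100.0,
    default_z_step: float = 300.0,
    channel_name: str = "",
) -> ImageStack:
    """Read a TIFF/OME-TIFF z-stack into an :class:`ImageStack`.

    Pixel sizes are taken from the file's resolution tags when present and
    otherwise fall back to the supplied defaults.  A 2D image is promoted to
    a single-slice stack with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image stack: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            px_xy = _pixel_size_from_tags(tif)
            z_step = _z_step_from_tags(tif)
    except FileNotFoundError:
        raise
    except Exception as exc:  # truncated / malformed file
        raise OSError(f"could not read TIFF stack {path}: {exc}") from exc
    if arr.ndim == 2:
        warnings.warn(
            f"{path} holds a single 2D plane; promoting to a 1-slice stack",
            stacklevel=2,
        )
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2D/3D grayscale image, got ndim={arr.ndim}")
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{path}: non-numeric pixel data ({arr.dtype})")
    return ImageStack(
        voxels=arr,
        pixel_size_xy=px_xy if px_xy else default_pixel_size_xy,
        z_step=z_step if z_step else default_z_step,
        channel_name=channel_name,
    )


def _pixel_size_from_tags(tif: "tifffile.TiffFile") -> float | None:
    """Return the x pixel pitch in nm from TIFF resolution tags, or None."""
    try:
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if xres is None:
            return None
        num, den = xres.value
        if num == 0:
            return None
        pixels_per_unit = num / den
        unit_value = getattr(unit, "value", None)
        unit_nm = {2: 2.54e7, 3: 1.0e7}.get(int(unit_value) if unit_value else 0)
        if unit_nm is None:
            return None
        return unit_nm / pixels_per_unit
    except Exception:
        return None


def _z_step_from_tags(tif: "tifffile.TiffFile") -> float | None:
    """Return the z spacing in nm from ImageJ metadata, or None."""
    try:
        meta = tif.imagej_metadata or {}
        spacing = meta.get("spacing")
        unit = (meta.get("unit") or "").lower()
        if spacing is None:
            return None
        scale = {"um": 1e3, "micron": 1e3, "µm": 1e3, "nm": 1.0}.get(unit)
        if scale is None:
            return None
        return float(spacing) * scale
    except Exception:
        return None


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as an ImageJ-compatible TIFF.

    The voxel dtype is preserved so that write-then-read round-trips are
    voxel-identical.
    """
    path = Path(path)
    px_per_cm = 1.0e7 / stack.pixel_size_xy
    data = stack.voxels
    if data.dtype == np.float64:
        data = data.astype(np.float32)  # ImageJ TIFF has no float64
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        metadata={"spacing": stack.z_step / 1e3, "unit": "um", "axes": "ZYX"},
    )


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

SPOT_COLUMNS = [
    "spot_id",
    "z",
    "y",
    "x",
    "intensity",
    "residual",
    "lineage",
    "n_molecules",
    "is_cluster",
    "granule_id",
]

GRANULE_COLUMNS = [
    "granule_id",
    "z",
    "y",
    "x",
    "minor_radius_px",
    "major_radius_px",
    "volume_vox",
    "half_z",
    "half_y",
    "half_x",
]

SCREEN_COLUMNS = [
    "transcript_id",
    "foci_P1",
    "foci_P2",
    "foci_P3",
    "foci_P4",
    "pgc_pattern",
    "group",
]

_TABLE_KINDS = {
    "spot": SPOT_COLUMNS,
    "granule": GRANULE_COLUMNS,
    "screen": SCREEN_COLUMNS,
}

_INT_NULLABLE = {"n_molecules", "granule_id"}
_BOOL_COLUMNS = {"is_cluster", "foci_P1", "foci_P2", "foci_P3", "foci_P4", "pgc_pattern"}


def _infer_kind(columns: Sequence[str]) -> str:
    cols = list(columns)
    for kind, schema in _TABLE_KINDS.items():
        if cols == schema or set(cols) == set(schema):
            return kind
    raise ValueError(f"columns {cols} do not match any known table schema")


def write_table(table: pd.DataFrame, path: str | Path, kind: str | None = None) -> None:
    """Write a spot/granule/screen table as CSV with the fixed column order.

    Floats are written at full (round-trippable) precision; an empty table
    produces a header-only file.  NaN intensities violate the spot-table
    invariant and are rejected.
    """
    kind = kind or _infer_kind(table.columns)
    schema = _TABLE_KINDS[kind]
    missing = set(schema) - set(table.columns)
    if missing:
        raise ValueError(f"{kind} table is missing columns {sorted(missing)}")
    out = table.loc[:, schema].copy()
    if kind == "spot" and len(out):
        intens = pd.to_numeric(out["intensity"], errors="coerce")
        if intens.isna().any() or not np.all(np.isfinite(intens.to_numpy(dtype=float))):
            raise ValueError("spot table contains NaN/non-finite intensities")
    out.to_csv(path, index=False)


def read_table(path: str | Path, kind: str | None = None) -> pd.DataFrame:
    """Read a table written by :func:`write_table`, restoring dtypes."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such table: {path}")
    df = pd.read_csv(path)
    kind = kind or _infer_kind(df.columns)
    schema = _TABLE_KINDS[kind]
    df = df.loc[:, schema]
    for col in df.columns:
        if col in _INT_NULLABLE:
            df[col] = df[col].astype("Int64")
        elif col in _BOOL_COLUMNS and df[col].dtype == object:
            df[col] = df[col].map(
                {"True": True, "False": False, True: True, False: False}
            )
    return df


def empty_spot_table() -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "spot_id": pd.Series(dtype=int),
            "z": pd.Series(dtype=float),
            "y": pd.Series(dtype=float),
            "x": pd.Series(dtype=float),
            "intensity": pd.Series(dtype=float),
            "residual": pd.Series(dtype=float),
            "lineage": pd.Series(dtype=object),
            "n_molecules": pd.Series(dtype="Int64"),
            "is_cluster": pd.Series(dtype=object),
            "granule_id": pd.Series(dtype="Int64"),
        }
    )
    return df


def empty_granule_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "granule_id": pd.Series(dtype=int),
            "z": pd.Series(dtype=float),
            "y": pd.Series(dtype=float),
            "x": pd.Series(dtype=float),
            "minor_radius_px": pd.Series(dtype=float),
            "major_radius_px": pd.Series(dtype=float),
            "volume_vox": pd.Series(dtype=int),
            "half_z": pd.Series(dtype=float),
            "half_y": pd.Series(dtype=float),
            "half_x": pd.Series(dtype=float),
        }
    )
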