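"""Synthetic embryo images with exhaustive ground truth.

The generator emulates the statistical structure of smFISH z-stacks of
*C. elegans* germline blastomeres:

* diffraction-limited spots rendered as voxel-integrated 3D Gaussians, with
  integrated intensity ``n_molecules * unit_intensity`` (one photon budget
  per molecule — photons are conserved);
* multi-molecule foci ("clusters") with sizes drawn from a truncated
  geometric distribution;
* ellipsoidal granules, largest along z, rendered into a second channel;
* an ellipsoidal cell with an interior nucleus (mRNA-free);
* a constant background plus linear gradient, Poisson shot noise and
  additive Gaussian read noise;
* asymmetric P-lineage divisions (P1 -> P4) in which the germline daughter
  inherits granule-associated molecules preferentially and cytoplasmic
  molecules in proportion to its volume.

Every latent variable (focus positions, molecule counts, granule geometry,
partition history) is returned as ground truth so downstream stages can be
scored exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from math import sqrt
from typing import Sequence

import numpy as np
import pandas as pd

from .imaging_io import CellROI, ImageStack, Lineage

log = logging.getLogger("granulefish")

__all__ = [
    "SimParams",
    "GroundTruth",
    "LineageStage",
    "generate_embryo",
    "generate_lineage_series",
    "generate_screen_table",
    "lineage_sim_params",
]

_SQRT2 = sqrt(2.0)

# Observed screen proportions, used as generator defaults: Group I 131/487,
# Group II 310/487, Group III 46/487; 5 of the 46 Group III transcripts
# nonetheless show a PGC-like maintenance pattern.
DEFAULT_GROUP_PROBS = (131 / 487, 310 / 487, 46 / 487)
DEFAULT_P_PGC_GIVEN_III = 5 / 46


@dataclass
class SimParams:
    """Parameters of one synthetic blastomere image.

    Units follow the package convention: x/y in pixels, z in slices.
    Defaults describe a high-SNR single P-blastomere field (~10^3 molecules,
    single-molecule peak amplitude roughly 10x the background noise sd).
    """

    shape: tuple[int, int, int] = (20, 160, 160)
    n_molecules: int = 947
    p_granule: float = 0.5
    cluster_mean_size: float = 1.2
    granule_cluster_mean_size: float = 3.0
    cluster_max_size: int = 35
    n_granules: int = 10
    granule_minor_range: tuple[float, float] = (4.0, 7.0)
    granule_major_range: tuple[float, float] = (5.0, 8.0)
    granule_min_gap_px: float = 2.0
    granule_intensity: float = 160.0
    cyto_marker_level: float = 80.0
    cyto_marker_sd: float = 15.0
    granule_render_blur: float = 0.6
    psf_sigma_xy_px: float = 1.0
    psf_sigma_z_slices: float = 1.0
    unit_intensity: float = 4000.0
    background_level: float = 100.0
    background_gradient: tuple[float, float, float] = (0.0, 0.15, 0.15)
    read_noise_sd: float = 5.0
    cell_radii: tuple[float, float, float] = (8.0, 70.0, 70.0)
    nucleus_radii: tuple[float, float, float] = (3.5, 20.0, 20.0)
    min_focus_separation_px: float = 4.0
    lineage: str = Lineage.SOMATIC.value
    pixel_size_xy: float = 100.0
    z_step: float = 300.0
    rng_seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.p_granule <= 1.0:
            raise ValueError("p_granule must be in [0, 1]")
        if self.unit_intensity <= 0:
            raise ValueError("unit_intensity must be > 0")
        if self.n_molecules < 0 or self.n_granules < 0:
            raise ValueError("counts must be >= 0")
        if self.cluster_mean_size < 1.0:
            raise ValueError("cluster_mean_size must be >= 1")
        if self.p_granule > 0 and self.n_molecules > 0 and self.n_granules == 0:
            raise ValueError("p_granule > 0 requires at least one granule")


@dataclass
class GroundTruth:
    """Latent variables of a simulated image.

    ``foci`` has one row per diffraction-limited focus:
    (focus_id, z, y, x, n_molecules, in_granule, granule_id).
    ``granules`` has one row per granule:
    (granule_id, z, y, x, r_z, r_y, r_x, volume_vox).
    ``partition_history`` is filled by :func:`generate_lineage_series`.
    """

    foci: pd.DataFrame
    granules: pd.DataFrame
    roi: CellROI
    partition_history: pd.DataFrame | None = None

    @property
    def n_molecules(self) -> int:
        return int(self.foci["n_molecules"].sum()) if len(self.foci) else 0


@dataclass
class LineageStage:
    """One cell of a simulated P-lineage series."""

    lineage: str
    rna_stack: ImageStack
    granule_stack: ImageStack | None
    roi: CellROI
    truth: GroundTruth


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def ellipsoid_mask(
    shape: Sequence[int], center: Sequence[float], radii: Sequence[float]
) -> np.ndarray:
    """Boolean mask of an axis-aligned ellipsoid (voxel centers inside)."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(tuple(shape), dtype=float)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def render_foci(
    shape: tuple[int, int, int],
    foci: pd.DataFrame,
    sigma_xy: float,
    sigma_z: float,
    unit_intensity: float,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Add voxel-integrated Gaussian spots for each truth focus.

    Each focus contributes a total of ``n_molecules * unit_intensity``
    photons (up to edge truncation), split across voxels by the product of
    per-axis integrated Gaussian profiles.
    """
    nz, ny, nx = shape
    img = out if out is not None else np.zeros(shape, dtype=np.float64)
    hz = int(np.ceil(4 * sigma_z)) + 1
    hxy = int(np.ceil(4 * sigma_xy)) + 1
    from scipy.special import erf as _verf

    for z, y, x, n in zip(foci["z"], foci["y"], foci["x"], foci["n_molecules"]):
        z0, z1 = max(0, int(z) - hz), min(nz, int(z) + hz + 1)
        y0, y1 = max(0, int(y) - hxy), min(ny, int(y) + hxy + 1)
        x0, x1 = max(0, int(x) - hxy), min(nx, int(x) + hxy + 1)
        pz = _erf_profile(_verf, z0, z1, z, sigma_z)
        py = _erf_profile(_verf, y0, y1, y, sigma_xy)
        px = _erf_profile(_verf, x0, x1, x, sigma_xy)
        img[z0:z1, y0:y1, x0:x1] += (
            float(n) * unit_intensity
        ) * pz[:, None, None] * py[None, :, None] * px[None, None, :]
    return img


def _erf_profile(verf, lo: int, hi: int, center: float, sigma: float) -> np.ndarray:
    idx = np.arange(lo, hi, dtype=float)
    return 0.5 * (
        verf((idx + 0.5 - center) / (_SQRT2 * sigma))
        - verf((idx - 0.5 - center) / (_SQRT2 * sigma))
    )


def _apply_noise(
    clean: np.ndarray, rng: np.random.Generator, read_noise_sd: float
) -> np.ndarray:
    """Camera model: Poisson(signal) shot noise plus Gaussian read noise."""
    img = rng.poisson(np.clip(clean, 0, None)).astype(np.float64)
    if read_noise_sd > 0:
        img += rng.normal(0.0, read_noise_sd, size=clean.shape)
    return np.clip(img, 0.0, None)


def _background_field(
    shape: tuple[int, int, int], level: float, gradient: tuple[float, float, float]
) -> np.ndarray:
    nz, ny, nx = shape
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    gz, gy, gx = gradient
    return level + gz * zz + gy * yy + gx * xx


def _sample_cluster_sizes(
    rng: np.random.Generator, total: int, mean: float, max_size: int
) -> list[int]:
    """Draw focus sizes from a truncated geometric distribution until the
    molecule budget ``total`` is exhausted (last focus clipped)."""
    sizes: list[int] = []
    remaining = total
    p = 1.0 / mean
    while remaining > 0:
        size = int(rng.geometric(p)) if mean > 1.0 else 1
        size = min(size, max_size, remaining)
        sizes.append(size)
        remaining -= size
    return sizes


# ---------------------------------------------------------------------------
# embryo generation
# ---------------------------------------------------------------------------


def _place_granules(params: SimParams, cytoplasm: np.ndarray, rng: np.random.Generator):
    """Sample non-overlapping ellipsoidal granules inside the cytoplasm."""
    shape = params.shape
    placed: list[dict] = []
    max_tries = 200 * max(params.n_granules, 1)
    tries = 0
    cyto_idx = np.argwhere(cytoplasm)
    if params.n_granules and len(cyto_idx) == 0:
        raise RuntimeError("no cytoplasm to place granules in")
    while len(placed) < params.n_granules:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could only place {len(placed)}/{params.n_granules} granules "
                "inside the cytoplasm after bounded retries"
            )
        minor = rng.uniform(*params.granule_minor_range)
        major = rng.uniform(*params.granule_major_range)
        major = max(major, minor)  # major axis (z) is the largest
        center = cyto_idx[rng.integers(len(cyto_idx))].astype(float)
        center += rng.uniform(-0.5, 0.5, size=3)
        radii = (major, minor, minor)  # (z, y, x)
        # stay separated from previously placed granules
        ok = True
        for g in placed:
            d = np.array(
                [
                    (center[i] - g["center"][i])
                    / (radii[i] + g["radii"][i] + params.granule_min_gap_px)
                    for i in range(3)
                ]
            )
            if np.sum(d**2) < 1.0:
                ok = False
                break
        if not ok:
            continue
        mask = ellipsoid_mask(shape, center, radii)
        if not mask.any() or np.any(mask & ~cytoplasm):
            continue
        placed.append({"center": center, "radii": radii, "mask": mask})
    return placed


def _sample_point_in_ellipsoid(
    rng: np.random.Generator, center, radii, shrink: float = 0.8
) -> np.ndarray:
    """Uniform point inside an ellipsoid, shrunk so rounded voxels stay in
    the granule's voxel mask."""
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    r = rng.uniform() ** (1.0 / 3.0)
    return np.asarray(center) + shrink * r * v * np.asarray(radii)


def generate_embryo(
    params: SimParams,
) -> tuple[ImageStack, ImageStack | None, CellROI, GroundTruth]:
    """Simulate one blastomere: RNA channel, granule channel, ROI and truth.

    Returns ``(rna_stack, granule_stack, roi, truth)``.  ``granule_stack`` is
    None when ``params.n_granules == 0``.
    """
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    shape = params.shape
    center = tuple((s - 1) / 2.0 for s in shape)

    cell = ellipsoid_mask(shape, center, params.cell_radii)
    nucleus = ellipsoid_mask(shape, center, params.nucleus_radii)
    nucleus &= cell
    cytoplasm = cell & ~nucleus
    roi = CellROI(cell, nucleus, params.lineage)

    granules = _place_granules(params, cytoplasm, rng) if params.n_granules else []
    granule_rows = [
        {
            "granule_id": i,
            "z": g["center"][0],
            "y": g["center"][1],
            "x": g["center"][2],
            "r_z": g["radii"][0],
            "r_y": g["radii"][1],
            "r_x": g["radii"][2],
            "volume_vox": int(g["mask"].sum()),
        }
        for i, g in enumerate(granules)
    ]

    # --- place foci -------------------------------------------------------
    # Split the molecule budget exactly: granule-associated molecules
    # coalesce into fewer, multi-copy foci (sub-granular clusters), while
    # dispersed cytoplasmic molecules are mostly singles.
    n_gran_mols = round(params.p_granule * params.n_molecules) if granules else 0
    n_cyto_mols = params.n_molecules - n_gran_mols
    gran_sizes = _sample_cluster_sizes(
        rng, n_gran_mols, params.granule_cluster_mean_size, params.cluster_max_size
    )
    cyto_sizes = _sample_cluster_sizes(
        rng, n_cyto_mols, params.cluster_mean_size, params.cluster_max_size
    )
    cyto_idx = np.argwhere(cytoplasm)
    foci_rows: list[dict] = []
    positions: list[np.ndarray] = []
    min_sep2 = params.min_focus_separation_px**2
    n_cramped = 0

    def _separated(pos: np.ndarray) -> bool:
        if min_sep2 <= 0 or not positions:
            return True
        d2 = np.sum((np.array(positions) - pos) ** 2, axis=1)
        return bool(d2.min() >= min_sep2)

    plan = [(size, True) for size in gran_sizes] + [(size, False) for size in cyto_sizes]
    for fid, (size, in_granule) in enumerate(plan):
        pos = None
        gid = -1
        if in_granule:
            for _ in range(500):
                gid = int(rng.integers(len(granules)))
                cand = _sample_point_in_ellipsoid(
                    rng, granules[gid]["center"], granules[gid]["radii"]
                )
                vox = tuple(np.clip(np.round(cand).astype(int), 0, np.array(shape) - 1))
                if granules[gid]["mask"][vox] and _separated(cand):
                    pos = cand
                    break
        if pos is None:
            if in_granule:
                # crowded granules: fall back to a dispersed position and
                # record the focus as cytoplasmic so truth stays consistent
                n_cramped += 1
                in_granule, gid = False, -1
            for _ in range(500):
                cand = cyto_idx[rng.integers(len(cyto_idx))].astype(float)
                cand += rng.uniform(-0.5, 0.5, size=3)
                if _separated(cand):
                    pos = cand
                    break
            else:
                cand = cyto_idx[rng.integers(len(cyto_idx))].astype(float)
                pos = cand + rng.uniform(-0.5, 0.5, size=3)
                n_cramped += 1
        positions.append(pos)
        foci_rows.append(
            {
                "focus_id": fid,
                "z": pos[0],
                "y": pos[1],
                "x": pos[2],
                "n_molecules": size,
                "in_granule": in_granule,
                "granule_id": gid if in_granule else -1,
            }
        )

    if n_cramped:
        log.debug(
            "%d/%d foci relocated or cramped by min_focus_separation_px "
            "(crowded cell)",
            n_cramped,
            len(plan),
        )
    foci = pd.DataFrame(
        foci_rows,
        columns=["focus_id", "z", "y", "x", "n_molecules", "in_granule", "granule_id"],
    )
    if len(foci) == 0:
        foci = foci.astype(
            {"focus_id": int, "n_molecules": int, "in_granule": bool, "granule_id": int}
        )

    # --- render -----------------------------------------------------------
    bg = _background_field(shape, params.background_level, params.background_gradient)
    rna_clean = bg.copy()
    if len(foci):
        render_foci(
            shape,
            foci,
            params.psf_sigma_xy_px,
            params.psf_sigma_z_slices,
            params.unit_intensity,
            out=rna_clean,
        )
    rna = _apply_noise(rna_clean, rng, params.read_noise_sd)
    rna_stack = ImageStack(
        rna, params.pixel_size_xy, params.z_step, channel_name="smFISH"
    )

    granule_stack = None
    if granules:
        from scipy.ndimage import gaussian_filter

        gr_clean = np.zeros(shape, dtype=np.float64)
        for g in granules:
            gr_clean[g["mask"]] += params.granule_intensity
        if params.granule_render_blur > 0:
            gr_clean = gaussian_filter(gr_clean, params.granule_render_blur)
        # diffuse cytoplasmic marker pool (the granule protein is only
        # partially condensed): smooth heterogeneous field inside the cell
        if params.cyto_marker_level > 0:
            pool = np.full(shape, params.cyto_marker_level)
            if params.cyto_marker_sd > 0:
                f = gaussian_filter(rng.normal(0.0, 1.0, shape), (2, 6, 6))
                sd = f.std()
                if sd > 0:
                    pool += params.cyto_marker_sd * f / sd
            gr_clean[cytoplasm] += np.clip(pool[cytoplasm], 0.0, None)
        gr_clean += bg
        gr = _apply_noise(gr_clean, rng, params.read_noise_sd)
        granule_stack = ImageStack(
            gr, params.pixel_size_xy, params.z_step, channel_name="granule-marker"
        )

    truth = GroundTruth(
        foci=foci,
        granules=pd.DataFrame(
            granule_rows,
            columns=["granule_id", "z", "y", "x", "r_z", "r_y", "r_x", "volume_vox"],
        ),
        roi=roi,
    )
    return rna_stack, granule_stack, roi, truth


# ---------------------------------------------------------------------------
# lineage series
# ---------------------------------------------------------------------------


def lineage_sim_params(
    n_molecules: int = 20000, rng_seed: int = 0, shape=(16, 192, 192)
) -> SimParams:
    """Imaging conditions for the P-lineage concentration series.

    Emulates the lower-magnification acquisition used for whole-cell
    concentration measurements: ~300 nm pixels (PSF sigma ~0.21 px in-plane),
    1 um z-steps, and a large mid-plane cell cross-section so that single-slice
    integrated density is a low-variance concentration readout.
    """
    return SimParams(
        shape=shape,
        n_molecules=n_molecules,
        p_granule=1.0,
        cluster_mean_size=1.0,
        n_granules=0,
        psf_sigma_xy_px=0.21,
        psf_sigma_z_slices=0.6,
        unit_intensity=500.0,
        background_level=100.0,
        background_gradient=(0.0, 0.0, 0.0),
        read_noise_sd=5.0,
        cell_radii=(6.5, 80.0, 80.0),
        nucleus_radii=(3.0, 30.0, 30.0),
        min_focus_separation_px=0.0,
        pixel_size_xy=300.0,
        z_step=1000.0,
        rng_seed=rng_seed,
    )


_P_LABELS = [Lineage.P1.value, Lineage.P2.value, Lineage.P3.value, Lineage.P4.value]


def generate_lineage_series(
    params: SimParams,
    n_divisions: int = 3,
    inherit_fraction: float = 1.0,
    volume_ratio: float = 0.5,
) -> list[LineageStage]:
    """Simulate asymmetric P-lineage divisions (P1 -> P4 for 3 divisions).

    At each division the germline daughter keeps a binomial
    ``inherit_fraction`` share of granule-associated molecules and a
    ``volume_ratio`` share of cytoplasmic molecules, while its cell volume
    shrinks by ``volume_ratio`` (x/y radii scale by sqrt(volume_ratio); the
    z geometry is held fixed, as nuclear height does not scale with the
    8-fold cell-volume decrease).

    Under full granule localization and inheritance with halving volumes the
    truth concentration doubles per division (8x over three divisions).

    Molecules are rendered uniformly in the cytoplasm: granule association
    here is partitioning bookkeeping, not a spatial statement (see the
    methods note).
    """
    # granule association is partition bookkeeping here, so a granule-free
    # image with p_granule > 0 is legitimate: validate a neutralized copy
    replace(params, p_granule=0.0).validate()
    if not 0.0 <= params.p_granule <= 1.0:
        raise ValueError("p_granule must be in [0, 1]")
    if n_divisions < 1:
        raise ValueError("n_divisions must be >= 1")
    if not 0.0 <= inherit_fraction <= 1.0:
        raise ValueError("inherit_fraction must be in [0, 1]")
    if not 0.0 < volume_ratio < 1.0:
        raise ValueError("volume_ratio must be in (0, 1)")

    rng = np.random.default_rng(params.rng_seed)
    n_gran = (
        params.n_molecules
        if params.p_granule == 1.0
        else int(rng.binomial(params.n_molecules, params.p_granule))
    )
    n_cyto = params.n_molecules - n_gran

    stages: list[LineageStage] = []
    history: list[dict] = []
    rel_volume = 1.0
    xy_scale = 1.0
    for stage in range(n_divisions + 1):
        label = _P_LABELS[min(stage, len(_P_LABELS) - 1)]
        n_total = n_gran + n_cyto
        stage_params = replace(
            params,
            n_molecules=n_total,
            p_granule=0.0,  # spatial placement is uniform; see docstring
            n_granules=0,
            cell_radii=(
                params.cell_radii[0],
                params.cell_radii[1] * xy_scale,
                params.cell_radii[2] * xy_scale,
            ),
            nucleus_radii=(
                params.nucleus_radii[0],
                params.nucleus_radii[1] * xy_scale,
                params.nucleus_radii[2] * xy_scale,
            ),
            lineage=label,
            rng_seed=int(rng.integers(2**31 - 1)),
        )
        rna_stack, granule_stack, roi, truth = generate_embryo(stage_params)
        history.append(
            {
                "stage": stage,
                "lineage": label,
                "n_molecules": n_total,
                "n_granule_associated": n_gran,
                "cytoplasm_volume_rel": rel_volume,
                "concentration_rel": (n_total / rel_volume) if rel_volume > 0 else np.nan,
                "inherit_fraction": inherit_fraction,
                "volume_ratio": volume_ratio,
            }
        )
        truth.partition_history = pd.DataFrame(history)
        stages.append(LineageStage(label, rna_stack, granule_stack, roi, truth))
        if stage == n_divisions:
            break
        # asymmetric division
        if inherit_fraction == 1.0:
            n_gran_next = n_gran
        else:
            n_gran_next = int(rng.binomial(n_gran, inherit_fraction))
        n_cyto_next = int(rng.binomial(n_cyto, volume_ratio)) if n_cyto else 0
        if n_gran_next + n_cyto_next == 0 and inherit_fraction >= 1.0 and n_total > 0:
            raise RuntimeError("molecule count underflow with full inheritance")
        n_gran, n_cyto = n_gran_next, n_cyto_next
        rel_volume *= volume_ratio
        xy_scale *= sqrt(volume_ratio)

    full_history = pd.DataFrame(history)
    for st in stages:
        st.truth.partition_history = full_history.copy()
    return stages


# ---------------------------------------------------------------------------
# screen fixture generation
# ---------------------------------------------------------------------------


def generate_screen_table(
    n_transcripts: int,
    group_probs: Sequence[float] = DEFAULT_GROUP_PROBS,
    rng_seed: int = 0,
    p_pgc_given_iii: float = DEFAULT_P_PGC_GIVEN_III,
    p_focus_flag: float = 0.8,
) -> pd.DataFrame:
    """Generate a screen annotation table with known group labels.

    ``group_probs`` are the (I, II, III) sampling probabilities.  Group I/II
    rows carry at least one per-stage focus flag; Group III rows carry none,
    but may still show a PGC-maintenance pattern with probability
    ``p_pgc_given_iii`` (a small minority of foci-negative transcripts do).
    The ``group`` column holds the generator's label and is re-derivable from
    the boolean fields.
    """
    probs = np.asarray(group_probs, dtype=float)
    if probs.shape != (3,) or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("group_probs must be three non-negative values summing to 1")
    rng = np.random.default_rng(rng_seed)
    groups = rng.choice(["I", "II", "III"], size=n_transcripts, p=probs)
    rows = []
    for i, grp in enumerate(groups):
        if grp in ("I", "II"):
            flags = rng.uniform(size=4) < p_focus_flag
            if not flags.any():
                flags[rng.integers(4)] = True
            pgc = grp == "I"
        else:
            flags = np.zeros(4, dtype=bool)
            pgc = bool(rng.uniform() < p_pgc_given_iii)
        rows.append(
            {
                "transcript_id": f"txp{i:04d}",
                "foci_P1": bool(flags[0]),
                "foci_P2": bool(flags[1]),
                "foci_P3": bool(flags[2]),
                "foci_P4": bool(flags[3]),
                "pgc_pattern": pgc,
                "group": grp,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "foci_P1",
            "foci_P2",
            "foci_P3",
            "foci_P4",
            "pgc_pattern",
            "group",
        ],
    )
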