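import numpy as np
import pytest
import scipy.spatial

from granulefish import PipelineConfig, SimParams, generate_embryo


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def cluster_embryo():
    """A P2 blastomere with granules, clusters and both channels."""
    params = SimParams(
        n_molecules=500,
        p_granule=0.5,
        n_granules=8,
        rng_seed=7,
        shape=(20, 128, 128),
        cell_radii=(8, 55, 55),
        nucleus_radii=(3.5, 16, 16),
        lineage="P2",
    )
    rna, marker, roi, truth = generate_embryo(params)
    return params, rna, marker, roi, truth


@pytest.fixture(scope="session")
def somatic_field():
    """A somatic blastomere of isolated single molecules (calibration data)."""
    params = SimParams(
        n_molecules=120,
        cluster_mean_size=1.0,
        p_granule=0.0,
        n_granules=0,
        rng_seed=1007,
        shape=(16, 128, 128),
        cell_radii=(6.5, 55, 55),
        nucleus_radii=(3, 16, 16),
        min_focus_separation_px=5.0,
    )
    rna, _, roi, truth = generate_embryo(params)
    return params, rna, roi, truth


def match_one_to_one(truth_xyz, spot_xyz, tol=2.0):
    """Greedy nearest-first one-to-one matching of truth foci to spots."""
    truth_xyz = np.asarray(truth_xyz, dtype=float)
    spot_xyz = np.asarray(spot_xyz, dtype=float)
    if len(truth_xyz) == 0 or len(spot_xyz) == 0:
        return {}
    tree = scipy.spatial.cKDTree(spot_xyz)
    cand = []
    for i, row in enumerate(truth_xyz):
        for j in tree.query_ball_point(row, tol):
            cand.append((float(np.linalg.norm(row - spot_xyz[j])), i, j))
    cand.sort()
    used_t, used_s, pairs = set(), set(), {}
    for _, i, j in cand:
        if i in used_t or j in used_s:
            continue
        used_t.add(i)
        used_s.add(j)
        pairs[i] = j
    return pairs
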