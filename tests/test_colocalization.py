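import numpy as np
import pandas as pd
import pytest

from granulefish.colocalization import (
    cluster_colocalization,
    granule_content_summary,
    pct_molecules_in_granules,
    spot_in_granule,
)
from granulefish.granule_segmentation import BoundingCube


def cube(gid, center, half_z, half_xy):
    return BoundingCube(gid, *center, half_z, half_xy, half_xy)


def spots_from(coords, n_molecules=None, clusters=None):
    n = len(coords)
    coords = np.asarray(coords, dtype=float).reshape(n, 3)
    return pd.DataFrame(
        {
            "spot_id": range(n),
            "z": coords[:, 0],
            "y": coords[:, 1],
            "x": coords[:, 2],
            "intensity": 1000.0,
            "residual": 0.0,
            "lineage": "P2",
            "n_molecules": pd.array(
                n_molecules if n_molecules is not None else [1] * n, dtype="Int64"
            ),
            "is_cluster": clusters if clusters is not None else [True] * n,
            "granule_id": pd.array([pd.NA] * n, dtype="Int64"),
        }
    )


class TestSpotInGranule:
    def test_spot_at_centroid_is_assigned(self):
        cubes = [cube(5, (10, 20, 30), 4, 5)]
        assert spot_in_granule({"z": 10, "y": 20, "x": 30}, cubes) == 5

    def test_spot_one_pixel_outside_face_is_none(self):
        cubes = [cube(0, (10, 20, 30), 4, 5)]
        assert spot_in_granule({"z": 10, "y": 20, "x": 36}, cubes) is None

    def test_boundary_is_inclusive(self):
        cubes = [cube(0, (10, 20, 30), 4, 5)]
        assert spot_in_granule({"z": 14, "y": 25, "x": 35}, cubes) == 0

    def test_overlapping_cubes_assign_nearer_centroid(self):
        cubes = [cube(0, (10, 20, 30), 4, 6), cube(1, (10, 20, 38), 4, 6)]
        # brute-force check: distance to 0 is 3, to 1 is 5
        assert spot_in_granule({"z": 10, "y": 20, "x": 33}, cubes) == 0
        assert spot_in_granule({"z": 10, "y": 20, "x": 35}, cubes) == 1

    def test_exact_tie_goes_to_lower_id(self):
        cubes = [cube(2, (10, 20, 30), 4, 6), cube(1, (10, 20, 38), 4, 6)]
        assert spot_in_granule({"z": 10, "y": 20, "x": 34}, cubes) == 1


class TestPctMoleculesInGranules:
    def test_all_inside_is_hundred(self):
        cubes = [cube(0, (5, 5, 5), 10, 10)]
        spots = spots_from([(5, 5, 5), (6, 6, 6)])
        assert pct_molecules_in_granules(spots, cubes) == 100.0

    def test_molecule_weighted_not_spot_weighted(self):
        # one 4-molecule cluster inside, four singles outside -> 50%
        cubes = [cube(0, (5, 5, 5), 2, 2)]
        spots = spots_from(
            [(5, 5, 5)] + [(50, 50, 50)] * 4, n_molecules=[4, 1, 1, 1, 1]
        )
        assert pct_molecules_in_granules(spots, cubes) == pytest.approx(50.0)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            pct_molecules_in_granules(spots_from([]), [])

    def test_monotone_nondecreasing_in_cube_pad(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 40, size=(200, 3))
        spots = spots_from(coords)
        centers = rng.uniform(5, 35, size=(5, 3))
        pcts = []
        for pad in (0, 1, 2, 4, 8):
            cubes = [
                BoundingCube(i, *c, 3.0, 2.0 + pad, 2.0 + pad)
                for i, c in enumerate(centers)
            ]
            pcts.append(pct_molecules_in_granules(spots, cubes))
        assert all(a <= b for a, b in zip(pcts, pcts[1:]))


def pairing_oracle(a, b, tol_xy, tol_z):
    """Brute-force one-to-one nearest pairing under the all-axes rule."""
    cand = []
    for i, ra in a.iterrows():
        for j, rb in b.iterrows():
            dz, dy, dx = (
                abs(ra.z - rb.z),
                abs(ra.y - rb.y),
                abs(ra.x - rb.x),
            )
            if dz <= tol_z and dy <= tol_xy and dx <= tol_xy:
                cand.append(
                    (np.sqrt(dz**2 + dy**2 + dx**2), ra.spot_id, rb.spot_id)
                )
    cand.sort()
    ua, ub, pairs = set(), set(), set()
    for d, ai, bi in cand:
        if ai in ua or bi in ub:
            continue
        ua.add(ai)
        ub.add(bi)
        pairs.add((ai, bi))
    return pairs


class TestClusterColocalization:
    def test_identical_coordinates_pair(self):
        a = spots_from([(5, 5, 5)])
        b = spots_from([(5, 5, 5)])
        pairs, pct_not = cluster_colocalization(a, b)
        assert len(pairs) == 1
        assert pct_not == 0.0

    def test_all_axes_rule(self):
        # within tolerance on two axes but 3 px off on the third: not
        # colocalized
        a = spots_from([(5, 5, 5)])
        b = spots_from([(5, 8, 5)])
        pairs, pct_not = cluster_colocalization(a, b, tol_xy_px=2, tol_z_slices=2)
        assert len(pairs) == 0
        assert pct_not == 100.0

    def test_non_clusters_are_ignored(self):
        a = spots_from([(5, 5, 5)], clusters=[False])
        b = spots_from([(5, 5, 5)])
        pairs, pct_not = cluster_colocalization(a, b)
        assert len(pairs) == 0 and np.isnan(pct_not)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle_on_random_scenes(self, seed):
        rng = np.random.default_rng(seed)
        a = spots_from(rng.uniform(0, 25, size=(rng.integers(5, 40), 3)))
        b = spots_from(rng.uniform(0, 25, size=(rng.integers(5, 40), 3)))
        pairs, pct_not = cluster_colocalization(a, b)
        got = set(zip(pairs.a_id, pairs.b_id))
        assert got == pairing_oracle(a, b, 2, 2)

    @pytest.mark.parametrize("seed", range(4))
    def test_pair_set_symmetric_under_swap(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = spots_from(rng.uniform(0, 20, size=(25, 3)))
        b = spots_from(rng.uniform(0, 20, size=(25, 3)))
        ab, _ = cluster_colocalization(a, b)
        ba, _ = cluster_colocalization(b, a)
        assert set(zip(ab.a_id, ab.b_id)) == set(zip(ba.b_id, ba.a_id))


class TestGranuleContent:
    def _granules(self, n):
        return pd.DataFrame(
            {
                "granule_id": range(n),
                "z": 10.0,
                "y": 10.0,
                "x": [10.0 + 20 * i for i in range(n)],
                "minor_radius_px": 3.0,
                "major_radius_px": 4.0,
                "volume_vox": 100,
                "half_z": 4.0,
                "half_y": 5.0,
                "half_x": 5.0,
            }
        )

    def test_no_clusters_is_all_neither(self):
        res = granule_content_summary(
            self._granules(4), spots_from([]), spots_from([])
        )
        assert res["percentages"]["neither"] == 100.0

    def test_one_granule_with_both_species(self):
        g = self._granules(1)
        res = granule_content_summary(
            g, spots_from([(10, 10, 10)]), spots_from([(11, 11, 11)])
        )
        assert res["counts"] == {"a_only": 0, "b_only": 0, "both": 1, "neither": 0}

    def test_constructed_scene_counts(self):
        g = self._granules(10)
        # A in granules 0,1,2; B in granules 2,3
        a = spots_from([(10, 10, 10), (10, 10, 30), (10, 10, 50)])
        b = spots_from([(10, 10, 50), (10, 10, 70)])
        res = granule_content_summary(g, a, b)
        assert res["counts"] == {"a_only": 2, "b_only": 1, "both": 1, "neither": 6}
        assert sum(res["counts"].values()) == 10
        assert sum(res["percentages"].values()) == pytest.approx(100.0)
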