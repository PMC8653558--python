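import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from discdegen.disc3d import (
    BIN_LABELS,
    ZONES,
    EndplateCloud,
    dhi_bin,
    fit_disc_frame,
    least_distance_height,
    partition_zones,
    three_d_dhi,
    zone_heights,
)
from discdegen.synthetic import generate_endplate_pair

from conftest import grid_cloud


def brute_force_directed_mean(inf_pts, sup_pts):
    """O(n^2) exhaustive directed least-distance oracle."""
    d = np.linalg.norm(inf_pts[:, None, :] - sup_pts[None, :, :], axis=2)
    return float(np.mean(d.min(axis=1))), d.min(axis=1)


class TestLeastDistance:
    def test_congruent_parallel_planes_equal_the_separation(self):
        inf = EndplateCloud(grid_cloud(0.0), "inferior")
        sup = EndplateCloud(grid_cloud(4.0), "superior")
        mean, d = least_distance_height(inf, sup)
        assert mean == pytest.approx(4.0, abs=1e-12)
        assert np.all(d == pytest.approx(4.0))

    def test_minimum_of_two_candidates(self):
        inf = EndplateCloud([[0.0, 0.0, 0.0]], "inferior")
        sup = EndplateCloud([[0.0, 0.0, 3.0], [4.0, 0.0, 0.0]], "superior")
        mean, _ = least_distance_height(inf, sup)
        assert mean == pytest.approx(3.0)

    def test_matches_brute_force_oracle_on_random_clouds(self, rng):
        for n in (50, 200, 500):
            inf_pts = rng.uniform(-5, 5, (n, 3))
            sup_pts = rng.uniform(-5, 5, (n, 3)) + [0, 0, 3.0]
            inf = EndplateCloud(inf_pts, "inferior")
            sup = EndplateCloud(sup_pts, "superior")
            mean, d = least_distance_height(inf, sup)
            o_mean, o_d = brute_force_directed_mean(inf_pts, sup_pts)
            assert mean == o_mean
            np.testing.assert_array_equal(d, o_d)

    def test_tilted_plane_matches_brute_force(self):
        inf_pts = grid_cloud(0.0, n=15)
        sup_pts = inf_pts.copy()
        sup_pts[:, 2] = 2.0 + 0.1 * sup_pts[:, 0]
        mean, _ = least_distance_height(
            EndplateCloud(inf_pts, "inferior"), EndplateCloud(sup_pts, "superior")
        )
        assert mean == brute_force_directed_mean(inf_pts, sup_pts)[0]

    def test_directedness_is_asymmetric(self, rng):
        # a superior outlier far away is invisible to the directed measure
        inf_pts = grid_cloud(0.0, n=8)
        sup_pts = np.vstack([grid_cloud(2.0, n=8), [[50.0, 50.0, 50.0]]])
        inf = EndplateCloud(inf_pts, "inferior")
        sup = EndplateCloud(sup_pts, "superior")
        directed, _ = least_distance_height(inf, sup)
        symmetric, _ = least_distance_height(inf, sup, symmetric=True)
        assert directed == pytest.approx(2.0)
        assert symmetric > directed

    def test_rigid_motion_invariance(self, rng):
        inf_pts = rng.uniform(-5, 5, (300, 3))
        sup_pts = rng.uniform(-5, 5, (300, 3)) + [0, 0, 3.0]
        rot = Rotation.from_rotvec([0.3, -0.2, 0.9]).as_matrix()
        shift = np.array([2.0, -7.0, 1.5])
        m1, d1 = least_distance_height(
            EndplateCloud(inf_pts, "inferior"), EndplateCloud(sup_pts, "superior")
        )
        m2, d2 = least_distance_height(
            EndplateCloud(inf_pts @ rot.T + shift, "inferior"),
            EndplateCloud(sup_pts @ rot.T + shift, "superior"),
        )
        assert m2 == pytest.approx(m1, abs=1e-9)
        np.testing.assert_allclose(d1, d2, atol=1e-9)

    def test_distances_nonnegative_and_mean_above_min(self, rng):
        inf_pts = rng.uniform(-5, 5, (100, 3))
        sup_pts = rng.uniform(-5, 5, (100, 3))
        mean, d = least_distance_height(
            EndplateCloud(inf_pts, "inferior"), EndplateCloud(sup_pts, "superior")
        )
        assert np.all(d >= 0)
        assert mean >= d.min()

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            EndplateCloud(np.empty((0, 3)), "inferior")


class TestDiscFrame:
    def test_parallel_horizontal_grids_give_vertical_normal(self):
        frame = fit_disc_frame(
            EndplateCloud(grid_cloud(0.0), "inferior"),
            EndplateCloud(grid_cloud(4.0), "superior"),
        )
        assert abs(frame.normal @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-9)
        assert frame.normal[2] > 0  # oriented toward the superior plate

    def test_single_plane_input_recovers_that_plane(self, rng):
        pts = grid_cloud(1.5) + rng.normal(0, 1e-12, (100, 3))
        frame = fit_disc_frame(
            EndplateCloud(pts, "inferior"), EndplateCloud(pts + [0, 0, 1e-9], "superior")
        )
        assert abs(frame.normal @ [0, 0, 1]) == pytest.approx(1.0, abs=1e-6)
        assert frame.origin[2] == pytest.approx(1.5, abs=1e-6)

    def test_rotated_clouds_recover_rotated_frame(self, rng):
        inf_pts = rng.uniform(-5, 5, (400, 3)) * [1, 1, 0.01]
        sup_pts = inf_pts + [0, 0, 3.0]
        base = fit_disc_frame(
            EndplateCloud(inf_pts, "inferior"), EndplateCloud(sup_pts, "superior")
        )
        rot = Rotation.from_rotvec([0.0, 0.0, 0.4]).as_matrix()  # in-plane rotation
        rotated = fit_disc_frame(
            EndplateCloud(inf_pts @ rot.T, "inferior"),
            EndplateCloud(sup_pts @ rot.T, "superior"),
            anterior_hint=rot @ [1, 0, 0],
        )
        np.testing.assert_allclose(rotated.normal, rot @ base.normal, atol=1e-6)
        np.testing.assert_allclose(rotated.e_anterior, rot @ base.e_anterior, atol=1e-6)

    def test_collinear_cloud_rejected(self):
        line = np.column_stack([np.linspace(0, 1, 10), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            fit_disc_frame(
                EndplateCloud(line, "inferior"), EndplateCloud(line, "superior")
            )


def _uniform_ellipse_pair(rng, n=4000, a=7.5, b=5.0, gap=4.0):
    r = np.sqrt(rng.uniform(0, 1, n))
    th = rng.uniform(0, 2 * np.pi, n)
    x, y = a * r * np.cos(th), b * r * np.sin(th)
    inf = EndplateCloud(np.column_stack([x, y, np.zeros(n)]), "inferior")
    sup = EndplateCloud(np.column_stack([x, y, np.full(n, gap)]), "superior")
    return inf, sup


class TestZonePartition:
    def test_centroid_point_is_np(self, rng):
        inf, sup = _uniform_ellipse_pair(rng)
        pts = np.vstack([inf.points, [[0.0, 0.0, 0.0]]])
        inf2 = EndplateCloud(pts, "inferior")
        frame = fit_disc_frame(inf2, sup)
        part = partition_zones(inf2, frame)
        assert part.labels[-1] == "np"

    def test_axis_extremes_are_anterior_and_posterior(self, rng):
        inf, sup = _uniform_ellipse_pair(rng)
        pts = np.vstack([inf.points, [[7.4, 0.0, 0.0], [-7.4, 0.0, 0.0]]])
        inf2 = EndplateCloud(pts, "inferior")
        part = partition_zones(inf2, fit_disc_frame(inf2, sup))
        assert part.labels[-2] == "anterior"
        assert part.labels[-1] == "posterior"

    def test_labels_disjoint_and_cover(self, rng):
        inf, sup = _uniform_ellipse_pair(rng)
        part = partition_zones(inf, fit_disc_frame(inf, sup))
        counts = part.counts()
        assert sum(counts.values()) == len(inf)
        assert set(np.unique(part.labels)) <= set(ZONES)

    def test_np_area_fraction_matches_np_fraction_squared(self, rng):
        inf, sup = _uniform_ellipse_pair(rng, n=8000)
        part = partition_zones(inf, fit_disc_frame(inf, sup), np_fraction=0.5)
        frac = part.counts()["np"] / len(inf)
        assert frac == pytest.approx(0.25, abs=0.02)  # area scales as fraction^2
        for z in ZONES:
            assert part.counts()[z] > 0

    def test_np_fraction_validated(self, rng):
        inf, sup = _uniform_ellipse_pair(rng, n=100)
        frame = fit_disc_frame(inf, sup)
        with pytest.raises(ValueError):
            partition_zones(inf, frame, np_fraction=1.5)


class TestZoneHeights:
    def test_parallel_planes_uniform_height(self, rng):
        inf, sup = _uniform_ellipse_pair(rng, gap=4.0)
        part = partition_zones(inf, fit_disc_frame(inf, sup))
        tab = zone_heights(inf, sup, part)
        for z in ZONES:
            assert tab.zone_height_mm[z] == pytest.approx(4.0, abs=1e-9)
        assert tab.whole_height_mm == pytest.approx(4.0, abs=1e-9)

    def test_posterior_wedge_recovers_generator_truth(self, presets, flat_geometry):
        # posterior gap narrowed to half, roughness off: zone means must hit
        # the generator's recorded true gaps
        import dataclasses

        p0 = presets.preset("NI", 2)
        wedge = dataclasses.replace(
            p0,
            zone_gap_scale={"posterior": 0.5, "anterior": 1.0, "l_lateral": 1.0,
                            "r_lateral": 1.0, "np": 1.0},
        )
        geom = dataclasses.replace(flat_geometry, points_per_endplate=3000)
        inf, sup, true_gaps = generate_endplate_pair(wedge, geom, 11)
        part = partition_zones(inf, fit_disc_frame(inf, sup))
        tab = zone_heights(inf, sup, part)
        assert tab.zone_height_mm["posterior"] == pytest.approx(true_gaps["posterior"], rel=0.03)
        assert tab.zone_height_mm["anterior"] == pytest.approx(4.0, rel=0.01)

    def test_whole_height_is_count_weighted_zone_mean(self, rng):
        inf, sup = _uniform_ellipse_pair(rng, n=2000)
        sup.points[:, 2] += 0.3 * np.sin(sup.points[:, 0])
        part = partition_zones(inf, fit_disc_frame(inf, sup))
        tab = zone_heights(inf, sup, part)
        counts = part.counts()
        weighted = sum(tab.zone_height_mm[z] * counts[z] for z in ZONES) / len(inf)
        assert tab.whole_height_mm == pytest.approx(weighted, abs=1e-12)

    def test_empty_zone_is_nan_not_zero(self, rng):
        # quarter-disc cloud leaves some zones empty
        inf, sup = _uniform_ellipse_pair(rng, n=2000)
        keep = (inf.points[:, 0] > 1.0) & (inf.points[:, 1] > 0.5)
        inf2 = EndplateCloud(inf.points[keep], "inferior")
        sup2 = EndplateCloud(sup.points[keep], "superior")
        part = partition_zones(inf2, fit_disc_frame(inf2, sup2))
        forced = part.labels.copy()
        forced[forced == "posterior"] = "anterior"
        part.labels = forced
        tab = zone_heights(inf2, sup2, part)
        assert np.isnan(tab.zone_height_mm["posterior"])

    def test_density_robustness_under_superior_oversampling(self, presets, flat_geometry):
        p = presets.preset("MIA_0.1", 2)
        inf1, sup1, _ = generate_endplate_pair(p, flat_geometry, 3)
        h1, _ = least_distance_height(inf1, sup1)
        inf2, sup2, _ = generate_endplate_pair(p, flat_geometry, 3, n_superior=2 * len(sup1.points))
        h2, _ = least_distance_height(inf2, sup2)
        assert abs(h2 - h1) / h1 < 0.01


class TestThreeDDHI:
    def _tables(self, rng):
        inf, sup = _uniform_ellipse_pair(rng, gap=4.0)
        part = partition_zones(inf, fit_disc_frame(inf, sup))
        return zone_heights(inf, sup, part)

    def test_self_normalisation_gives_100_everywhere(self, rng):
        tab = self._tables(rng)
        res = three_d_dhi(tab, tab)
        for z in ZONES:
            assert res.zone_dhi_pct[z] == pytest.approx(100.0)
            assert res.zone_bin[z] == ">=90"

    @pytest.mark.parametrize(
        "value, label",
        [(68.75, "<70"), (70.0, "70-<80"), (79.999, "70-<80"), (80.0, "80-<90"),
         (89.999, "80-<90"), (90.0, ">=90"), (150.0, ">=90"), (69.999, "<70")],
    )
    def test_bin_boundaries_lower_inclusive(self, value, label):
        assert dhi_bin(value) == label

    def test_bin_labels_exhaustive(self):
        assert set(BIN_LABELS) == {"<70", "70-<80", "80-<90", ">=90"}

    def test_zone_matched_vs_whole_disc_modes(self, rng, presets, flat_geometry):
        import dataclasses

        p = dataclasses.replace(
            presets.preset("NI", 2),
            zone_gap_scale={"posterior": 0.5, "anterior": 1.0, "l_lateral": 1.0,
                            "r_lateral": 1.0, "np": 1.0},
        )
        inf, sup, _ = generate_endplate_pair(p, flat_geometry, 7)
        part = partition_zones(inf, fit_disc_frame(inf, sup))
        tab = zone_heights(inf, sup, part)
        rinf, rsup, _ = generate_endplate_pair(presets.preset("NI", 2), flat_geometry, 8)
        rpart = partition_zones(rinf, fit_disc_frame(rinf, rsup))
        ref = zone_heights(rinf, rsup, rpart)
        zm = three_d_dhi(tab, ref, mode="zone_matched")
        wd = three_d_dhi(tab, ref, mode="whole_disc")
        # reference is uniform, so the two normalisations agree here
        for z in ZONES:
            assert zm.zone_dhi_pct[z] == pytest.approx(wd.zone_dhi_pct[z], rel=1e-6)
        with pytest.raises(ValueError):
            three_d_dhi(tab, ref, mode="nope")
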