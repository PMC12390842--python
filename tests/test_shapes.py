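"""Ellipsoid fitting, surface meshes, alignment index, morphotype
clustering and Shannon-diversity statistics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from organomorph import shapes
from organomorph.synthgen import _ball_mask


def ellipsoid_cloud(radii, centre=(0, 0, 0), n=400, seed=0):
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return u * np.asarray(radii) + np.asarray(centre, float)


class TestEllipsoidFit:
    def test_exact_recovery_within_two_percent(self):
        fit = shapes.fit_ellipsoid(ellipsoid_cloud((20, 10, 5), (3, -2, 7)))
        assert fit.valid
        assert np.all(np.abs(fit.radii - (20, 10, 5)) / (20, 10, 5) < 0.02)
        assert np.allclose(fit.centre, (3, -2, 7), atol=0.2)
        # principal axes orthonormal
        assert np.allclose(fit.axes @ fit.axes.T, np.eye(3), atol=1e-6)

    def test_sphere_is_orientation_degenerate(self):
        fit = shapes.fit_ellipsoid(ellipsoid_cloud((10, 10, 10)))
        assert fit.valid
        assert fit.axis_ratio > 0.95

    def test_oversized_fit_invalid(self):
        fit = shapes.fit_ellipsoid(ellipsoid_cloud((200, 40, 40)))
        assert not fit.valid

    def test_degenerate_inputs_flagged_not_raised(self):
        assert not shapes.fit_ellipsoid(np.zeros((5, 3))).valid
        planar = ellipsoid_cloud((10, 10, 10))
        planar[:, 0] = 0.0
        assert not shapes.fit_ellipsoid(planar).valid

    def test_radii_recovery_under_five_percent_for_100_points(self):
        fit = shapes.fit_ellipsoid(ellipsoid_cloud((15, 9, 6), n=100, seed=3))
        assert fit.valid
        assert np.all(np.abs(fit.radii - (15, 9, 6)) / (15, 9, 6) < 0.05)


class TestOrganoidMesh:
    @pytest.fixture(scope="class")
    def ball_mesh(self):
        mask = _ball_mask((110, 110, 110), (1, 1, 1),
                          np.array([55.0] * 3), 50.0)
        return shapes.organoid_mesh(mask, (1, 1, 1), step_size=4)

    def test_normals_radial_on_ball(self, ball_mesh):
        radial = ball_mesh.vertices - 55.0
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        dots = np.abs(np.sum(ball_mesh.normals * radial, axis=1))
        assert dots.mean() >= 0.98

    def test_area_close_to_analytic(self, ball_mesh):
        import trimesh

        area = trimesh.Trimesh(ball_mesh.vertices, ball_mesh.faces).area
        assert abs(area - 4 * np.pi * 50**2) / (4 * np.pi * 50**2) < 0.05

    def test_normals_unit_length(self, ball_mesh):
        norms = np.linalg.norm(ball_mesh.normals, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-6)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            shapes.organoid_mesh(np.zeros((8, 8, 8), bool), (1, 1, 1))


class TestAlignmentIndex:
    def unit_mesh(self, normal):
        return shapes.SurfaceMesh(
            vertices=np.array([[0.0, 0.0, 0.0]]),
            faces=np.zeros((0, 3), dtype=int),
            normals=np.array([normal], dtype=float),
        )

    def fit_with_major(self, major):
        axes = np.eye(3)
        axes[0] = major
        return shapes.EllipsoidFit(
            centre=np.zeros(3), radii=np.array([5.0, 2.0, 2.0]),
            axes=axes, valid=True,
        )

    def test_parallel_is_exactly_one(self):
        idx = shapes.alignment_index(
            self.fit_with_major([0, 0, 1]), self.unit_mesh([0, 0, 1]),
            np.zeros(3),
        )
        assert idx == 1.0

    def test_orthogonal_is_exactly_zero(self):
        idx = shapes.alignment_index(
            self.fit_with_major([0, 1, 0]), self.unit_mesh([0, 0, 1]),
            np.zeros(3),
        )
        assert idx == 0.0

    def test_invalid_fit_rejected(self):
        bad = shapes.EllipsoidFit(np.zeros(3), np.zeros(3), np.eye(3), False)
        with pytest.raises(ValueError):
            shapes.alignment_index(bad, self.unit_mesh([0, 0, 1]), np.zeros(3))

    def test_sign_flip_and_scale_invariance(self):
        fit = self.fit_with_major([0, 0.6, 0.8])
        mesh = self.unit_mesh([0, 0, 1])
        base = shapes.alignment_index(fit, mesh, np.zeros(3))
        flipped = self.fit_with_major([0, -0.6, -0.8])
        assert shapes.alignment_index(flipped, mesh, np.zeros(3)) == base

    def test_radial_scene_high_tangential_scene_low(
        self, radial_alignment_table, tangential_alignment_table
    ):
        _, radial = radial_alignment_table
        _, tangential = tangential_alignment_table
        assert radial["alignment_index"].median() >= 0.95
        assert tangential["alignment_index"].median() <= 0.2


class TestClustering:
    @pytest.fixture(scope="class")
    def two_population_features(self):
        rng = np.random.default_rng(0)
        n = 150
        feat = pd.DataFrame(
            {
                "volume_um3": np.r_[rng.normal(300, 30, n),
                                    rng.normal(320, 30, n)],
                "axis_ratio": np.r_[rng.normal(0.9, 0.03, n),
                                    rng.normal(0.3, 0.03, n)],
                "surface_area_um2": np.r_[rng.normal(200, 20, n),
                                          rng.normal(400, 30, n)],
                "sphericity": np.r_[rng.normal(0.9, 0.02, n),
                                    rng.normal(0.5, 0.04, n)],
            }
        )
        return feat, np.r_[np.zeros(n), np.ones(n)]

    def test_separable_populations_recovered(self, two_population_features):
        feat, truth = two_population_features
        asg = shapes.cluster_morphotypes(feat, n_pcs=3, resolution=0.05,
                                         seed=0)
        assert adjusted_rand_score(truth, asg.clusters) >= 0.9

    def test_same_seed_same_partition(self, two_population_features):
        feat, _ = two_population_features
        a = shapes.cluster_morphotypes(feat, n_pcs=3, resolution=0.05, seed=0)
        b = shapes.cluster_morphotypes(feat, n_pcs=3, resolution=0.05, seed=0)
        assert adjusted_rand_score(a.clusters, b.clusters) == 1.0

    def test_duplicated_rows_cluster_together(self, two_population_features):
        feat, _ = two_population_features
        sub = feat.iloc[:60]
        doubled = pd.concat([sub, sub], ignore_index=True)
        asg = shapes.cluster_morphotypes(doubled, n_pcs=3, resolution=0.05,
                                         seed=0)
        first, second = asg.clusters[:60], asg.clusters[60:]
        assert adjusted_rand_score(first, second) == 1.0

    def test_too_few_structures_rejected(self, two_population_features):
        feat, _ = two_population_features
        with pytest.raises(ValueError):
            shapes.cluster_morphotypes(feat.iloc[:3], n_pcs=5)


class TestShannon:
    def test_reference_values(self):
        assert shapes.shannon_index([5, 5, 5, 5]) == pytest.approx(2.0)
        assert shapes.shannon_index([3, 1]) == pytest.approx(0.8113, abs=1e-4)
        assert shapes.shannon_index([7]) == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shapes.shannon_index([0, 0, 0])

    def test_uniform_maximal_and_concentration_decreases(self):
        uniform = shapes.shannon_index([4, 4, 4, 4])
        for counts in ([5, 4, 4, 3], [7, 4, 3, 2], [13, 1, 1, 1]):
            assert shapes.shannon_index(counts) < uniform
        assert shapes.shannon_index([7, 4, 3, 2]) > shapes.shannon_index(
            [13, 1, 1, 1]
        )


def make_assignments(n_per_cluster, condition="c", day=0, seed=0):
    rng = np.random.default_rng(seed)
    clusters = np.repeat(np.arange(len(n_per_cluster)), n_per_cluster)
    rng.shuffle(clusters)
    return pd.DataFrame(
        {"condition": condition, "day": day, "cluster": clusters}
    )


class TestBootstrap:
    def test_point_estimate_inside_ci(self):
        asg = make_assignments([30, 20, 10])
        out = shapes.bootstrap_shannon(asg, B=500, seed=1)
        row = out.iloc[0]
        assert row.ci_low <= row.shannon <= row.ci_high

    def test_same_seed_identical(self):
        asg = make_assignments([30, 20, 10])
        a = shapes.bootstrap_shannon(asg, B=200, seed=5)
        b = shapes.bootstrap_shannon(asg, B=200, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_ci_narrows_with_sample_size(self):
        widths = []
        for scale in (1, 20):
            asg = make_assignments([30 * scale, 20 * scale, 10 * scale])
            out = shapes.bootstrap_shannon(asg, B=300, seed=2)
            widths.append(out.iloc[0].ci_high - out.iloc[0].ci_low)
        assert widths[1] < widths[0] / 2

    def test_tiny_stratum_flagged(self):
        asg = pd.DataFrame(
            [{"condition": "c", "day": 0, "cluster": 0}]
        )
        out = shapes.bootstrap_shannon(asg, B=50, seed=0)
        assert not out.iloc[0].ci_defined


class TestProportions:
    def test_rows_sum_to_one(self):
        asg = pd.concat(
            [make_assignments([5, 5], day=0), make_assignments([9, 1], day=1)]
        )
        props = shapes.cluster_proportions(asg)
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-12)

    def test_single_cluster_day(self):
        props = shapes.cluster_proportions(make_assignments([7]))
        assert props.iloc[0, 0] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            shapes.cluster_proportions(pd.DataFrame())

    def test_shifted_composition_recovered(self):
        asg = pd.concat(
            [
                make_assignments([80, 20], condition="a"),
                make_assignments([20, 80], condition="b"),
            ]
        )
        props = shapes.cluster_proportions(asg)
        assert props.loc[("a", 0), 0] == pytest.approx(0.8)
        assert props.loc[("b", 0), 0] == pytest.approx(0.2)
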