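"""Geometric morphometrics: GPA, mirroring, distances, PCA, traits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylodecouple import shapes as sh

RNG = np.random.default_rng(42)


def cfg(coords, spec="s1", species="sp1", structure="oral_premaxilla"):
    return sh.LandmarkConfiguration(spec, species, structure, np.asarray(coords, float))


def rigid(coords, angle, shift, scale=1.0):
    R = np.array(
        [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
    )
    return scale * coords @ R.T + shift


TRIANGLE = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 0.9]])
QUAD = np.array([[0.0, 0.0], [1.0, 0.1], [0.9, 0.8], [0.1, 0.6]])


class TestGPA:
    def test_identical_configs_align_exactly(self):
        a = sh.gpa([cfg(TRIANGLE, "a"), cfg(TRIANGLE, "b")])
        x0, x1 = (c.coords for c in a.configurations)
        np.testing.assert_allclose(x0, x1, atol=1e-12)
        np.testing.assert_allclose(a.consensus, x0, atol=1e-12)

    def test_rigid_motion_and_scale_removed(self):
        moved = rigid(TRIANGLE, 0.7, [3.0, -2.0], scale=2.5)
        a = sh.gpa([cfg(TRIANGLE, "a"), cfg(moved, "b")])
        x0, x1 = (c.coords for c in a.configurations)
        np.testing.assert_allclose(x0, x1, atol=1e-8)

    def test_two_triangles_match_rotation_grid_oracle(self):
        """Summed squared residual to the consensus equals half the
        grid-search minimum of the pairwise superimposition."""
        t2 = np.array([[0.0, 0.1], [1.1, 0.0], [0.5, 0.7]])
        a = sh.gpa([cfg(TRIANGLE, "a"), cfg(t2, "b")])
        resid = sum(
            ((c.coords - a.consensus) ** 2).sum() for c in a.configurations
        )
        x = TRIANGLE - TRIANGLE.mean(0)
        x /= np.sqrt((x**2).sum())
        y = t2 - t2.mean(0)
        y /= np.sqrt((y**2).sum())
        best = np.inf
        for th in np.arange(0, 2 * np.pi, 0.001):
            R = np.array(
                [[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]
            )
            best = min(best, ((x - y @ R.T) ** 2).sum())
        assert resid == pytest.approx(best / 2, rel=1e-4)

    def test_mismatched_landmark_count_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            sh.gpa([cfg(TRIANGLE), cfg(QUAD, "q")])

    def test_degenerate_configuration_names_specimen(self):
        with pytest.raises(ValueError, match="bad_one"):
            sh.gpa([cfg(TRIANGLE), cfg(np.zeros((3, 2)), "bad_one")])

    @given(
        angle=st.floats(0, 2 * np.pi),
        dx=st.floats(-5, 5),
        dy=st.floats(-5, 5),
        logs=st.floats(-1, 1),
    )
    @settings(max_examples=25, deadline=None)
    def test_invariance_under_common_rigid_motion(self, angle, dx, dy, logs):
        configs = [cfg(TRIANGLE, "a"), cfg(QUAD[:3], "b")]
        moved = [
            cfg(rigid(c.coords, angle, [dx, dy], np.exp(logs)), c.specimen_id)
            for c in configs
        ]
        a0 = sh.gpa(configs)
        a1 = sh.gpa(moved)
        for c0, c1 in zip(a0.configurations, a1.configurations):
            np.testing.assert_allclose(c1.coords, c0.coords, atol=1e-8)


class TestMirror:
    @staticmethod
    def half_config(n_mid=5, n_pair=6, seed=0):
        rng = np.random.default_rng(seed)
        mid = np.column_stack(
            [np.zeros(n_mid), np.linspace(-1, 1, n_mid), rng.normal(0, 0.2, n_mid)]
        )
        pair = np.column_stack(
            [-0.5 - rng.random(n_pair), rng.normal(0, 1, n_pair), rng.normal(0, 0.3, n_pair)]
        )
        return cfg(np.vstack([mid, pair]), structure="lpj_half")

    def test_output_landmark_count(self):
        c = self.half_config()
        full = sh.mirror_landmarks(c, list(range(5)), list(range(5, 11)))
        assert full.n_landmarks == 5 + 2 * 6
        assert full.structure == "lpj_full"

    def test_reflection_across_known_plane(self):
        c = self.half_config()
        full = sh.mirror_landmarks(c, list(range(5)), list(range(5, 11)))
        # template midline lies in the x=0 plane
        mirrored = full.coords[11:]
        np.testing.assert_allclose(mirrored[:, 0], -c.coords[5:, 0], atol=1e-9)
        np.testing.assert_allclose(mirrored[:, 1:], c.coords[5:, 1:], atol=1e-9)

    def test_object_symmetry_residual(self):
        c = self.half_config()
        full = sh.mirror_landmarks(c, list(range(5)), list(range(5, 11)))
        twice = sh.mirror_landmarks(
            sh.LandmarkConfiguration("s", "sp", "lpj_half",
                                     np.vstack([full.coords[:5], full.coords[11:]])),
            list(range(5)), list(range(5, 11)),
        )
        np.testing.assert_allclose(twice.coords[11:], c.coords[5:], atol=1e-9)

    def test_collinear_midline_rejected(self):
        mid = np.column_stack([np.zeros(4), np.linspace(0, 1, 4), np.zeros(4)])
        pair = np.array([[-1.0, 0.0, 0.5]])
        c = cfg(np.vstack([mid, pair]), structure="lpj_half")
        with pytest.raises(ValueError, match="collinear"):
            sh.mirror_landmarks(c, [0, 1, 2, 3], [4])


class TestSubsetExtraction:
    @staticmethod
    def dataset(n=4, seed=1):
        rng = np.random.default_rng(seed)
        base = rng.normal(0, 1, (10, 2))
        configs = [
            cfg(base + rng.normal(0, 0.05, (10, 2)), f"s{i}", f"sp{i}",
                "oral_full_skeleton")
            for i in range(n)
        ]
        return sh.gpa(configs)

    def test_centroid_at_origin(self):
        subs = sh.extract_recentered_subset(self.dataset(), [0, 2, 5, 7])
        for s in subs:
            np.testing.assert_allclose(s.coords.mean(0), 0.0, atol=1e-12)

    def test_relative_size_preserved(self):
        aligned = self.dataset()
        subs = sh.extract_recentered_subset(aligned, [0, 2, 5, 7])
        # size differences in the full alignment carry into the subsets
        full_sub_sizes = [
            sh.centroid_size(c.coords[[0, 2, 5, 7]])
            for c in aligned.configurations
        ]
        sub_sizes = [sh.centroid_size(s.coords) for s in subs]
        np.testing.assert_allclose(sub_sizes, full_sub_sizes, atol=1e-12)

    def test_angles_unchanged_by_extraction(self):
        aligned = self.dataset()
        subs = sh.extract_recentered_subset(aligned, [0, 2, 5, 7])
        for c, s in zip(aligned.configurations, subs):
            v_full = c.coords[2] - c.coords[0]
            v_sub = s.coords[1] - s.coords[0]
            np.testing.assert_allclose(v_sub, v_full, atol=1e-12)

    def test_wrong_subset_length_rejected(self):
        with pytest.raises(ValueError, match="4 landmarks"):
            sh.extract_recentered_subset(self.dataset(), [0, 1, 2])


class TestMeanShapeAndDistance:
    def test_mean_of_noiseless_specimens_is_template(self):
        configs = [cfg(QUAD, f"s{i}") for i in range(10)]
        m = sh.mean_shape(configs)
        np.testing.assert_allclose(m.coords, QUAD, atol=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sh.mean_shape([])

    def test_distance_zero_for_rotated_copy(self):
        rot = rigid(QUAD, 1.2, [0.5, 0.5])
        assert sh.procrustes_distance(QUAD, rot) == pytest.approx(0.0, abs=1e-9)

    def test_distance_matches_rotation_grid(self):
        a = QUAD
        b = np.array([[0.0, 0.0], [1.0, 0.3], [0.7, 0.9], [0.0, 0.5]])
        d = sh.procrustes_distance(a, b)
        x = a - a.mean(0); x /= np.sqrt((x**2).sum())
        y = b - b.mean(0); y /= np.sqrt((y**2).sum())
        best = np.inf
        for th in np.arange(0, 2 * np.pi, 0.001):
            R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            best = min(best, ((x - y @ R.T) ** 2).sum())
        assert d == pytest.approx(np.sqrt(best), rel=1e-4)

    def test_triangle_inequality_unit_size(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a, b, c = (rng.normal(0, 1, (4, 2)) for _ in range(3))
            dab = sh.procrustes_distance(a, b)
            dbc = sh.procrustes_distance(b, c)
            dac = sh.procrustes_distance(a, c)
            assert dac <= dab + dbc + 1e-9


class TestShapePCA:
    @staticmethod
    def rank1_means(n=8):
        basis = np.zeros(8)
        basis[0] = 1.0
        return [
            sh.SpeciesMeanShape(f"sp{i}", (QUAD.ravel() + 0.1 * i * basis).reshape(4, 2))
            for i in range(n)
        ]

    def test_rank1_variation_on_pc1(self):
        pca = sh.shape_pca(self.rank1_means())
        assert pca.percent_variance[0] == pytest.approx(100.0, abs=1e-8)

    def test_percent_variance_sums_to_100(self):
        rng = np.random.default_rng(3)
        means = [
            sh.SpeciesMeanShape(f"sp{i}", QUAD + rng.normal(0, 0.1, (4, 2)))
            for i in range(10)
        ]
        pca = sh.shape_pca(means)
        assert pca.percent_variance.sum() == pytest.approx(100.0, abs=1e-6)
        np.testing.assert_allclose(pca.scores.mean(0), 0.0, atol=1e-12)

    def test_scores_preserve_distances(self):
        rng = np.random.default_rng(4)
        means = [
            sh.SpeciesMeanShape(f"sp{i}", QUAD + rng.normal(0, 0.1, (4, 2)))
            for i in range(6)
        ]
        pca = sh.shape_pca(means)
        X = np.array([m.coords.ravel() for m in means])
        Xc = X - X.mean(0)
        d_flat = np.linalg.norm(Xc[:, None] - Xc[None, :], axis=-1)
        d_pca = np.linalg.norm(
            pca.scores[:, None] - pca.scores[None, :], axis=-1
        )
        np.testing.assert_allclose(d_pca, d_flat, atol=1e-9)

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError, match="3 species"):
            sh.shape_pca(self.rank1_means(2))


class TestMetricTraits:
    def test_right_angle(self):
        coords = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        t = sh.metric_traits(
            cfg(coords), {"ang": {"kind": "angle", "landmarks": (0, 1, 2)}}
        )
        assert t["ang"] == pytest.approx(90.0)

    def test_square_side_ratio(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        t = sh.metric_traits(
            cfg(sq),
            {"ratio": {"kind": "distance_ratio", "numerator": (0, 1),
                       "denominator": (1, 2)}},
        )
        assert t["ratio"] == pytest.approx(1.0)

    def test_nested_square_area_ratio(self):
        outer = np.array([[0, 0], [2, 0], [2, 2], [0, 2]], dtype=float)
        inner = outer / 2 + 0.5
        coords = np.vstack([outer, inner])
        t = sh.metric_traits(
            cfg(coords),
            {"teeth": {"kind": "area_ratio", "numerator": (4, 5, 6, 7),
                       "denominator": (0, 1, 2, 3)}},
        )
        assert t["teeth"] == pytest.approx(0.25)

    @given(angle=st.floats(0, 2 * np.pi), dx=st.floats(-3, 3))
    @settings(max_examples=20, deadline=None)
    def test_invariance_to_rotation_translation(self, angle, dx):
        spec = {
            "ang": {"kind": "angle", "landmarks": (0, 1, 2)},
            "rat": {"kind": "distance_ratio", "numerator": (0, 1),
                    "denominator": (2, 3)},
            "dcs": {"kind": "distance_over_centroid_size", "landmarks": (0, 3)},
        }
        t0 = sh.metric_traits(cfg(QUAD), spec)
        t1 = sh.metric_traits(cfg(rigid(QUAD, angle, [dx, 0.0])), spec)
        for k in spec:
            assert t1[k] == pytest.approx(t0[k], abs=1e-9)

    def test_scale_invariance_of_size_normalized_traits(self):
        spec = {
            "dcs": {"kind": "distance_over_centroid_size", "landmarks": (0, 3)},
            "area": {"kind": "area_ratio", "numerator": (0, 1, 2),
                     "denominator": (0, 1, 2, 3)},
        }
        t0 = sh.metric_traits(cfg(QUAD), spec)
        t1 = sh.metric_traits(cfg(QUAD * 7.3), spec)
        for k in spec:
            assert t1[k] == pytest.approx(t0[k], abs=1e-12)

    def test_coincident_landmarks_rejected(self):
        coords = np.array([[0, 0], [0, 0], [1, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError, match="zero-length"):
            sh.metric_traits(
                cfg(coords), {"a": {"kind": "angle", "landmarks": (0, 1, 2)}}
            )


class TestIO:
    def test_tps_round_trip(self):
        configs = [
            cfg(QUAD, "sp1_01", "sp1"),
            cfg(QUAD + 0.1, "sp1_02", "sp1"),
        ]
        text = sh.write_tps(configs)
        back = sh.read_tps(text, "oral_premaxilla")
        assert [c.specimen_id for c in back] == ["sp1_01", "sp1_02"]
        assert [c.species_id for c in back] == ["sp1", "sp1"]
        np.testing.assert_allclose(back[1].coords, QUAD + 0.1, atol=1e-9)

    def test_tps_3d_uses_lm3(self):
        c = cfg(np.random.default_rng(0).normal(0, 1, (5, 3)),
                structure="lpj_half")
        text = sh.write_tps([c])
        assert text.startswith("LM3=5")
        back = sh.read_tps(text, "lpj_half")
        np.testing.assert_allclose(back[0].coords, c.coords, atol=1e-9)

    def test_csv_round_trip(self):
        import io as _io
        configs = [cfg(QUAD, "a_01", "a"), cfg(QUAD * 2, "b_01", "b")]
        text = sh.write_landmark_csv(configs)
        back = sh.read_landmark_csv(_io.StringIO(text), "oral_premaxilla")
        assert {c.species_id for c in back} == {"a", "b"}
        by_id = {c.specimen_id: c for c in back}
        np.testing.assert_allclose(by_id["b_01"].coords, QUAD * 2, atol=1e-9)
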