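import numpy as np
import pytest

from nasoflow import (
    DuctGeometry,
    build_ssm,
    default_variation_spec,
    generate_corpus,
    hausdorff_distance,
    hausdorff_distance_symmetric,
    mean_shape,
    mean_surface_distance,
    mirror_augment,
    mirror_subject,
    modes_for_variance,
    synthesize_shape,
)


class TestBuildSsm:
    def test_identical_corpus_zero_variance(self, small_template):
        g = small_template.base
        model = build_ssm([g, g, g])
        assert model.n_modes == 0
        assert np.allclose(model.mean_vertices, g.vertices, atol=1e-12)

    def test_two_member_midpoint(self, small_corpus):
        a, b = small_corpus.members[:2]
        model = build_ssm([a, b])
        assert model.n_modes == 1
        assert np.allclose(model.mean_vertices, 0.5 * (a.vertices + b.vertices))

    def test_topology_mismatch_names_member(self, small_corpus):
        a = small_corpus.members[0]
        alien = DuctGeometry(
            vertices=a.vertices.copy(), triangles=a.triangles[::-1].copy()
        )
        with pytest.raises(ValueError, match="member 1"):
            build_ssm([a, alien])

    def test_noise_free_recovery_of_mode_subspace(self, small_template):
        k = 3
        spec = default_variation_spec(
            small_template, n_modes=k, noise_sd=0.0, seed=21
        )
        c = generate_corpus(small_template, spec, 50)
        model = build_ssm(c)
        assert model.n_modes == k
        truth = spec.mode_fields.reshape(k, -1)
        p_model = model.modes.T @ model.modes
        p_truth = truth.T @ truth
        assert np.abs(p_model - p_truth).max() < 1e-8

    def test_variance_conservation(self, small_corpus):
        model = build_ssm(small_corpus)
        x = np.stack([m.vertices.reshape(-1) for m in small_corpus.members])
        xc = x - x.mean(axis=0)
        total = np.sum(xc**2) / (x.shape[0] - 1)
        assert model.total_variance == pytest.approx(total, rel=1e-8)

    def test_reconstruction_identity(self, small_corpus):
        model = build_ssm(small_corpus)
        g = small_corpus.members[2]
        rec = synthesize_shape(model, model.project(g))
        assert np.abs(rec.vertices - g.vertices).max() < 1e-8

    def test_mode_orthonormality(self, small_corpus):
        model = build_ssm(small_corpus)
        gram = model.modes @ model.modes.T
        assert np.abs(gram - np.eye(model.n_modes)).max() < 1e-10

    def test_rigid_alignment_absorbs_translation(self, small_corpus):
        a = small_corpus.members[0]
        b = a.with_vertices(a.vertices + np.array([5.0, -2.0, 1.0]), recompute=False)
        assert build_ssm([a, b]).total_variance > 1.0
        assert build_ssm([a, b], align=True).total_variance < 1e-10


class TestMeanShape:
    def test_mirror_augmented_mean_symmetric(self, small_corpus):
        model = build_ssm(mirror_augment(small_corpus))
        avg = mean_shape(model)
        assert np.abs(mirror_subject(avg).vertices - avg.vertices).max() < 1e-9

    def test_mean_ring_area_between_members(self, small_corpus):
        a, b = small_corpus.members[:2]
        avg = mean_shape(build_ssm([a, b]))
        for side in ("left", "right"):
            lo = np.minimum(a.profiles[side].area_mm2, b.profiles[side].area_mm2)
            hi = np.maximum(a.profiles[side].area_mm2, b.profiles[side].area_mm2)
            mid = avg.profiles[side].area_mm2
            assert np.all(mid >= lo - 1e-9) and np.all(mid <= hi + 1e-9)

    def test_vertexwise_mean_consistency(self, small_corpus):
        model = build_ssm(small_corpus)
        manual = np.mean([m.vertices for m in small_corpus.members], axis=0)
        assert np.array_equal(mean_shape(model).vertices, model.mean_vertices)
        assert np.allclose(model.mean_vertices, manual)


class TestModesForVariance:
    @pytest.mark.parametrize(
        "fraction,expected", [(0.90, 3), (0.95, 4), (0.40, 1), (1.0, 4)]
    )
    def test_cumulative_thresholds(self, small_template, fraction, expected):
        # model with prescribed variances [4, 3, 2, 1]
        model = build_ssm([small_template.base] * 2 + [small_template.base])
        model.variances = np.array([4.0, 3.0, 2.0, 1.0])
        model.modes = np.eye(4, model.mean_vertices.size)
        assert modes_for_variance(model, fraction) == expected

    def test_zero_variance_errors(self, small_template):
        model = build_ssm([small_template.base, small_template.base])
        with pytest.raises(ValueError):
            modes_for_variance(model, 0.95)


class TestSynthesize:
    def test_zero_weights_gives_mean(self, small_corpus):
        model = build_ssm(small_corpus)
        g = synthesize_shape(model, np.zeros(model.n_modes))
        assert np.array_equal(g.vertices, mean_shape(model).vertices)

    def test_too_many_weights_rejected(self, small_corpus):
        model = build_ssm(small_corpus)
        with pytest.raises(ValueError):
            synthesize_shape(model, np.zeros(model.n_modes + 1))

    def test_mirrored_member_weights_flip_by_mode_symmetry(self, small_corpus):
        """In a mirror-augmented model every mode is symmetric or
        antisymmetric under mirroring, and a member's mirror has the same
        weights up to those per-mode signs."""
        aug = mirror_augment(small_corpus)
        model = build_ssm(aug)
        g = aug.members[0]
        gm = aug.members[1]  # its mirror
        ref = model.reference
        perm, flip = ref.mirror_map, np.array([-1.0, 1.0, 1.0])

        signs = np.empty(model.n_modes)
        for k in range(model.n_modes):
            f = model.modes[k].reshape(-1, 3)
            mf = (f[perm] * flip).reshape(-1)
            s = float(np.sign(mf @ model.modes[k]))
            assert np.abs(mf - s * model.modes[k]).max() < 1e-6
            signs[k] = s
        w, wm = model.project(g), model.project(gm)
        assert np.abs(wm - signs * w).max() < 1e-6


class TestSurfaceDistances:
    def test_identical_meshes_zero(self, small_corpus):
        g = small_corpus.members[0]
        assert hausdorff_distance(g, g) == 0.0
        assert mean_surface_distance(g, g) == 0.0

    def test_point_clouds(self):
        a = DuctGeometry(np.zeros((1, 3)), np.zeros((0, 3), dtype=int))
        b = DuctGeometry(np.array([[3.0, 0.0, 0.0]]), np.zeros((0, 3), dtype=int))
        assert hausdorff_distance(a, b) == pytest.approx(3.0)

    def test_scaled_ring(self):
        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        ring = np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
        a = DuctGeometry(ring, np.zeros((0, 3), dtype=int))
        b = DuctGeometry(1.1 * ring, np.zeros((0, 3), dtype=int))
        assert hausdorff_distance(a, b) == pytest.approx(0.1, abs=1e-6)
        assert mean_surface_distance(a, b) == pytest.approx(0.1, abs=1e-6)

    def test_translated_planar_patch_mean_distance(self):
        quad = np.array(
            [[0, 0, 0], [0, 1, 0], [0, 1, 1], [0, 0, 1]], dtype=float
        )
        tris = np.array([[0, 1, 2], [0, 2, 3]])
        a = DuctGeometry(quad, tris)
        d = 0.37
        b = DuctGeometry(quad + np.array([d, 0, 0]), tris)
        assert mean_surface_distance(a, b) == pytest.approx(d, rel=1e-12)

    def test_translation_invariance(self, small_corpus):
        a, b = small_corpus.members[:2]
        t = np.array([1.0, -2.0, 3.0])
        at = a.with_vertices(a.vertices + t, recompute=False)
        bt = b.with_vertices(b.vertices + t, recompute=False)
        assert hausdorff_distance(at, bt) == pytest.approx(
            hausdorff_distance(a, b), rel=1e-9
        )

    def test_symmetric_variant_upper_bounds_each_direction(self, small_corpus):
        a, b = small_corpus.members[:2]
        hs = hausdorff_distance_symmetric(a, b)
        assert hs >= hausdorff_distance(a, b) - 1e-12
        assert hs >= hausdorff_distance(b, a) - 1e-12

    def test_empty_mesh_errors(self, small_corpus):
        empty = DuctGeometry(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError):
            hausdorff_distance(small_corpus.members[0], empty)
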