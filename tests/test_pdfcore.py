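import math

import numpy as np
import pytest

import smlmfit as sf
from smlmfit.models import GeometricModel, _model_points
from smlmfit.pdfcore import (Component, CompositeSpec, DensityImage,
                             DiscretizedModel, Pose, angles_from_matrix,
                             apply_pose, background_stats, composite_pdf,
                             compose_poses, cross_correlation_score,
                             discretize, invert_pose, log_likelihood,
                             max_spacing, mix_background, pdf_discrete,
                             pdf_image, rotation_matrix)
from tests.conftest import make_site


class TestRotationMatrix:
    def test_identity(self):
        np.testing.assert_allclose(rotation_matrix(0, 0, 0), np.eye(3))

    def test_quarter_turn_about_z(self):
        # substituting γ = π/2 maps the x unit vector onto y
        R = rotation_matrix(0, 0, math.pi / 2)
        np.testing.assert_allclose(R @ [1, 0, 0], [0, 1, 0], atol=1e-15)

    def test_rotation_properties(self, rng):
        for _ in range(20):
            a, b, g = rng.uniform(-math.pi, math.pi, 3)
            R = rotation_matrix(a, b, g)
            assert math.isclose(np.linalg.det(R), 1.0, abs_tol=1e-12)
            np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-12)

    def test_angle_extraction_inverts(self, rng):
        for _ in range(20):
            a, b, g = rng.uniform(-1.4, 1.4, 3)
            back = angles_from_matrix(rotation_matrix(a, b, g))
            np.testing.assert_allclose(back, (a, b, g), atol=1e-10)


class TestApplyPose:
    def test_identity_pose_is_noop(self, cloud2d):
        out = apply_pose(cloud2d, Pose(x0=(0.0, 0.0)), "data-to-model")
        np.testing.assert_array_equal(out.coords, cloud2d.coords)

    def test_forward_then_reverse_roundtrip(self, rng):
        pts = rng.normal(0, 30, size=(15, 3))
        dm = DiscretizedModel(pts, np.ones(15), spacing=1.0)
        pose = Pose(x0=(4.0, -7.0, 2.0), angles=(0.3, -0.2, 1.1),
                    scale=(1.2, 0.9, 1.0))
        there = apply_pose(dm, pose, "model-to-data")
        back = apply_pose(there, pose, "data-to-model")
        np.testing.assert_allclose(back.points, pts, atol=1e-10)

    def test_pure_translation_reverse(self, rng):
        locs = sf.LocalizationSet(rng.normal(0, 10, (5, 3)),
                                  np.full((5, 3), 2.0))
        out = apply_pose(locs, Pose(x0=(10.0, 0.0, 0.0)), "data-to-model")
        np.testing.assert_allclose(out.coords, locs.coords - [10, 0, 0])
        np.testing.assert_array_equal(out.precisions, locs.precisions)

    def test_compose_and_invert(self, rng):
        p1 = Pose(x0=(3.0, -2.0, 5.0), angles=(0.2, 0.4, -0.6))
        p2 = Pose(x0=(-1.0, 7.0, 0.5), angles=(-0.3, 0.1, 0.9))
        pts = rng.normal(0, 20, size=(10, 3))
        dm = DiscretizedModel(pts, np.ones(10), 1.0)
        seq = apply_pose(apply_pose(dm, p2, "model-to-data"), p1,
                         "model-to-data")
        combined = apply_pose(dm, compose_poses(p1, p2), "model-to-data")
        np.testing.assert_allclose(combined.points, seq.points, atol=1e-9)
        inv = apply_pose(seq, invert_pose(compose_poses(p1, p2)),
                         "model-to-data")
        np.testing.assert_allclose(inv.points, pts, atol=1e-9)


class TestDiscretize:
    def test_spacing_bound(self, rng):
        # min σ = 4 nm with no clamp: spacing must be < 3 nm
        sig = np.full((10, 3), 7.0)
        sig[3, 1] = 4.0
        locs = sf.LocalizationSet(rng.normal(0, 20, (10, 3)), sig)
        assert math.isclose(max_spacing(locs), 3.0)
        dm = discretize(sf.get_model("npc_dual_ring"), locs)
        assert dm.spacing < 3.0
        # J >= ceil(2πr/δ) samples per ring
        assert dm.n_points >= 2 * math.ceil(2 * math.pi * 53.4 / 3.0)

    def test_sigma_min_coarsens(self, rng):
        sig = np.full((10, 3), 4.0)
        locs = sf.LocalizationSet(rng.normal(0, 20, (10, 3)), sig)
        fine = discretize(sf.get_model("npc_dual_ring"), locs)
        coarse = discretize(sf.get_model("npc_dual_ring"), locs,
                            sigma_min=8.0)
        assert coarse.n_points < fine.n_points

    def test_uniform_line_weights_equal(self, rng):
        locs = sf.LocalizationSet(rng.normal(0, 20, (5, 3)),
                                  np.full((5, 3), 6.0))
        dm = discretize(sf.get_model("npc_dual_ring"), locs)
        assert np.allclose(dm.weights, dm.weights[0])


class TestPdfDiscrete:
    def test_gaussian_peak_2d(self):
        locs = sf.LocalizationSet([[0.0, 0.0]], [[1.0, 1.0]])
        dm = DiscretizedModel(np.zeros((1, 2)), np.ones(1), 1.0)
        val = pdf_discrete(locs, dm)[0]
        assert math.isclose(val, 1.0 / (2 * math.pi), rel_tol=1e-14)

    def test_gaussian_peak_3d(self):
        locs = sf.LocalizationSet([[0.0, 0.0, 0.0]], [[1.0, 1.0, 1.0]])
        dm = DiscretizedModel(np.zeros((1, 3)), np.ones(1), 1.0)
        val = pdf_discrete(locs, dm)[0]
        assert math.isclose(val, (2 * math.pi) ** -1.5, rel_tol=1e-14)

    def test_extra_sigma_inflates_variance(self):
        # σ = 1, ε = 1: per-axis variance 2, peak 1/(2π·2)
        locs = sf.LocalizationSet([[0.0, 0.0]], [[1.0, 1.0]])
        dm = DiscretizedModel(np.zeros((1, 2)), np.ones(1), 1.0)
        val = pdf_discrete(locs, dm, extra_sigma=1.0)[0]
        assert math.isclose(val, 1.0 / (4 * math.pi), rel_tol=1e-14)

    def test_empty_model_rejected(self):
        locs = sf.LocalizationSet([[0.0, 0.0]], [[1.0, 1.0]])
        with pytest.raises(ValueError):
            DiscretizedModel(np.empty((0, 2)), np.empty(0), 1.0)

    def test_unit_weights_match_weighted_form(self, rng):
        """The plain mixture is the weighted mixture with all q_j equal."""
        pts = rng.normal(0, 20, size=(12, 3))
        locs = sf.LocalizationSet(rng.normal(0, 20, (8, 3)),
                                  rng.uniform(2, 9, (8, 3)))
        a = pdf_discrete(locs, DiscretizedModel(pts, np.ones(12), 1.0))
        b = pdf_discrete(locs, DiscretizedModel(pts, np.full(12, 3.7), 1.0))
        np.testing.assert_allclose(a, b, rtol=1e-14)


class TestPdfImage:
    def test_uniform_density_is_flat(self, rng):
        site = make_site(rng.uniform(-40, 40, (6, 2)),
                         np.full((6, 2), 5.0), side=200.0)
        n = 100
        img = DensityImage(np.ones((n, n)), origin=np.full(2, -99.0),
                           cell=2.0)
        dens = pdf_image(site.localizations, img, mean_sigma=5.0)
        np.testing.assert_allclose(dens, 200.0**-2, rtol=1e-6)

    def test_hot_pixel_matches_discrete_gaussian(self):
        # a delta-like density blurred with ⟨σ⟩ equals the single-point
        # Gaussian mixture within grid error
        n, cell = 201, 1.0
        vals = np.zeros((n, n))
        vals[100, 100] = 1.0
        img = DensityImage(vals, origin=np.full(2, -100.0), cell=cell)
        coords = np.array([[0.0, 0.0], [5.0, 3.0], [-8.0, 12.0]])
        locs = sf.LocalizationSet(coords, np.full((3, 2), 6.0))
        dens = pdf_image(locs, img, mean_sigma=6.0)
        dm = DiscretizedModel(np.zeros((1, 2)), np.ones(1), 1.0)
        ref = pdf_discrete(locs, dm)
        np.testing.assert_allclose(dens, ref, rtol=5e-3)

    def test_normalizes_over_grid(self, rng):
        n, cell = 120, 2.0
        vals = rng.random((n, n))
        img = DensityImage(vals, origin=np.full(2, -(n - 1) * cell / 2),
                           cell=cell)
        locs = sf.LocalizationSet(rng.uniform(-60, 60, (4, 2)),
                                  np.full((4, 2), 5.0))
        blurred = pdf_image(locs, img, mean_sigma=4.0)
        assert (blurred >= 0).all()
        # numerical integral of the blurred, normalized image is 1
        from scipy import ndimage
        sd = 4.0 / cell
        ref = ndimage.gaussian_filter(vals, sigma=sd, mode="constant")
        assert math.isclose((ref / (ref.sum() * cell**2)).sum() * cell**2,
                            1.0, rel_tol=1e-9)

    def test_all_zero_rejected(self):
        img = DensityImage(np.zeros((10, 10)), origin=np.zeros(2), cell=1.0)
        locs = sf.LocalizationSet([[0.0, 0.0]], [[2.0, 2.0]])
        with pytest.raises(ValueError):
            pdf_image(locs, img, mean_sigma=2.0)


class TestBackground:
    def test_pure_background_density(self, rng):
        site = make_site(rng.uniform(-50, 50, (10, 2)),
                         np.full((10, 2), 3.0), side=100.0)
        dens = mix_background(np.zeros(10), 1.0, site)
        np.testing.assert_allclose(dens, 1e-4)

    def test_zero_weight_keeps_model(self, rng):
        site = make_site(rng.uniform(-50, 50, (5, 2)),
                         np.full((5, 2), 3.0), side=100.0)
        m = rng.random(5)
        np.testing.assert_array_equal(mix_background(m, 0.0, site), m)

    def test_half_mix(self, rng):
        site = make_site(rng.uniform(-50, 50, (5, 2)),
                         np.full((5, 2), 3.0), side=100.0)
        m = rng.random(5)
        np.testing.assert_allclose(mix_background(m, 0.5, site),
                                   0.5 * m + 0.5 * 1e-4)

    def test_background_bookkeeping(self):
        d = background_stats(200, 0.25, 100.0)
        assert d["K_bg"] == 50.0
        assert math.isclose(d["rho_bg"], 50.0 / 1e4)
        assert d["K_m"] == 150.0


def _point_model(pts, channels=None):
    pts = np.atleast_2d(pts)

    def _eval(v, spacing):
        return _model_points(pts, channels=channels)

    return GeometricModel("pts", "discrete-points", pts.shape[1], (), _eval)


class TestCompositeAndLikelihood:
    def test_single_component_equals_mixed_pdf(self, rng):
        site = make_site(rng.uniform(-30, 30, (12, 3)),
                         rng.uniform(3, 8, (12, 3)))
        pts = rng.normal(0, 20, (6, 3))
        spec = CompositeSpec([Component(_point_model(pts), weight=0.8)],
                             bg_weight=0.2)
        dens = composite_pdf(site.localizations, spec, site)
        dm = DiscretizedModel(pts, np.ones(6), 1.0)
        direct = mix_background(pdf_discrete(site.localizations, dm), 0.2,
                                site)
        np.testing.assert_allclose(dens, direct, rtol=1e-12)

    def test_two_identical_components_equal_one(self, rng):
        site = make_site(rng.uniform(-30, 30, (10, 3)),
                         rng.uniform(3, 8, (10, 3)))
        pts = rng.normal(0, 20, (5, 3))
        one = CompositeSpec([Component(_point_model(pts), weight=1.0)])
        two = CompositeSpec([Component(_point_model(pts), weight=0.5),
                             Component(_point_model(pts), weight=0.5)])
        np.testing.assert_allclose(
            composite_pdf(site.localizations, one, site),
            composite_pdf(site.localizations, two, site), rtol=1e-12)

    def test_zero_relative_pose_colocates(self, rng):
        site = make_site(rng.uniform(-30, 30, (10, 3)),
                         rng.uniform(3, 8, (10, 3)))
        pts = rng.normal(0, 15, (5, 3))
        base = Pose(x0=(5.0, -3.0, 2.0), angles=(0.1, 0.2, 0.3))
        spec = CompositeSpec([
            Component(_point_model(pts), pose=base, weight=0.5),
            Component(_point_model(pts), pose=Pose(), weight=0.5)])
        one = CompositeSpec([Component(_point_model(pts), pose=base,
                                       weight=1.0)])
        np.testing.assert_allclose(
            composite_pdf(site.localizations, spec, site),
            composite_pdf(site.localizations, one, site), rtol=1e-9)

    def test_weight_sum_enforced(self):
        with pytest.raises(ValueError):
            CompositeSpec([Component(_point_model(np.zeros((1, 3))),
                                     weight=0.5)], bg_weight=0.2)

    def test_pure_background_loglik(self, rng):
        # 10 localizations, uniform background over a 100 nm 2D site
        site = make_site(rng.uniform(-50, 50, (10, 2)),
                         np.full((10, 2), 3.0), side=100.0)
        spec = CompositeSpec([Component(_point_model(np.zeros((1, 2))),
                                        weight=0.0)], bg_weight=1.0)
        ll, _ = log_likelihood(site.localizations, spec, site)
        assert math.isclose(ll, 10 * math.log(1e-4), rel_tol=1e-12)

    def test_ratio_color_weights(self, rng):
        coords = rng.uniform(-30, 30, (200, 2))
        ch = np.repeat([0, 1], 100)
        site = make_site(coords, np.full((200, 2), 4.0), channel=ch)
        spec = CompositeSpec(
            [Component(_point_model(np.zeros((1, 2))), weight=0.9, channel=0),
             Component(_point_model(np.zeros((1, 2))), weight=0.9, channel=1)],
            bg_weight=0.1, color_weights="ratio")
        ll, info = log_likelihood(site.localizations, spec, site)
        # w_c = K_c⁻¹ ΣK_c = 200/100 = 2 for both channels
        assert info["color_weights"] == {0: 2.0, 1: 2.0}
        assert math.isclose(
            ll, 2.0 * (info["per_channel"][0] + info["per_channel"][1]),
            rel_tol=1e-12)

    def test_unit_color_weight_is_plain_sum(self, rng):
        site = make_site(rng.uniform(-30, 30, (20, 2)),
                         np.full((20, 2), 4.0))
        spec = CompositeSpec([Component(_point_model(np.zeros((1, 2))),
                                        weight=0.7)], bg_weight=0.3)
        ll, info = log_likelihood(site.localizations, spec, site)
        dens = composite_pdf(site.localizations, spec, site)
        assert math.isclose(ll, np.log(dens).sum(), rel_tol=1e-12)

    def test_cross_correlation_pure_background(self, rng):
        site = make_site(rng.uniform(-50, 50, (10, 2)),
                         np.full((10, 2), 3.0), side=100.0)
        spec = CompositeSpec([Component(_point_model(np.zeros((1, 2))),
                                        weight=0.0)], bg_weight=1.0)
        assert math.isclose(cross_correlation_score(
            site.localizations, spec, site), 10 * 1e-4, rel_tol=1e-12)

    def test_cross_correlation_peaks_at_centroid(self, rng):
        # a single-point model scores highest at the centroid of an
        # isotropic cloud (grid search oracle); σ well above the cloud
        # spread keeps the score surface unimodal
        coords = rng.normal(0, 4, size=(40, 2))
        site = make_site(coords, np.full((40, 2), 10.0))
        best, best_xy = -1, None
        for x in np.linspace(-15, 15, 61):
            for y in np.linspace(-15, 15, 61):
                spec = CompositeSpec([Component(
                    _point_model(np.zeros((1, 2))),
                    pose=Pose(x0=(x, y)), weight=1.0)])
                v = cross_correlation_score(site.localizations, spec, site)
                if v > best:
                    best, best_xy = v, (x, y)
        centroid = coords.mean(axis=0)
        assert np.linalg.norm(np.array(best_xy) - centroid) < 1.0


class TestLikelihoodOracle:
    def test_matches_direct_evaluation(self, rng):
        """Channel-weighted mixture log-likelihood equals a naive
        independently coded evaluation (weighted Gaussian sums with
        background and extra uncertainty) to 1e-10 relative."""
        K, J = 20, 50
        coords = rng.uniform(-60, 60, size=(K, 3))
        sig = rng.uniform(3, 10, size=(K, 3))
        site = make_site(coords, sig, side=250.0)
        pts = rng.normal(0, 30, size=(J, 3))
        q = rng.uniform(0.5, 2.0, size=J)

        def eval_model(pts_q):
            def _eval(v, spacing):
                return _model_points(pts, weights=q)
            return GeometricModel("w", "discrete-points", 3, (), _eval)

        eps, w_bg = 2.5, 0.3
        pose = Pose(x0=(3.0, -4.0, 1.0), angles=(0.2, -0.1, 0.7),
                    extra_sigma=eps)
        spec = CompositeSpec([Component(eval_model(None), pose=pose,
                                        weight=1 - w_bg)], bg_weight=w_bg)
        ll, _ = log_likelihood(site.localizations, spec, site)

        # --- independent oracle: plain loops and math functions ---
        R = rotation_matrix(*pose.angles)
        moved = [(R @ p) + np.array(pose.x0) for p in pts]
        total = 0.0
        for k in range(K):
            var = [sig[k, a] ** 2 + eps**2 for a in range(3)]
            mix = 0.0
            for j in range(J):
                d2 = sum((coords[k, a] - moved[j][a]) ** 2 / (2 * var[a])
                         for a in range(3))
                norm = (2 * math.pi) ** -1.5 / math.sqrt(
                    var[0] * var[1] * var[2])
                mix += q[j] * norm * math.exp(-d2)
            mix /= q.sum()
            dens = (1 - w_bg) * mix + w_bg / 250.0**3
            total += math.log(dens)
        assert math.isclose(ll, total, rel_tol=1e-10)

    def test_pose_invariance(self, rng):
        """LL is unchanged when the same rigid transform is applied to the
        data and composed into the model pose (continuous model path)."""
        model = sf.get_model("npc_dual_ring")
        coords = rng.normal(0, 40, size=(25, 3))
        sig = rng.uniform(4, 9, size=(25, 3))
        site = make_site(coords, sig, side=400.0)
        pose = Pose(x0=(5.0, 2.0, -3.0), angles=(0.2, 0.1, 0.5))
        spec = CompositeSpec([Component(model, pose=pose, weight=0.9)],
                             bg_weight=0.1)
        ll0, _ = log_likelihood(site.localizations, spec, site)

        T = Pose(x0=(-8.0, 3.0, 6.0), angles=(0.3, -0.4, 1.2))
        moved = apply_pose(site.localizations, T, "model-to-data")
        site2 = sf.Site(moved, side_length=400.0, center=np.zeros(3))
        spec2 = CompositeSpec([Component(model, pose=compose_poses(T, pose),
                                         weight=0.9)], bg_weight=0.1)
        ll1, _ = log_likelihood(moved, spec2, site2)
        assert math.isclose(ll0, ll1, rel_tol=1e-8)

    def test_precision_weighting_monotonic(self):
        """Shrinking the σ of a localization sitting exactly on a model
        point strictly increases the log-likelihood."""
        pts = np.array([[0.0, 0.0, 0.0], [40.0, 0.0, 0.0]])
        lls = []
        for s in (8.0, 4.0, 2.0, 1.0):
            site = make_site(np.array([[0.0, 0.0, 0.0]]),
                             np.full((1, 3), s))
            spec = CompositeSpec([Component(_point_model(pts), weight=1.0)])
            lls.append(log_likelihood(site.localizations, spec, site)[0])
        assert all(b > a for a, b in zip(lls, lls[1:]))

    def test_zero_density_is_floored_and_flagged(self):
        site = make_site(np.array([[140.0, 140.0, 140.0]]),
                         np.full((1, 3), 1.0))
        spec = CompositeSpec([Component(_point_model(np.zeros((1, 3))),
                                        weight=1.0)], bg_weight=0.0)
        ll, info = log_likelihood(site.localizations, spec, site)
        assert np.isfinite(ll) and info["floored"] == 1


class TestNormalization:
    @pytest.mark.parametrize("name", ["npc_dual_ring", "npc_discrete",
                                      "npc_elliptical", "mt_tube",
                                      "line_segments", "endocytic"])
    def test_pdf_integrates_to_one_over_site(self, name, rng):
        """For every built-in model under a random pose, the mixture PDF
        plus background integrates to 1 ± 1% over the site box (analytic
        per-axis Gaussian integrals)."""
        from scipy.stats import norm as gauss

        model = sf.get_model(name)
        D = model.dim
        # the site box must cover the model (plus Gaussian tails)
        side = 1300.0 if name.startswith("mt") else 500.0
        sig = np.full((6, D), 6.0)
        coords = rng.uniform(-20, 20, size=(6, D))
        site = make_site(coords, sig, side=side)
        pose = Pose(x0=tuple(rng.uniform(-10, 10, D)),
                    angles=(rng.uniform(-0.3, 0.3), rng.uniform(-0.3, 0.3),
                            rng.uniform(-math.pi, math.pi)),
                    extra_sigma=3.0)
        mp = model.evaluate(spacing=2.0)
        pts = mp.points[:, :D]
        R = rotation_matrix(*pose.angles)
        if D == 2:
            pts = pts @ R[:2, :2].T + np.array(pose.x0)
        else:
            pts = pts @ R.T + np.array(pose.x0)
        w_bg = 0.15
        q = mp.weights / mp.weights.sum()
        var = sig[0, 0] ** 2 + pose.extra_sigma**2
        sd = math.sqrt(var)
        half = side / 2
        per_axis = gauss.cdf((half - pts) / sd) - gauss.cdf((-half - pts) / sd)
        integral = float((q * per_axis.prod(axis=1)).sum())
        total = (1 - w_bg) * integral + w_bg
        assert abs(total - 1.0) < 0.01


class TestPoseProperties:
    """Hypothesis property tests for the rotation/pose algebra."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    angles = st.floats(-1.4, 1.4, allow_nan=False)

    @given(a=angles, b=angles, g=angles)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_rotation_is_orthonormal(self, a, b, g):
        R = rotation_matrix(a, b, g)
        assert abs(np.linalg.det(R) - 1.0) < 1e-10
        assert np.abs(R.T @ R - np.eye(3)).max() < 1e-10

    @given(a=angles, b=angles, g=angles,
           tx=st.floats(-50, 50), ty=st.floats(-50, 50),
           tz=st.floats(-50, 50))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_pose_forward_reverse_identity(self, a, b, g, tx, ty, tz):
        pose = Pose(x0=(tx, ty, tz), angles=(a, b, g))
        pts = np.array([[1.0, 2.0, 3.0], [-40.0, 7.0, 0.5]])
        dm = DiscretizedModel(pts, np.ones(2), 1.0)
        back = apply_pose(apply_pose(dm, pose, "model-to-data"), pose,
                          "data-to-model")
        assert np.abs(back.points - pts).max() < 1e-9


def test_unsatisfiable_spacing_raises_resource_error():
    """A model that would need millions of points at the required spacing
    refuses to discretize and advises raising sigma_min."""
    from smlmfit.pdfcore import ResourceError

    locs = sf.LocalizationSet(np.zeros((3, 3)), np.full((3, 3), 0.2))
    with pytest.raises(ResourceError, match="sigma_min"):
        discretize(sf.get_model("mt_tube"), locs)
    # clamping the precision makes the same model tractable
    dm = discretize(sf.get_model("mt_tube"), locs, sigma_min=4.0)
    assert dm.n_points > 0
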