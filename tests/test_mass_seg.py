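"""Chan-Vese level set, FCM clustering, and GVF-snake mass segmentation."""

from __future__ import annotations

import numpy as np
import pytest
from skimage import measure

from breastcad import breast_seg, mass_seg, phantom
from breastcad.contour import Contour, contour_length, trace_boundary


def _jaccard(a, b):
    return (a & b).sum() / (a | b).sum()


class TestRegularizedHeavisideDirac:
    def test_closed_form_values(self):
        assert mass_seg.regularized_heaviside(0.0, 1.0) == pytest.approx(0.5)
        assert mass_seg.regularized_heaviside(2.0, 2.0) == pytest.approx(0.75)
        assert mass_seg.regularized_dirac(0.0, 1.0) == pytest.approx(1 / np.pi)

    def test_limits_and_symmetries(self):
        z = np.linspace(-5, 5, 41)
        h = mass_seg.regularized_heaviside(z, 0.7)
        assert np.all(np.diff(h) > 0)  # strictly increasing
        assert np.allclose(h + mass_seg.regularized_heaviside(-z, 0.7), 1.0)
        assert mass_seg.regularized_heaviside(1e9, 1.0) == pytest.approx(1.0, abs=1e-6)
        assert mass_seg.regularized_heaviside(-1e9, 1.0) == pytest.approx(0.0, abs=1e-6)
        d = mass_seg.regularized_dirac(z, 0.7)
        assert np.allclose(d, mass_seg.regularized_dirac(-z, 0.7))

    def test_dirac_is_heaviside_derivative(self):
        eps = 1.3
        z = np.linspace(-5 * eps, 5 * eps, 201)
        h = 1e-6
        numeric = (
            mass_seg.regularized_heaviside(z + h, eps)
            - mass_seg.regularized_heaviside(z - h, eps)
        ) / (2 * h)
        assert np.allclose(numeric, mass_seg.regularized_dirac(z, eps), atol=1e-6)

    def test_dirac_integrates_to_one(self):
        z = np.linspace(-3000, 3000, 2_000_001)
        d = mass_seg.regularized_dirac(z, 1.7)
        assert np.trapezoid(d, z) == pytest.approx(1.0, abs=1e-3)

    def test_nonpositive_epsilon_rejected(self):
        with pytest.raises(ValueError):
            mass_seg.regularized_heaviside(0.0, 0.0)
        with pytest.raises(ValueError):
            mass_seg.regularized_dirac(0.0, -1.0)


class TestRegionMeans:
    def test_two_phase_recovery(self):
        # near the sharp-interface limit (small epsilon) the weighted
        # means recover the phase intensities; at larger epsilon the
        # arctan Heaviside's global tails deliberately blend the phases
        yy, xx = np.mgrid[0:40, 0:40]
        obj = (yy - 20) ** 2 + (xx - 20) ** 2 <= 10**2
        img = np.where(obj, 50.0, 200.0)
        phi = mass_seg._signed_distance(obj)
        c1, c2 = mass_seg.region_means(img, phi, 0.01)
        assert abs(c1 - 50) <= 1.0
        assert abs(c2 - 200) <= 1.0

    def test_constant_image(self):
        phi = np.linspace(-1, 1, 64).reshape(8, 8)
        c1, c2 = mass_seg.region_means(np.full((8, 8), 42.0), phi, 1.0)
        assert c1 == pytest.approx(42.0)
        assert c2 == pytest.approx(42.0)

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 255, (8, 8))
        phi = rng.normal(0, 2, (8, 8))
        eps = 1.4
        num1 = den1 = num2 = den2 = 0.0
        for i in range(8):
            for j in range(8):
                h = 0.5 * (1 + (2 / np.pi) * np.arctan(phi[i, j] / eps))
                num1 += img[i, j] * h
                den1 += h
                num2 += img[i, j] * (1 - h)
                den2 += 1 - h
        c1, c2 = mass_seg.region_means(img, phi, eps)
        assert c1 == pytest.approx(num1 / den1, abs=1e-12)
        assert c2 == pytest.approx(num2 / den2, abs=1e-12)

    def test_vanished_phase_rejected(self):
        phi = np.full((8, 8), 50.0)  # H(phi) ~ 1 everywhere but never exactly
        c1, c2 = mass_seg.region_means(np.ones((8, 8)), phi, 1.0)
        assert np.isfinite(c1) and np.isfinite(c2)
        with pytest.raises(ValueError, match="vanished phase"):
            mass_seg.region_means(
                np.ones((2, 2)), np.full((2, 2), np.inf), 1.0
            )


class TestCvEnergy:
    def test_constant_image_leaves_length_term(self):
        rng = np.random.default_rng(0)
        phi = rng.normal(0, 1, (12, 12))
        img = np.full((12, 12), 90.0)
        params = mass_seg.LevelSetParams(mu=2.0, nu=0.0)
        state = mass_seg.LevelSetState(phi=phi, c1=90.0, c2=90.0)
        d = mass_seg.regularized_dirac(phi, params.epsilon)
        gr, gc = np.gradient(phi)
        expected = 2.0 * (d * np.hypot(gr, gc)).sum()
        assert mass_seg.cv_energy(img, state, params) == pytest.approx(expected)

    def test_perfect_two_phase_fit_zero_energy(self):
        yy, xx = np.mgrid[0:30, 0:30]
        obj = (yy - 15) ** 2 + (xx - 15) ** 2 <= 8**2
        img = np.where(obj, 60.0, 190.0)
        phi = mass_seg._signed_distance(obj)
        params = mass_seg.LevelSetParams(mu=0.0, nu=0.0, epsilon=0.01)
        state = mass_seg.LevelSetState(phi=phi, c1=60.0, c2=190.0)
        energy = mass_seg.cv_energy(img, state, params)
        # residual only from the smoothed Heaviside transition band
        assert energy <= 1e-2 * ((img - img.mean()) ** 2).sum()

    def test_matches_termwise_oracle(self):
        rng = np.random.default_rng(7)
        img = rng.uniform(0, 255, (8, 8))
        phi = rng.normal(0, 2, (8, 8))
        params = mass_seg.LevelSetParams(
            mu=3.0, nu=0.5, lambda1=1.2, lambda2=0.8, epsilon=1.6
        )
        state = mass_seg.LevelSetState(phi=phi, c1=100.0, c2=50.0)
        eps = params.epsilon
        total = 0.0
        gr, gc = np.gradient(phi)
        for i in range(8):
            for j in range(8):
                h = 0.5 * (1 + (2 / np.pi) * np.arctan(phi[i, j] / eps))
                d = (1 / np.pi) * eps / (eps**2 + phi[i, j] ** 2)
                grad = np.hypot(gr[i, j], gc[i, j])
                total += params.mu * d * grad
                total += params.nu * h
                total += params.lambda1 * (img[i, j] - state.c1) ** 2 * h
                total += params.lambda2 * (img[i, j] - state.c2) ** 2 * (1 - h)
        assert mass_seg.cv_energy(img, state, params) == pytest.approx(total, abs=1e-9)


class TestCvEvolveStep:
    def test_zero_forcing_on_constant_image(self):
        phi = mass_seg._signed_distance(np.eye(10, dtype=bool))
        params = mass_seg.LevelSetParams(mu=0.0, nu=0.0)
        state = mass_seg.LevelSetState(phi=phi, c1=0.0, c2=0.0)
        new = mass_seg.cv_evolve_step(np.full((10, 10), 77.0), state, params)
        assert np.abs(new.phi - phi).max() <= 1e-9

    def test_single_step_descends_energy(self, disk_image):
        img, disk = disk_image
        yy, xx = np.mgrid[0:100, 0:100]
        init = (yy - 40) ** 2 + (xx - 42) ** 2 <= 20**2
        u0 = img / 255.0
        params = mass_seg.LevelSetParams(mu=0.1, nu=0.0)
        phi = mass_seg._signed_distance(init)
        c1, c2 = mass_seg.region_means(u0, phi, params.epsilon)
        state = mass_seg.LevelSetState(phi=phi, c1=c1, c2=c2)
        state.energy = mass_seg.cv_energy(u0, state, params)
        new = mass_seg.cv_evolve_step(u0, state, params)
        assert new.energy <= state.energy
        assert new.iteration == 1

    def test_area_penalty_shrinks_inside(self):
        yy, xx = np.mgrid[0:40, 0:40]
        init = (yy - 20) ** 2 + (xx - 20) ** 2 <= 12**2
        phi = mass_seg._signed_distance(init)
        params = mass_seg.LevelSetParams(mu=0.0, nu=0.5, dt=0.5)
        state = mass_seg.LevelSetState(phi=phi, c1=1.0, c2=1.0)
        img = np.ones((40, 40))
        area0 = mass_seg.regularized_heaviside(phi, params.epsilon).sum()
        for _ in range(20):
            state = mass_seg.cv_evolve_step(img, state, params)
        area1 = mass_seg.regularized_heaviside(state.phi, params.epsilon).sum()
        assert area1 < area0


class TestChanVeseSegment:
    def test_disk_recovery_from_offset_init(self, disk_image):
        img, disk = disk_image
        yy, xx = np.mgrid[0:100, 0:100]
        init = (yy - 40) ** 2 + (xx - 42) ** 2 <= 20**2
        params = mass_seg.LevelSetParams(max_iters=3000)
        mask, meta = mass_seg.chan_vese_segment(img, init, params)
        assert _jaccard(mask, disk) >= 0.98
        assert abs(meta["c1"] - 200) <= 0.5
        assert abs(meta["c2"] - 50) <= 0.5

    def test_true_mask_is_fixed_point(self, disk_image):
        img, disk = disk_image
        mask, _ = mass_seg.chan_vese_segment(img, disk)
        assert _jaccard(mask, disk) >= 0.99

    def test_two_circles_merge_over_one_object(self, disk_image):
        img, disk = disk_image
        yy, xx = np.mgrid[0:100, 0:100]
        init = ((yy - 50) ** 2 + (xx - 30) ** 2 <= 12**2) | (
            (yy - 50) ** 2 + (xx - 70) ** 2 <= 12**2
        )
        params = mass_seg.LevelSetParams(max_iters=3000)
        mask, _ = mass_seg.chan_vese_segment(img, init, params)
        assert measure.label(mask, connectivity=2).max() == 1

    def test_one_circle_splits_over_two_objects(self):
        yy, xx = np.mgrid[0:100, 0:100]
        two = ((yy - 35) ** 2 + (xx - 35) ** 2 <= 13**2) | (
            (yy - 65) ** 2 + (xx - 65) ** 2 <= 13**2
        )
        img = np.where(two, 200.0, 50.0)
        init = (yy - 50) ** 2 + (xx - 50) ** 2 <= 28**2
        params = mass_seg.LevelSetParams(max_iters=8000)
        mask, _ = mass_seg.chan_vese_segment(img, init, params)
        assert measure.label(mask, connectivity=2).max() == 2
        assert _jaccard(mask, two) >= 0.95

    def test_degenerate_inits_rejected(self):
        img = np.zeros((10, 10))
        with pytest.raises(ValueError):
            mass_seg.chan_vese_segment(img, np.zeros((10, 10), bool))
        with pytest.raises(ValueError):
            mass_seg.chan_vese_segment(img, np.ones((10, 10), bool))

    def test_agrees_with_independent_level_set_solver(self, disk_image):
        """Cross-check against an unrelated Chan-Vese implementation."""
        from skimage.segmentation import chan_vese as sk_chan_vese

        img, disk = disk_image
        yy, xx = np.mgrid[0:100, 0:100]
        init = (yy - 40) ** 2 + (xx - 42) ** 2 <= 20**2
        ours, _ = mass_seg.chan_vese_segment(
            img, init, mass_seg.LevelSetParams(max_iters=3000)
        )
        theirs = sk_chan_vese(
            img / 255.0, mu=0.1, lambda1=1, lambda2=1, dt=0.5,
            max_num_iter=500, init_level_set=np.where(init, 1.0, -1.0),
        )
        assert _jaccard(ours, theirs) >= 0.95


class TestFcm:
    def test_two_valued_image_exact_partition(self):
        yy, xx = np.mgrid[0:60, 0:60]
        disk = (yy - 30) ** 2 + (xx - 30) ** 2 <= 15**2
        img = np.where(disk, 200.0, 50.0)
        u, centroids = mass_seg.fcm_memberships(
            img.ravel(), mass_seg.FcmParams(n_clusters=2)
        )
        assert np.allclose(centroids, [50.0, 200.0], atol=0.5)
        mask = mass_seg.fcm_segment(
            img, np.ones_like(disk), mass_seg.FcmParams(n_clusters=2)
        )
        assert (mask ^ disk).sum() == 0

    def test_large_fuzziness_flattens_memberships(self):
        # the membership rule at fixed distinct centroids tends to 1/c
        # as the fuzziness exponent grows
        yy, xx = np.mgrid[0:30, 0:30]
        img = np.where((yy - 15) ** 2 + (xx - 15) ** 2 <= 8**2, 200.0, 50.0)
        u, _ = mass_seg.fcm_memberships(
            img.ravel(),
            mass_seg.FcmParams(n_clusters=2, fuzziness=60.0, max_iters=1),
            init_centroids=np.array([80.0, 120.0]),
        )
        assert np.allclose(u, 0.5, atol=0.05)

    def test_matches_fixed_point_oracle_on_toy_sample(self):
        """Direct fixed-point iteration on 16 values, checked to 1e-6."""
        x = np.array(
            [10, 12, 11, 13, 50, 52, 49, 51, 90, 91, 89, 92, 30, 31, 70, 71],
            dtype=float,
        )
        params = mass_seg.FcmParams(n_clusters=3, fuzziness=2.0, tol=1e-12,
                                    max_iters=500)
        u, centroids = mass_seg.fcm_memberships(x, params)

        # oracle: plain alternating updates from the same quantile init
        c = np.quantile(x, np.linspace(0, 1, 5)[1:-1])
        for _ in range(500):
            d = np.abs(x[:, None] - c[None, :])
            d = np.maximum(d, 1e-12)
            inv = d ** (-2.0)
            w = inv / inv.sum(axis=1, keepdims=True)
            c_new = (w**2 * x[:, None]).sum(axis=0) / (w**2).sum(axis=0)
            if np.abs(c_new - c).max() < 1e-12:
                c = c_new
                break
            c = c_new
        order = np.argsort(c)
        d = np.maximum(np.abs(x[:, None] - c[None, :]), 1e-12)
        inv = d ** (-2.0)
        w = (inv / inv.sum(axis=1, keepdims=True))[:, order]
        assert np.allclose(centroids, c[order], atol=1e-6)
        assert np.allclose(u, w, atol=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            mass_seg.fcm_memberships(np.arange(9.0), mass_seg.FcmParams(n_clusters=1))
        with pytest.raises(ValueError):
            mass_seg.fcm_memberships(
                np.arange(9.0), mass_seg.FcmParams(fuzziness=1.0)
            )


class TestGvfSnakeRefine:
    @staticmethod
    def _circle(center, radius, n=100):
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.stack(
            [center[0] + radius * np.sin(theta), center[1] + radius * np.cos(theta)],
            axis=1,
        )
        return Contour(pts, closed=True)

    def test_equilibrium_on_clean_edge(self):
        yy, xx = np.mgrid[0:60, 0:60]
        disk = (yy - 30) ** 2 + (xx - 30) ** 2 <= 15**2
        img = np.where(disk, 200.0, 50.0)
        mask = mass_seg.gvf_snake_refine(img, self._circle((30, 30), 15))
        contour = trace_boundary(mask)
        r = np.hypot(contour.rows - 30, contour.cols - 30)
        assert np.abs(r - 15).max() <= 1.5  # within ~1 px of the init circle

    def test_capture_from_outside(self):
        yy, xx = np.mgrid[0:60, 0:60]
        disk = (yy - 30) ** 2 + (xx - 30) ** 2 <= 15**2
        img = np.where(disk, 200.0, 50.0)
        mask = mass_seg.gvf_snake_refine(img, self._circle((30, 30), 20))
        assert _jaccard(mask, disk) >= 0.95

    def test_spiculated_boundary_smoothed(self, malignant_case):
        """The snake's contour is too smooth to follow spicules."""
        case = malignant_case
        rows, cols = np.nonzero(case.mass_mask)
        pad = 20
        rs = slice(rows.min() - pad, rows.max() + pad)
        cs = slice(cols.min() - pad, cols.max() + pad)
        roi = case.image[rs, cs].astype(float)
        true_local = case.mass_mask[rs, cs]
        init = trace_boundary(true_local)
        mask = mass_seg.gvf_snake_refine(roi, init)
        snake_perim = contour_length(trace_boundary(mask))
        true_perim = contour_length(trace_boundary(true_local))
        assert snake_perim < true_perim

    def test_open_contour_rejected(self):
        with pytest.raises(ValueError):
            mass_seg.gvf_snake_refine(
                np.zeros((20, 20)),
                Contour(np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 1.0]]), closed=False),
            )


class TestSegmentMass:
    def test_cv_ls_mask_inside_breast(self, benign_case):
        mask, meta = mass_seg.segment_mass(
            benign_case.image, benign_case.breast_mask, "cv_ls"
        )
        assert mask.any()
        assert not (mask & ~benign_case.breast_mask).any()
        assert measure.label(mask, connectivity=2).max() == 1

    def test_mass_free_image_rejected(self):
        rng = np.random.default_rng(0)
        img = np.clip(rng.normal(140, 5, (128, 128)), 0, 255).astype(np.uint8)
        breast = np.zeros((128, 128), bool)
        breast[10:118, 10:118] = True
        with pytest.raises(ValueError, match="no enhancing mass"):
            mass_seg.segment_mass(img, breast, "cv_ls")

    def test_unknown_method_rejected(self, benign_case):
        with pytest.raises(ValueError, match="unknown method"):
            mass_seg.segment_mass(benign_case.image, benign_case.breast_mask, "watershed")

    def test_cv_beats_snake_on_spiculated_mass(self, malignant_case):
        case = malignant_case
        breast = case.breast_mask
        cv_mask, _ = mass_seg.segment_mass(case.image, breast, "cv_ls")
        snake_mask, _ = mass_seg.segment_mass(case.image, breast, "fcm_gvf")
        cv_j = _jaccard(cv_mask, case.mass_mask)
        assert cv_j >= 0.85
        assert cv_j >= _jaccard(snake_mask, case.mass_mask)
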