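"""Contour registration, map fusion and stiffness/fluorescence association."""

import numpy as np
import pytest
from oracles import dtw_cost_bruteforce, fisher_two_sided

from neuroworkbench import brainmap, synth
from neuroworkbench.brainmap import (
    ContingencyTable,
    bin_image,
    circle_average,
    dtw_correspond,
    ellipse_align,
    fisher_exact_p,
    fuse_maps,
    line_profile_ratio,
    mean_contour,
    orient_clockwise,
    resample_contour,
    rbf_warp,
)


def circle(n=150, r=1.0, phase=0.0):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


class TestBinning:
    def test_constant_image_normalises_to_one(self):
        out = bin_image(np.full((45, 60), 7.0), block=15)
        assert out.shape == (3, 4)
        assert np.allclose(out, 1.0)

    def test_blocks_equal_direct_means(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(0, 9, (45, 30))
        out = bin_image(img, block=15)
        direct = img.reshape(3, 15, 2, 15).mean(axis=(1, 3))
        assert np.allclose(out, direct / direct.max())

    def test_max_maps_to_one(self):
        rng = np.random.default_rng(0)
        out = bin_image(rng.uniform(0, 9, (60, 60)), block=15)
        assert out.max() == pytest.approx(1.0)


class TestResample:
    def test_circle_spacing_uniform(self):
        dense = circle(n=1000)
        pts = resample_contour(dense, n=150)
        assert pts.shape == (150, 2)
        d = np.hypot(*np.diff(np.vstack([pts, pts[:1]]), axis=0).T)
        assert np.allclose(d, d[0], atol=1e-6)

    def test_square_arc_length_spacing(self):
        sq = np.array([[0, 0], [4, 0], [4, 4], [0, 4]], dtype=float)
        pts = resample_contour(sq, n=16)
        d = np.hypot(*np.diff(np.vstack([pts, pts[:1]]), axis=0).T)
        assert np.allclose(d, 1.0, atol=1e-9)  # perimeter 16 / 16 points

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            resample_contour(circle(), n=2)


class TestEllipseAlign:
    def test_unit_circle_is_fixed_point(self):
        pts = circle(n=80)
        aligned, tf = ellipse_align(pts)
        assert np.abs(np.hypot(aligned[:, 0], aligned[:, 1]) - 1).max() < 1e-6

    def test_rotated_ellipse_maps_to_unit_circle(self):
        th = np.linspace(0, 2 * np.pi, 120, endpoint=False)
        e = np.column_stack([2 * np.cos(th), 1 * np.sin(th)])
        rot = np.array(
            [
                [np.cos(np.pi / 6), -np.sin(np.pi / 6)],
                [np.sin(np.pi / 6), np.cos(np.pi / 6)],
            ]
        )
        pts = e @ rot.T + [5.0, -3.0]
        aligned, tf = ellipse_align(pts)
        assert np.abs(np.hypot(aligned[:, 0], aligned[:, 1]) - 1).max() < 1e-3

    def test_degenerate_contour_rejected(self):
        line = np.column_stack([np.linspace(0, 1, 50), np.linspace(0, 2, 50)])
        with pytest.raises(ValueError):
            ellipse_align(line)


class TestMeanContour:
    def test_identical_contours_returned(self):
        c = circle(phase=0.3)
        m = mean_contour([c, c.copy(), c.copy()])
        shifted = brainmap._shift_to_start(orient_clockwise(c), np.array([1.0, 0.0]))
        assert np.allclose(m, shifted)

    def test_two_circles_average_radius(self):
        m = mean_contour([circle(r=1.0), circle(r=3.0)])
        assert np.allclose(np.hypot(m[:, 0], m[:, 1]), 2.0, atol=1e-3)

    def test_orientation_fix_invariance(self):
        c = circle(phase=0.7)
        m1 = mean_contour([c, circle(r=2.0)])
        m2 = mean_contour([c[::-1].copy(), circle(r=2.0)])
        assert np.allclose(m1, m2, atol=1e-9)


class TestDTW:
    def test_identity_path_zero_cost(self):
        c = circle(n=30)
        src, dst = dtw_correspond(c, c)
        assert np.allclose(src, dst, atol=1e-12)

    def test_dp_cost_matches_bruteforce_on_tiny_sequences(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = rng.normal(0, 1, (7, 2))
            b = rng.normal(0, 1, (6, 2))
            cost = np.hypot(
                a[:, 0][:, None] - b[:, 0][None, :],
                a[:, 1][:, None] - b[:, 1][None, :],
            )
            n, m = len(a), len(b)
            acc = np.full((n + 1, m + 1), np.inf)
            acc[0, 0] = 0.0
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    acc[i, j] = cost[i - 1, j - 1] + min(
                        acc[i - 1, j], acc[i - 1, j - 1], acc[i, j - 1]
                    )
            assert acc[n, m] == pytest.approx(dtw_cost_bruteforce(a, b), rel=1e-12)

    def test_collapse_averages_many_to_one(self):
        a = np.array([[0.0, 0.0], [0.0, 1.0], [0.0, 2.0], [5.0, 5.0]])
        b = np.array([[0.0, 1.0], [5.0, 5.0]])
        src, dst = dtw_correspond(a, b)
        assert np.allclose(src[0], [0.0, 1.0])  # centroid of the 3 collapsed
        assert np.allclose(dst[0], [0.0, 1.0])


class TestRBF:
    def test_translation_reproduced_exactly(self):
        rng = np.random.default_rng(1)
        src = rng.uniform(-1, 1, (40, 2))
        dst = src + [0.3, -0.7]
        coords = rng.uniform(-1, 1, (100, 2))
        warped = rbf_warp(src, dst, coords)
        assert np.allclose(warped, coords + [0.3, -0.7], atol=1e-9)

    def test_exact_at_control_points(self):
        rng = np.random.default_rng(2)
        src = rng.uniform(-1, 1, (30, 2))
        dst = src + 0.1 * rng.normal(0, 1, (30, 2))
        assert np.allclose(rbf_warp(src, dst, src), dst, atol=1e-8)


class TestFusion:
    def test_identical_samples_fuse_to_member_values(self):
        samples, _ = synth.make_brain_cohort(n_embryos=2, deform_sd=0.0, seed=4)
        s = samples[0]
        cohort = [
            brainmap.BrainSample(
                outline=s.outline.copy(),
                afm_points=s.afm_points.copy(),
                fm_image=s.fm_image.copy(),
            )
            for _ in range(4)
        ]
        fused = fuse_maps(cohort)
        ok = np.isfinite(fused.stiff_values)
        # every fused node value equals some member measurement
        diffs = np.abs(
            fused.stiff_values[ok][:, None] - s.afm_points[:, 2][None, :]
        ).min(axis=1)
        assert diffs.max() < 1e-9

    def test_median_robust_to_one_outlier(self):
        samples, _ = synth.make_brain_cohort(n_embryos=2, deform_sd=0.0, seed=4)
        s = samples[0]
        def clone():
            return brainmap.BrainSample(
                outline=s.outline.copy(),
                afm_points=s.afm_points.copy(),
                fm_image=s.fm_image.copy(),
            )
        cohort = [clone() for _ in range(5)]
        cohort[2].afm_points[:, 2] += 1e6
        fused_clean = fuse_maps([clone() for _ in range(5)])
        fused_dirty = fuse_maps(cohort)
        ok = np.isfinite(fused_clean.stiff_values) & np.isfinite(fused_dirty.stiff_values)
        assert np.allclose(
            fused_clean.stiff_values[ok], fused_dirty.stiff_values[ok]
        )

    def test_fused_field_tracks_smooth_latent_template(self):
        # regionally smooth planted field: fusion fidelity is then limited
        # only by registration, not by site-scale texture
        samples, gt = synth.make_brain_cohort(n_embryos=8, seed=6, fine_share=0.0)
        fused = fuse_maps(samples)
        # map fused node positions back to template coordinates through the
        # template's own affine normalisation and read the latent field there
        _, tf = ellipse_align(gt.extras["template_contour"])
        inv = np.linalg.inv(tf.matrix)
        ok = np.isfinite(fused.stiff_values)
        back = fused.stiff_nodes[ok] @ inv.T + tf.centre
        latent = gt.extras["stiff_field"](back[:, ::-1])
        r = np.corrcoef(fused.stiff_values[ok], latent)[0, 1]
        assert r > 0.9

    def test_registration_contracts_cohort_dispersion(self):
        samples, _ = synth.make_brain_cohort(n_embryos=6, seed=9)
        contours = [resample_contour(s.outline) for s in samples]
        aligned = [ellipse_align(c)[0] for c in contours]
        mean = mean_contour(aligned)

        def disp(cs, ref):
            from scipy.spatial import cKDTree

            tree = cKDTree(ref)
            return np.mean([tree.query(c)[0].mean() for c in cs])

        pre = disp(aligned, mean)
        post_contours = []
        for c in aligned:
            prep = brainmap._shift_to_start(orient_clockwise(c), np.array([1.0, 0.0]))
            src, dst = dtw_correspond(prep, mean)
            post_contours.append(rbf_warp(src, dst, prep))
        post = disp(post_contours, mean)
        assert post <= 0.2 * pre

    def test_cohort_of_one_rejected(self):
        samples, _ = synth.make_brain_cohort(n_embryos=2, seed=0)
        with pytest.raises(ValueError):
            fuse_maps(samples[:1])


class TestCircleAverage:
    def test_uniform_values(self):
        nodes = np.array([[0.0, 0.0], [10.0, 0.0]])
        pts = np.random.default_rng(0).uniform(-5, 15, (200, 2))
        vals = np.full(200, 3.3)
        out = circle_average(pts, vals, nodes, np.array([5.0, 5.0]))
        assert np.allclose(out, 3.3)

    def test_two_nodes_tangent_radii(self):
        nodes = np.array([[0.0, 0.0], [10.0, 0.0]])
        radii = brainmap._half_nn_distance(nodes)
        assert radii.tolist() == [5.0, 5.0]

    def test_regular_grid_half_pitch(self):
        gx, gy = np.meshgrid(np.arange(4) * 2.0, np.arange(3) * 2.0)
        nodes = np.column_stack([gx.ravel(), gy.ravel()])
        assert np.allclose(brainmap._half_nn_distance(nodes), 1.0)


class TestAssociation:
    def test_balanced_table_odds_one(self):
        t = ContingencyTable(1, 1, 1, 1)
        assert t.odds_ratio == 1.0
        assert t.fisher_p == pytest.approx(1.0, abs=1e-12)

    def test_printed_example_quarter(self):
        t = ContingencyTable(
            n_stiff_high=10, n_soft_high=40, n_stiff_low=40, n_soft_low=40
        )
        assert t.odds_ratio == pytest.approx(0.25, rel=1e-12)

    def test_conditional_probabilities_sum_to_one(self):
        t = ContingencyTable(7, 13, 22, 3)
        probs = t.conditional_probs()
        assert np.allclose(probs.sum(axis=0), 1.0)

    def test_zero_denominator_flagged_not_crash(self):
        t = ContingencyTable(n_stiff_high=5, n_stiff_low=0, n_soft_high=3, n_soft_low=2)
        assert t.odds_ratio is None

    def test_fisher_matches_exact_fraction_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 12, 4)
            assert fisher_exact_p(a, b, c, d) == pytest.approx(
                fisher_two_sided(a, b, c, d), abs=1e-12
            )

    def test_fisher_matches_scipy(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(8)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 15, 4)
            ours = fisher_exact_p(a, b, c, d)
            ref = fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_high_fraction_near_forty_percent(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 500)
        y = rng.normal(0, 1, 500)
        _, table = brainmap.associate(x, y)
        frac_high = (table.n_stiff_high + table.n_soft_high) / table.total
        assert 0.35 <= frac_high <= 0.45


class TestLineProfile:
    def test_constant_image_ratio_one(self):
        img = np.full((200, 300), 5.0)
        _, ratio = line_profile_ratio(img, (100, 10), (100, 290))
        assert ratio == pytest.approx(1.0)

    def test_planted_band_closed_form(self):
        img = np.ones((200, 300))
        img[:, 140:160] = 10.0  # 10x band over ~6.9% of the stripe length
        profile, ratio = line_profile_ratio(img, (100, 9), (100, 299))
        frac = 20 / 290
        expect = 10.0 / (frac * 10.0 + (1 - frac) * 1.0)
        assert ratio == pytest.approx(expect, rel=0.02)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            line_profile_ratio(np.zeros((0, 0)), (0, 0), (1, 1))
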