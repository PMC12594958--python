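"""Wavelet spot detection, neurite segmentation and synapse matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import b3_smooth_direct, bh_reject

from neuroworkbench import puncta, synth
from neuroworkbench.puncta import (
    MultiChannelImage,
    NeuriteMask,
    PunctaSet,
    atrous_decompose,
    detect_spots,
    match_synapses,
    neurite_mask,
    significant_support,
    synapse_density,
)


class TestAtrous:
    def test_constant_image_has_zero_details(self):
        details, approx = atrous_decompose(np.full((32, 32), 3.7), levels=3)
        for d in details:
            assert np.allclose(d, 0.0, atol=1e-12)
        assert np.allclose(approx, 3.7)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_reconstruction_identity(self, seed):
        img = np.random.default_rng(seed).normal(0, 1, (40, 40))
        details, approx = atrous_decompose(img, levels=3)
        assert np.abs(sum(details) + approx - img).max() < 1e-9

    def test_first_detail_matches_direct_convolution(self):
        img = np.zeros((21, 21))
        img[10, 10] = 1.0
        details, _ = atrous_decompose(img, levels=1)
        assert np.allclose(details[0], img - b3_smooth_direct(img), atol=1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            atrous_decompose(np.zeros((8, 8)), levels=0)
        with pytest.raises(ValueError):
            atrous_decompose(np.full((8, 8), np.nan))


class TestSupport:
    def test_bh_equals_sorted_pvalue_oracle(self):
        from scipy import stats
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0, 1, 500)
            p[rng.integers(0, 500, 30)] **= 6  # plant some small p-values
            ours = multipletests(p, alpha=0.01, method="fdr_bh")[0]
            assert (ours == bh_reject(p, 0.01)).all()

    def test_strong_outlier_lands_in_support(self):
        rng = np.random.default_rng(1)
        plane = rng.normal(0, 1, (50, 50))
        plane[25, 25] = 50.0
        support = significant_support([plane], fdr=0.01)
        assert support[25, 25]

    def test_all_zero_details_give_empty_support(self):
        zeros = [np.zeros((30, 30)) for _ in range(3)]
        assert not significant_support(zeros).any()

    def test_noise_planes_give_nearly_empty_support(self):
        counts = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            planes = [rng.normal(0, 1, (64, 64)) for _ in range(3)]
            counts.append(significant_support(planes, fdr=0.01).sum())
        assert np.mean(counts) < 0.01 * 64 * 64


class TestDetectSpots:
    def test_single_spot_detected_within_one_pixel(self):
        img = np.zeros((256, 256))
        synth._add_spot(img, 130.0, 90.0, 20.0, 1.5)
        img += np.random.default_rng(2).normal(0, 1, img.shape)
        ps = detect_spots(img)
        assert len(ps) == 1
        assert np.hypot(*(ps.centres[0] - [130, 90])) <= 1.0

    def test_two_close_spots_with_merged_support_resolved(self):
        img = np.zeros((256, 256))
        synth._add_spot(img, 100.0, 100.0, 20.0, 1.5)
        synth._add_spot(img, 100.0, 106.0, 20.0, 1.5)
        ps = detect_spots(img)
        assert len(ps) == 2
        got = sorted(map(tuple, ps.centres))
        assert got == [(100, 100), (100, 106)]

    def test_blank_noise_rarely_detects(self):
        n_with = sum(
            len(detect_spots(np.random.default_rng(s).normal(0, 1, (256, 256)))) > 0
            for s in range(20)
        )
        assert n_with <= 1  # >= 95% of seeds clean

    def test_translation_equivariance(self):
        base = np.zeros((200, 200))
        for r, c in [(60, 70), (120, 45), (90, 150)]:
            synth._add_spot(base, r, c, 25.0, 1.5)
        noise = np.random.default_rng(4).normal(0, 1, (200, 200))
        img = base + noise
        shifted = np.roll(np.roll(img, 7, axis=0), -5, axis=1)
        c0 = detect_spots(img).centres
        c1 = detect_spots(shifted).centres
        expect = c0 + [7, -5]
        assert sorted(map(tuple, expect)) == sorted(map(tuple, c1))

    def test_centres_must_lie_in_support(self):
        with pytest.raises(ValueError):
            PunctaSet("NRL", np.array([[3, 3]]), np.zeros((8, 8), dtype=bool))


class TestNeuriteMask:
    def test_straight_filament_length(self):
        img = np.zeros((300, 300))
        img[150:152, :] = 8.0
        img += np.random.default_rng(1).normal(0, 1, img.shape)
        nm = neurite_mask(img)
        assert abs(nm.process_length_px - 600) <= 0.15 * 600

    def test_blank_image_zero_length(self):
        nm = neurite_mask(np.zeros((64, 64)))
        assert nm.process_length_px == 0

    def test_soma_blob_excluded_by_opening(self):
        img = np.zeros((300, 300))
        img[150:152, :] = 8.0
        rr, cc = np.indices(img.shape)
        blob = np.hypot(rr - 80, cc - 80) < 15
        img[blob] = 8.0
        img += np.random.default_rng(2).normal(0, 1, img.shape)
        nm = neurite_mask(img)
        assert nm.soma_mask.sum() >= 400  # blob found
        # blob interior does not count towards process length
        assert not (nm.process_mask & ~nm.soma_mask & blob).sum() > 100


class TestMatching:
    def _mask(self, shape=(30, 30), row=10):
        m = np.zeros(shape, dtype=bool)
        m[row, :] = True
        return NeuriteMask(process_mask=m, soma_mask=np.zeros(shape, bool))

    def _ps(self, ch, centres, shape=(30, 30)):
        sup = np.zeros(shape, dtype=bool)
        for r, c in centres:
            sup[r, c] = True
        return PunctaSet(ch, np.array(centres), sup)

    def test_diagonal_neighbour_pair_matches(self):
        pairs = match_synapses(
            self._ps("VGLUT2", [(10, 10)]), self._ps("NRL", [(11, 11)]), self._mask()
        )
        assert len(pairs) == 1
        assert pairs["distance_px"].iloc[0] == pytest.approx(np.sqrt(2))

    def test_pair_beyond_radius_rejected(self):
        pairs = match_synapses(
            self._ps("VGLUT2", [(10, 10)]), self._ps("NRL", [(13, 10)]), self._mask()
        )
        assert len(pairs) == 0

    def test_off_filament_pre_rejected(self):
        pairs = match_synapses(
            self._ps("VGLUT2", [(20, 10)]), self._ps("NRL", [(21, 10)]), self._mask()
        )
        assert len(pairs) == 0

    def test_post_used_at_most_once(self):
        pairs = match_synapses(
            self._ps("VGLUT2", [(10, 10), (10, 12)]),
            self._ps("NRL", [(10, 11)]),
            self._mask(),
        )
        assert len(pairs) == 1

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            match_synapses(
                self._ps("VGLUT2", [(10, 10)]),
                self._ps("NRL", [(10, 11)]),
                self._mask(),
                radius_px=0,
            )


class TestDensity:
    def test_density_arithmetic(self):
        import pandas as pd

        mask = NeuriteMask(
            process_mask=np.ones((101, 55), dtype=bool),
            soma_mask=np.zeros((101, 55), dtype=bool),
        )
        assert mask.process_length_px == 5555
        pairs = pd.DataFrame(
            {"pre_channel": ["VGLUT2"] * 10, "distance_px": [1.0] * 10}
        )
        d = synapse_density(pairs, mask, pixel_nm=180.0)
        assert d["VGLUT2"] == pytest.approx(10 / (5555 * 180e-6), rel=1e-12)
        assert d["VGAT"] == 0.0

    def test_zero_length_raises(self):
        import pandas as pd

        mask = NeuriteMask(
            process_mask=np.zeros((10, 10), dtype=bool),
            soma_mask=np.zeros((10, 10), dtype=bool),
        )
        with pytest.raises(ZeroDivisionError):
            synapse_density(pd.DataFrame({"pre_channel": []}), mask)


class TestEndToEnd:
    def test_recall_precision_on_synthetic_fov(self):
        img, gt = synth.make_synapse_image(seed=3, snr=5.0, jitter_px=1.0)
        table = puncta.quantify_image(img)
        true_pre = gt.records[gt.records["role"] == "pre"]
        tp, used = 0, set()
        for _, row in table.pairs.iterrows():
            d = np.hypot(
                true_pre["row"] - row["pre_row"], true_pre["col"] - row["pre_col"]
            )
            j = d.idxmin()
            if d[j] <= 2 and j not in used:
                tp += 1
                used.add(j)
        assert tp / max(len(table), 1) >= 0.9  # precision
        assert tp / len(true_pre) >= 0.9  # recall

    def test_density_monotone_in_planted_density(self):
        from scipy.stats import spearmanr

        planted, measured = [], []
        for k, dens in enumerate([10, 25, 50, 80, 120]):
            img, gt = synth.make_synapse_image(
                seed=40 + k, synapse_density=dens, distractor_rate=0.0, snr=8.0
            )
            table = puncta.quantify_image(img)
            planted.append(dens)
            measured.append(sum(table.densities.values()))
        rho = spearmanr(planted, measured).statistic
        assert rho > 0.9

    def test_channel_shape_validation(self):
        with pytest.raises(ValueError):
            MultiChannelImage(
                channels={"NF": np.zeros((10, 10)), "NRL": np.zeros((9, 10))}
            )
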