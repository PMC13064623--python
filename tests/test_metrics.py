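"""Reference and non-reference metric identities, oracles, orderings."""

import numpy as np
import pytest
from scipy import ndimage

from stedlite.metrics import (
    FRCCurve,
    deviation_map,
    edge_preservation,
    frc,
    frc_resolution,
    hf_disagreement,
    line_profile,
    metric_report,
    npsnr,
    pearson,
    psnr_db,
    snr_nonref,
    ssim,
)


@pytest.fixture()
def noise_pair():
    rng = np.random.default_rng(0)
    return rng.random((64, 64)), rng.random((64, 64))


class TestSSIM:
    def test_identity_is_one(self, noise_pair):
        a, _ = noise_pair
        assert ssim(a, a) == 1.0

    def test_constants_closed_form(self):
        # mu_x=0, mu_y=1, all variances 0:
        # SSIM = C1 * C2 / ((1 + C1) * C2) = C1 / (1 + C1), C1 = 0.01^2
        a = np.zeros((32, 32))
        b = np.ones((32, 32))
        c1 = 0.01**2
        assert ssim(a, b, data_range=1.0) == pytest.approx(c1 / (1 + c1), rel=1e-6)

    def test_symmetry(self, noise_pair):
        a, b = noise_pair
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((4, 4)), np.zeros((5, 5)))


class TestPSNR:
    def test_identity_infinite(self, noise_pair):
        a, _ = noise_pair
        assert np.isinf(psnr_db(a, a))

    def test_closed_form_20db(self):
        # MSE 0.01 on unit range -> 10 log10(1/0.01) = 20 dB
        a = np.zeros((10, 10))
        b = np.full((10, 10), 0.1)
        assert psnr_db(a, b) == pytest.approx(20.0, abs=1e-9)

    def test_matches_skimage(self, noise_pair):
        from skimage.metrics import peak_signal_noise_ratio

        a, b = noise_pair
        assert psnr_db(a, b) == pytest.approx(
            peak_signal_noise_ratio(a, b, data_range=1.0), abs=1e-10)

    def test_noise_monotonicity(self):
        rng = np.random.default_rng(1)
        base = rng.random((64, 64)) * 0.5 + 0.25
        vals = []
        for sd in (0.01, 0.05, 0.1):
            noisy = base + rng.normal(0, sd, base.shape)
            vals.append(psnr_db(base, noisy))
        assert vals[0] > vals[1] > vals[2]


class TestNPSNR:
    def test_identity_maps_to_one(self):
        assert npsnr(float("inf")) == 1.0

    def test_ratio_and_clipping(self):
        assert npsnr(20.0, cap_db=40.0) == 0.5
        assert npsnr(60.0, cap_db=40.0) == 1.0

    def test_invalid_cap(self):
        with pytest.raises(ValueError):
            npsnr(10.0, cap_db=0.0)


class TestFRC:
    def test_identity_is_one_on_every_ring(self, noise_pair):
        a, _ = noise_pair
        curve = frc(a, a)
        np.testing.assert_allclose(curve.correlations, 1.0, atol=1e-10)

    def test_symmetric_in_arguments(self, noise_pair):
        a, b = noise_pair
        np.testing.assert_allclose(frc(a, b).correlations,
                                   frc(b, a).correlations, atol=1e-12)

    def test_independent_noise_decorrelated(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(128, 128)), rng.normal(size=(128, 128))
        curve = frc(a, b, apodize=False)
        bound = 3.0 / np.sqrt(curve.ring_counts)
        frac_within = np.mean(np.abs(curve.correlations) < bound)
        assert frac_within > 0.9
        assert abs(curve.correlations.mean()) < 0.05

    def test_frequencies_increasing_up_to_nyquist(self, noise_pair):
        a, b = noise_pair
        curve = frc(a, b)
        assert np.all(np.diff(curve.ring_freqs) > 0)
        assert curve.ring_freqs[-1] <= 0.5

    def test_nonsquare_rejected(self):
        with pytest.raises(ValueError):
            frc(np.zeros((4, 8)), np.zeros((4, 8)))


class TestHFDisagreement:
    def test_identity_curve_gives_zero(self, noise_pair):
        a, _ = noise_pair
        assert hf_disagreement(frc(a, a)) == pytest.approx(0.0, abs=1e-10)

    def test_zero_correlations_give_one(self):
        curve = FRCCurve(np.linspace(0.05, 0.5, 10), np.zeros(10), np.ones(10))
        assert hf_disagreement(curve) == 1.0

    def test_hand_averaged_band(self):
        freqs = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        corr = np.array([0.9, 0.8, 0.6, 0.4, 0.2])
        curve = FRCCurve(freqs, corr, np.ones(5))
        # band: freq >= 0.25 -> rings (0.3, 0.4, 0.5), mean 0.4
        assert hf_disagreement(curve, 0.5) == pytest.approx(1 - 0.4, abs=1e-12)

    def test_empty_band_rejected(self):
        curve = FRCCurve(np.array([0.05, 0.1]), np.ones(2), np.ones(2))
        with pytest.raises(ValueError):
            hf_disagreement(curve, 0.9)


class TestFRCResolution:
    def test_never_crossing_is_nyquist_limited(self, noise_pair):
        a, _ = noise_pair
        res = frc_resolution(frc(a, a))
        assert res.nyquist_limited and res.resolution_px == 2.0

    def test_hand_interpolated_crossing(self):
        # rings (0.20, 0.18) and (0.22, 0.12), threshold 1/7:
        # f* = 0.20 + 0.02*(0.18 - 1/7)/(0.18 - 0.12) ~= 0.2124 -> ~4.71 px
        curve = FRCCurve(np.array([0.20, 0.22]), np.array([0.18, 0.12]),
                         np.ones(2))
        res = frc_resolution(curve)
        assert not res.nyquist_limited
        assert res.resolution_px == pytest.approx(4.71, abs=0.01)

    def test_blur_coarsens_resolution_on_noisy_renders(self):
        from stedlite.synthdata import PhantomConfig, generate_emitters, render_modality

        em = generate_emitters(PhantomConfig(size_px=128, seed=4))
        res = {}
        for sigma in (1.0, 4.0):
            a = render_modality(em, sigma, 200.0, 0.01, seed=1)
            b = render_modality(em, sigma, 200.0, 0.01, seed=2)
            res[sigma] = frc_resolution(frc(a.pixels, b.pixels)).resolution_px
        assert res[4.0] > res[1.0]

    def test_degenerate_curve_rejected(self):
        with pytest.raises(ValueError):
            frc_resolution(FRCCurve(np.array([0.1]), np.array([0.5]), np.ones(1)))


class TestLineProfile:
    def test_horizontal_line_returns_row(self):
        rng = np.random.default_rng(5)
        img = rng.random((32, 32))
        prof = line_profile(img, (10, 0), (10, 31), n_samples=32)
        np.testing.assert_allclose(prof.intensities, img[10], atol=1e-12)

    def test_constant_image_constant_profile(self):
        prof = line_profile(np.full((16, 16), 0.7), (0, 0), (15, 15), 20)
        np.testing.assert_allclose(prof.intensities, 0.7, atol=1e-12)

    def test_diagonal_on_bilinear_ramp_is_linear(self):
        # f(r, c) = 2r + 3c is exactly reproduced by bilinear interpolation
        rr, cc = np.mgrid[0:16, 0:16]
        img = 2.0 * rr + 3.0 * cc
        prof = line_profile(img, (1.0, 2.0), (14.0, 13.0), n_samples=25)
        rows = np.linspace(1, 14, 25)
        cols = np.linspace(2, 13, 25)
        np.testing.assert_allclose(prof.intensities, 2 * rows + 3 * cols, atol=1e-9)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            line_profile(np.zeros((8, 8)), (0, 0), (8, 8), 5)


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        x = np.array([1.0, 2.0, 4.0, 7.0, 9.0])
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_five_vector(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        am, bm = a - a.mean(), b - b.mean()
        expect = np.sum(am * bm) / np.sqrt(np.sum(am**2) * np.sum(bm**2))
        assert pearson(a, b) == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson(np.ones(5), np.arange(5.0))


class TestSNRNonRef:
    def test_constructed_truth(self):
        # fg mean 10 sigma above bg with bg sd sigma -> SNR ~ 10
        rng = np.random.default_rng(6)
        sigma = 0.02
        img = rng.normal(0.1, sigma, (128, 128))
        img[40:80, 40:80] = rng.normal(0.1 + 10 * sigma, sigma, (40, 40))
        img = np.clip(img, 0, 1)
        assert snr_nonref(img) == pytest.approx(10.0, rel=0.25)

    def test_noisier_background_lowers_snr(self):
        rng = np.random.default_rng(7)
        base = np.zeros((64, 64)) + 0.1
        base[20:40, 20:40] = 0.9
        a = np.clip(base + rng.normal(0, 0.01, base.shape), 0, 1)
        b = np.clip(base + rng.normal(0, 0.05, base.shape), 0, 1)
        assert snr_nonref(b) < snr_nonref(a)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            snr_nonref(np.full((8, 8), 0.5))


class TestEdgePreservation:
    def test_constant_is_zero(self):
        assert edge_preservation(np.full((16, 16), 0.3)) == 0.0

    def test_blur_strictly_decreases_score(self):
        rng = np.random.default_rng(8)
        img = (rng.random((64, 64)) > 0.8).astype(float)
        scores = [edge_preservation(ndimage.gaussian_filter(img, s) if s else img)
                  for s in (0, 1, 2, 4)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_tenengrad_variant_available(self):
        img = np.random.default_rng(9).random((32, 32))
        assert edge_preservation(img, method="tenengrad") > 0


class TestDeviationMap:
    def test_identical_inputs_zero(self):
        x = np.random.default_rng(10).random((16, 16))
        m, score = deviation_map(x, x)
        assert score == 0.0 and m.sum() == 0.0

    def test_constant_gap_unit_score(self):
        _, score = deviation_map(np.zeros((8, 8)), np.ones((8, 8)))
        assert score == 1.0

    def test_flags_degraded_images(self):
        # a fixed reference vs HQ/LQ renders of the same phantom: the LQ
        # deviation exceeds the HQ deviation in most seeded trials
        from stedlite.imagecore import normalize_unit, MicroImage
        from stedlite.synthdata import PhantomConfig, degrade_low_quality, generate_phantom

        wins = 0
        for seed in range(20):
            ph = generate_phantom(PhantomConfig(size_px=64, seed=seed),
                                  modalities=("sted",))
            hq = ph.renderings["sted"]
            lq = degrade_low_quality(hq, 0.02, 0.4, 0.08, seed=seed)
            ref = normalize_unit(MicroImage(ph.emitters))
            _, s_hq = deviation_map(ref.pixels, hq.pixels)
            _, s_lq = deviation_map(ref.pixels, lq.pixels)
            wins += int(s_lq > s_hq)
        assert wins >= 14


class TestMetricReport:
    def test_identity_reference_point(self):
        img = np.random.default_rng(11).random((64, 64))
        rep = metric_report(img, img)
        assert rep.ssim == 1.0
        assert np.isinf(rep.psnr_db)
        assert rep.npsnr == 1.0
        assert rep.hf_disagreement == pytest.approx(0.0, abs=1e-10)
        assert rep.frc_resolution_px == 2.0
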