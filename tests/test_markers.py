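"""Marker unit tests: hand-computed examples, brute-force oracle
equivalence, and monotone response to the degradations each marker is
designed to detect."""

import math

import numpy as np
import pytest

from mmsim import fixtures as fx
from mmsim.image import Image, as_image, rescale_unit
from mmsim.markers import (
    EPSILON,
    FRC_THRESHOLD,
    FRCCurve,
    compute_frc,
    compute_markers,
    edge_energy_ratio,
    frc_markers,
    hf_sum,
    rms_contrast,
    snr_mu,
    snr_sigma,
    structural_complexity,
)

# ---------------------------------------------------------------- oracles


def hf_sum_oracle(px: np.ndarray) -> float:
    """Brute-force double loop over all frequency pixels."""
    ps = np.abs(np.fft.fftshift(np.fft.fft2(px))) ** 2
    nr, nc = ps.shape
    f_th = 0.375 * min(nr, nc)
    total = ps.sum()
    acc = 0.0
    for i in range(nr):
        for j in range(nc):
            fy, fxx = i - nr // 2, j - nc // 2
            if math.hypot(fy, fxx) > f_th:
                acc += ps[i, j]
    return acc / total


def sc_oracle(px: np.ndarray) -> float:
    """Per-pixel loop: central differences with replicated borders."""
    nr, nc = px.shape
    acc = 0.0
    for i in range(nr):
        for j in range(nc):
            jm, jp = max(j - 1, 0), min(j + 1, nc - 1)
            im, ip = max(i - 1, 0), min(i + 1, nr - 1)
            gx = 0.5 * (px[i, jp] - px[i, jm]) if 0 < j < nc - 1 else 0.5 * (px[i, jp] - px[i, jm])
            gy = 0.5 * (px[ip, j] - px[im, j])
            acc += math.sqrt(0.5 * (gx**2 + gy**2))
    return acc / (nr * nc)


def e_edge_oracle(px: np.ndarray) -> float:
    """Geometric loop over pixel radii from the image centre."""
    nr, nc = px.shape
    r_th = 0.375 * min(nr, nc)
    total = acc = 0.0
    for i in range(nr):
        for j in range(nc):
            total += px[i, j]
            if math.hypot(i - (nr - 1) / 2, j - (nc - 1) / 2) > r_th:
                acc += px[i, j]
    return acc / total


def frc_oracle(px: np.ndarray):
    """Brute-force ring sums over the split half-images."""
    nr, nc = px.shape[0] - px.shape[0] % 2, px.shape[1] - px.shape[1] % 2
    p = px[:nr, :nc]
    a = 0.5 * (p[0::2, 0::2] + p[1::2, 1::2])
    b = 0.5 * (p[0::2, 1::2] + p[1::2, 0::2])
    fa = np.fft.fftshift(np.fft.fft2(a))
    fb = np.fft.fftshift(np.fft.fft2(b))
    hr, hc = fa.shape
    n_rings = min(hr, hc) // 2
    corr = []
    for ring in range(1, n_rings + 1):
        num = da = db = 0.0
        for i in range(hr):
            for j in range(hc):
                r = round(math.hypot(i - hr // 2, j - hc // 2))
                if r == ring:
                    num += (fa[i, j] * np.conj(fb[i, j])).real
                    da += abs(fa[i, j]) ** 2
                    db += abs(fb[i, j]) ** 2
        corr.append(num / math.sqrt(da * db))
    freq = np.arange(1, n_rings + 1) / (2 * n_rings)
    return freq, np.array(corr)


# ----------------------------------------------------------- hand examples


class TestSnrHandExamples:
    def test_snr_sigma_symmetric_binary(self):
        # mu=0.5, sigma=0.5, s_max=1 -> 20 log10(1) = 0 dB
        img = as_image(np.array([[0.0, 1.0], [0.0, 1.0]]))
        assert snr_sigma(img) == pytest.approx(0.0, abs=1e-6)

    def test_snr_sigma_single_bright_pixel(self):
        img = as_image(np.array([[0.0, 0.0], [0.0, 1.0]]))
        expected = 20 * math.log10(0.75 / math.sqrt(0.1875))
        assert snr_sigma(img) == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(4.77, abs=0.01)

    def test_snr_mu_symmetric_binary(self):
        img = as_image(np.array([[0.0, 1.0], [0.0, 1.0]]))
        assert snr_mu(img) == pytest.approx(0.0, abs=1e-6)

    def test_snr_mu_single_bright_pixel(self):
        img = as_image(np.array([[0.0, 0.0], [0.0, 1.0]]))
        expected = 20 * math.log10(0.75 / 0.25)
        assert snr_mu(img) == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(9.54, abs=0.01)

    def test_degenerate_images_return_epsilon(self):
        assert snr_sigma(as_image(np.full((8, 8), 3.0))) == EPSILON
        assert snr_mu(as_image(np.zeros((8, 8)))) == EPSILON

    def test_background_mask_drives_statistics(self, rng):
        px = np.ones((16, 16))
        px[:8] = 0.05 + 0.01 * rng.random((8, 16))
        mask = np.zeros((16, 16), bool)
        mask[:8] = True
        masked = Image(px, background_mask=mask)
        unmasked = Image(px)
        assert snr_mu(masked) > snr_mu(unmasked)


class TestOracleEquivalence:
    """Vectorised markers match independent brute-force loops to 1e-10."""

    def test_hf_sum_random(self, rng):
        px = rng.random((32, 32))
        assert hf_sum(as_image(px)) == pytest.approx(hf_sum_oracle(px), rel=1e-10)

    def test_hf_sum_checkerboard(self):
        px = np.indices((32, 32)).sum(axis=0) % 2.0
        assert hf_sum(as_image(px)) == pytest.approx(hf_sum_oracle(px), rel=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_sc_random(self, seed):
        px = np.random.default_rng(seed).random((32, 32))
        assert structural_complexity(as_image(px)) == pytest.approx(
            sc_oracle(px), rel=1e-10
        )

    def test_sc_ramp(self):
        # horizontal ramp: interior gradient is the ramp step / sqrt(2) scaling
        px = np.tile(np.linspace(0, 1, 32), (32, 1))
        assert structural_complexity(as_image(px)) == pytest.approx(
            sc_oracle(px), rel=1e-10
        )

    def test_e_edge_random_and_uniform(self, rng):
        px = rng.random((32, 32))
        assert edge_energy_ratio(as_image(px)) == pytest.approx(
            e_edge_oracle(px), rel=1e-10
        )
        flat = np.ones((32, 32))
        assert edge_energy_ratio(as_image(flat)) == pytest.approx(
            e_edge_oracle(flat), rel=1e-10
        )

    def test_frc_matches_ring_sum_oracle(self, rng):
        px = rng.random((32, 32))
        freq, corr = frc_oracle(px)
        curve = compute_frc(as_image(px))
        np.testing.assert_allclose(curve.ring_frequency, freq)
        np.testing.assert_allclose(curve.correlation, corr, rtol=1e-10)


class TestDegenerateMarkers:
    def test_constant_image(self):
        img = as_image(np.full((16, 16), 5.0))
        assert hf_sum(rescale_unit(img)) == 0.0
        assert structural_complexity(rescale_unit(img)) == 0.0
        assert rms_contrast(rescale_unit(img)) == 0.0
        assert edge_energy_ratio(rescale_unit(img)) == EPSILON

    def test_center_pixel_only(self):
        px = np.zeros((17, 17))
        px[8, 8] = 1.0
        assert edge_energy_ratio(as_image(px)) == 0.0

    def test_binary_half_contrast(self):
        px = np.concatenate([np.zeros((8, 16)), np.ones((8, 16))])
        assert rms_contrast(as_image(px)) == pytest.approx(0.5)


class TestFRC:
    def test_white_noise_decorrelates(self):
        hi_means = []
        for seed in range(20):
            px = np.random.default_rng(seed).random((128, 128))
            curve = compute_frc(rescale_unit(as_image(px)))
            half = len(curve.correlation) // 2
            hi_means.append(np.abs(curve.correlation[half:]).mean())
        assert max(hi_means) < 0.2

    def test_gaussian_blob_crosses_early(self):
        # a band-limited blob plus faint noise: high correlation at low
        # frequency, early crossing where noise outweighs the blob spectrum
        # (a noise-free image correlates at every radius and never crosses)
        y, x = np.mgrid[0:128, 0:128]
        px = np.exp(-((y - 64.0) ** 2 + (x - 64.0) ** 2) / (2 * 16.0**2))
        px = px + 1e-3 * np.random.default_rng(0).normal(size=px.shape)
        curve = compute_frc(as_image(px))
        assert curve.correlation[0] > 0.9
        assert curve.resolution_freq is not None
        # crossing recorded from the brute-force oracle run
        freq, corr = frc_oracle(px)
        below = np.nonzero(corr < FRC_THRESHOLD)[0]
        i = below[0]
        t = (corr[i - 1] - FRC_THRESHOLD) / (corr[i - 1] - corr[i])
        oracle_cross = freq[i - 1] + t * (freq[i] - freq[i - 1])
        assert curve.resolution_freq == pytest.approx(oracle_cross, rel=1e-10)
        assert curve.resolution_freq < 0.15

    def test_correlation_bounded(self, rng):
        curve = compute_frc(as_image(rng.random((64, 64))))
        assert np.all(np.abs(curve.correlation) <= 1 + 1e-9)
        assert np.all(np.diff(curve.ring_frequency) > 0)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="minimum size"):
            compute_frc(np.zeros((4, 4)))

    def test_noise_free_frc_sum_exceeds_noisy(self):
        wins = 0
        for seed in range(20):
            clean = fx.generate_structure(structure="blobs", size=(64, 64), seed=seed)
            noisy = fx.apply_poisson_gaussian(
                clean, peak_photons=10, read_sigma=0.05, n_averaged=1, seed=seed + 1
            )
            _, s_clean = frc_markers(compute_frc(rescale_unit(clean)))
            _, s_noisy = frc_markers(compute_frc(rescale_unit(noisy)))
            wins += s_clean > s_noisy
        assert wins == 20


class TestFRCMarkers:
    def test_reciprocal_resolution(self):
        curve = FRCCurve(np.array([0.1, 0.25]), np.array([1.0, 0.1]), 0.25)
        res, _ = frc_markers(curve)
        assert res == pytest.approx(4.0)

    def test_sum_of_ones(self):
        curve = FRCCurve(np.linspace(0.05, 0.5, 10), np.ones(10), None)
        _, total = frc_markers(curve)
        assert total == pytest.approx(10.0)

    def test_nyquist_fallback(self):
        curve = FRCCurve(np.linspace(0.05, 0.5, 10), np.ones(10), None)
        res, _ = frc_markers(curve)
        assert res == pytest.approx(2.0)

    def test_negative_sum_floored(self):
        curve = FRCCurve(np.array([0.1, 0.2]), np.array([-0.5, -0.5]), 0.1)
        _, total = frc_markers(curve)
        assert total == EPSILON


class TestComputeMarkers:
    def test_constant_image_degenerate_panel(self):
        vec = compute_markers(as_image(np.full((16, 16), 2.0)))
        assert vec["HF_sum"] == 0.0
        assert vec["SC"] == 0.0
        assert vec["C_RMS"] == 0.0
        assert vec["SNR_sigma"] == EPSILON
        assert vec["SNR_mu"] == EPSILON
        assert vec["E_edge"] == EPSILON

    def test_subset_contract(self, structured_image):
        vec = compute_markers(structured_image, marker_set=["HF_sum"])
        assert list(vec.index) == ["HF_sum"]

    def test_unknown_marker_rejected(self, structured_image):
        with pytest.raises(ValueError, match="unknown marker"):
            compute_markers(structured_image, marker_set=["HF_sum", "bogus"])

    def test_deterministic(self, structured_image):
        v1 = compute_markers(structured_image)
        v2 = compute_markers(structured_image)
        assert (v1 == v2).all()

    def test_bounds_invariants(self, rng):
        for _ in range(5):
            vec = compute_markers(as_image(rng.random((32, 32))))
            assert (vec >= 0).all()
            assert 0 <= vec["HF_sum"] <= 1
            assert 0 <= vec["E_edge"] <= 1
            assert 0 <= vec["C_RMS"] <= 0.5


class TestMonotoneDirections:
    """Each degradation moves its target marker in the documented direction."""

    @pytest.fixture()
    def clean(self):
        return fx.generate_structure(structure="filaments", size=(96, 96), seed=3)

    def test_blur_decreases_hf_sum_and_sc(self, clean):
        # measured (noisy) acquisitions: blur removes structure and noise HF
        base = fx.apply_poisson_gaussian(clean, n_averaged=1, seed=5)
        blurs = [0.0, 1.0, 2.0, 3.0]
        hf = [compute_markers(fx.apply_defocus(base, b))["HF_sum"] for b in blurs]
        sc = [compute_markers(fx.apply_defocus(base, b))["SC"] for b in blurs]
        assert all(np.diff(hf) < 0)
        assert all(np.diff(sc) < 0)

    def test_noise_increases_c_rms(self, clean):
        # bounded detector range (saturation clip): noise adds variance
        # without inflating the min-max range the rescale divides by
        noisy = fx.apply_poisson_gaussian(
            clean, peak_photons=1e9, read_sigma=0.08, n_averaged=1, seed=5, clip=True
        )
        assert compute_markers(noisy)["C_RMS"] > compute_markers(clean)["C_RMS"]

    def test_offset_decreases_snr_mu(self, clean):
        # offset applied before the shot noise, as a detector offset would be
        plain = fx.apply_poisson_gaussian(clean, n_averaged=4, seed=9)
        offset = fx.apply_poisson_gaussian(
            fx.apply_offset(clean, 0.3), n_averaged=4, seed=9
        )
        assert compute_markers(offset)["SNR_mu"] < compute_markers(plain)["SNR_mu"]

    def test_vignetting_decreases_e_edge(self, clean):
        vign = fx.apply_vignetting(clean, 0.5)
        assert compute_markers(vign)["E_edge"] < compute_markers(clean)["E_edge"]
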