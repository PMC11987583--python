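"""Fourier ring anisotropy: transforms, FA images, ring moments, spectra.

FFT-path results are checked against independent brute-force oracles
(O(N^4) double-sum DFT, explicit index remapping, lookup loops, direct sums)
on small grids.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fourd as fd
from fourd.ring import (
    RingProfile,
    anisotropy_moments,
    average_spectra,
    extract_ring,
    fit_ring_series,
    max_ring,
)


def dft2_bruteforce(x: np.ndarray) -> np.ndarray:
    """Direct double-sum evaluation of the 2-D DFT (independent oracle)."""
    m, n = x.shape
    out = np.zeros((m, n), dtype=complex)
    for p in range(m):
        for q in range(n):
            acc = 0.0 + 0.0j
            for j in range(m):
                for k in range(n):
                    acc += x[j, k] * np.exp(-2j * np.pi * (j * p / m + k * q / n))
            out[p, q] = acc
    return out


def quadrant_swap_bruteforce(x: np.ndarray) -> np.ndarray:
    """Explicit index remap sending frequency (p, q) to the centred layout."""
    m, n = x.shape
    out = np.empty_like(x)
    for p in range(m):
        for q in range(n):
            out[(p + m // 2) % m, (q + n // 2) % n] = x[p, q]
    return out


class TestForwardTransform:
    def test_constant_image_single_dc_coefficient(self):
        img = fd.Image2D(values=np.full((8, 8), 3.0))
        y = fd.forward_transform(img).values
        assert y[0, 0] == pytest.approx(3.0 * 64)
        y[0, 0] = 0
        np.testing.assert_allclose(np.abs(y), 0, atol=1e-10)

    def test_round_trip_identity(self, rng):
        img = fd.Image2D(values=rng.normal(size=(16, 16)))
        back = fd.inverse_transform(fd.forward_transform(img)).real
        np.testing.assert_allclose(back, img.values, rtol=0, atol=1e-10)

    def test_matches_bruteforce_dft(self, rng):
        x = rng.normal(size=(4, 4))
        fast = fd.forward_transform(fd.Image2D(values=x)).values
        slow = dft2_bruteforce(x)
        np.testing.assert_allclose(fast, slow, rtol=1e-8, atol=1e-8)


class TestCentre:
    def test_centre_then_uncentre_is_identity(self, rng):
        f = fd.forward_transform(fd.Image2D(values=rng.normal(size=(6, 6))))
        back = fd.uncentre(fd.centre(f))
        np.testing.assert_array_equal(back.values, f.values)

    def test_matches_index_remap(self, rng):
        x = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
        centred = fd.centre(fd.FourierImage(values=x)).values
        np.testing.assert_array_equal(centred, quadrant_swap_bruteforce(x))

    def test_odd_dims_dc_lands_at_floor_centre(self, rng):
        x = np.zeros((5, 5))
        x[0, 0] = 7.0
        centred = fd.centre(fd.FourierImage(values=x)).values
        assert centred[2, 2] == 7.0

    def test_double_centring_rejected(self):
        f = fd.FourierImage(values=np.zeros((4, 4)), centred=True)
        with pytest.raises(ValueError, match="already centred"):
            fd.centre(f)


class TestAnisotropyImages:
    def test_identical_pair_gives_unity(self, rng):
        img = fd.Image2D(values=rng.uniform(1, 2, size=(16, 16)))
        fa = fd.anisotropy_image_pair(img, img)
        np.testing.assert_allclose(fa.values, 1.0, atol=1e-12)
        assert fa.mode == "pair" and fa.centred

    def test_scaled_pair_constant_fa(self, rng):
        h = fd.Image2D(values=rng.uniform(1, 2, size=(16, 16)))
        v = fd.Image2D(values=3.0 * h.values)
        fa = fd.anisotropy_image_pair(h, v)
        np.testing.assert_allclose(fa.values, 1.5, atol=1e-12)

    def test_g_factor_divides_designated_channel(self, rng):
        h = fd.Image2D(values=rng.uniform(1, 2, size=(16, 16)))
        v = fd.Image2D(values=1.13 * h.values)
        cal = fd.DetectionCalibration(g_factor=1.13, which_divided="vertical")
        fa = fd.anisotropy_image_pair(h, v, cal)
        np.testing.assert_allclose(fa.values, 1.0, atol=1e-12)

    def test_pair_matches_bruteforce(self, rng):
        h = rng.uniform(0.5, 1.5, size=(8, 8))
        v = rng.uniform(0.5, 1.5, size=(8, 8))
        fa = fd.anisotropy_image_pair(fd.Image2D(values=h), fd.Image2D(values=v)).values
        mh, mv = np.abs(dft2_bruteforce(h)), np.abs(dft2_bruteforce(v))
        expected = quadrant_swap_bruteforce(1.0 + (mv - mh) / (mv + mh))
        np.testing.assert_allclose(fa, expected, rtol=1e-8)

    def test_single_matches_bruteforce(self, rng):
        x = rng.uniform(0.5, 1.5, size=(8, 8))
        fa = fd.anisotropy_image_single(fd.Image2D(values=x)).values
        expected = quadrant_swap_bruteforce(np.abs(dft2_bruteforce(x)))
        np.testing.assert_allclose(fa, expected, rtol=1e-8)

    def test_constant_image_single_zero_off_dc(self):
        fa = fd.anisotropy_image_single(fd.Image2D(values=np.full((8, 8), 5.0)))
        assert fa.values[4, 4] == pytest.approx(5.0 * 64)
        off_dc = fa.values.copy()
        off_dc[4, 4] = 0
        np.testing.assert_allclose(off_dc, 0, atol=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_pair_fa_bounded(self, seed):
        """FA = 1 + (|a|-|b|)/(|a|+|b|) lies in [0, 2] for any image pair,
        which bounds the moments |gamma| <= 1."""
        r = np.random.default_rng(seed)
        h = fd.Image2D(values=r.uniform(0, 10, size=(12, 12)))
        v = fd.Image2D(values=r.uniform(0, 10, size=(12, 12)))
        fa = fd.anisotropy_image_pair(h, v)
        assert fa.values.min() >= 0.0 and fa.values.max() <= 2.0
        spec = fd.spectrum(fa)
        assert np.all(np.abs(spec.gamma_c) <= 1.0)
        assert np.all(np.abs(spec.gamma_s) <= 1.0)


class TestRings:
    def test_constant_fa_constant_profile(self):
        fa = fd.AnisotropyImage(values=np.full((32, 32), 1.3), centred=True, mode="pair")
        prof = extract_ring(fa, 7)
        np.testing.assert_allclose(prof.samples, 1.3)

    def test_delta_on_positive_column_axis_is_theta_zero(self):
        values = np.zeros((32, 32))
        values[16, 16 + 7] = 5.0  # offset +7 columns from centre
        fa = fd.AnisotropyImage(values=values, centred=True, mode="single")
        prof = extract_ring(fa, 7)
        hits = prof.thetas_rad[prof.samples > 0]
        assert hits.size > 0
        # nonzero samples only near theta = 0 (or wrapping just below 2*pi)
        assert np.all((hits < 0.2) | (hits > 2 * np.pi - 0.2))

    def test_matches_lookup_loop(self, rng):
        values = rng.uniform(0.5, 1.5, size=(16, 16))
        fa = fd.AnisotropyImage(values=values, centred=True, mode="pair")
        prof = extract_ring(fa, 7)
        for theta, sample in zip(prof.thetas_rad, prof.samples):
            row = round(8 - 7 * np.sin(theta))
            col = round(8 + 7 * np.cos(theta))
            assert sample == values[row, col]

    def test_radius_bounds_enforced(self):
        fa = fd.AnisotropyImage(values=np.ones((32, 32)), centred=True, mode="pair")
        with pytest.raises(ValueError):
            extract_ring(fa, 0)
        with pytest.raises(ValueError):
            extract_ring(fa, max_ring((32, 32)) + 1)

    def test_uncentred_input_rejected(self):
        fa = fd.AnisotropyImage(values=np.ones((32, 32)), centred=False, mode="pair")
        with pytest.raises(ValueError, match="centred"):
            extract_ring(fa, 5)

    def test_elliptical_ring_on_nonsquare_image(self):
        """On a 32x64 grid the ring index lives on the major (column) axis and
        the row semi-axis is halved."""
        values = np.zeros((32, 64))
        values[16, 32 + 10] = 1.0  # theta=0 at full radius on columns
        values[16 - 5, 32] = 1.0  # theta=90 at the scaled row semi-axis
        fa = fd.AnisotropyImage(values=values, centred=True, mode="single")
        prof = extract_ring(fa, 10, n_angles=4)
        assert prof.samples[0] == 1.0  # theta 0
        assert prof.samples[1] == 1.0  # theta 90


class TestMoments:
    def test_constant_profile_zero_moments(self):
        thetas = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        prof = RingProfile(radius=5, thetas_rad=thetas, samples=np.ones(64))
        gc, gs = anisotropy_moments(prof)
        assert gc == pytest.approx(0, abs=1e-12)
        assert gs == pytest.approx(0, abs=1e-12)

    @pytest.mark.parametrize("amp, which", [(0.5, "cos"), (0.8, "sin")])
    def test_pure_modulation_halved(self, amp, which):
        thetas = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        mod = np.cos(2 * thetas) if which == "cos" else np.sin(2 * thetas)
        prof = RingProfile(radius=5, thetas_rad=thetas, samples=1 + amp * mod)
        gc, gs = anisotropy_moments(prof)
        expected = (amp / 2, 0.0) if which == "cos" else (0.0, amp / 2)
        assert gc == pytest.approx(expected[0], abs=1e-9)
        assert gs == pytest.approx(expected[1], abs=1e-9)

    def test_matches_direct_sum(self, rng):
        thetas = np.linspace(0, 2 * np.pi, 96, endpoint=False)
        samples = rng.uniform(0.1, 2.0, 96)
        prof = RingProfile(radius=5, thetas_rad=thetas, samples=samples)
        gc, gs = anisotropy_moments(prof)
        gc_slow = sum(s * np.cos(2 * t) for s, t in zip(samples, thetas)) / samples.sum()
        gs_slow = sum(s * np.sin(2 * t) for s, t in zip(samples, thetas)) / samples.sum()
        assert gc == pytest.approx(gc_slow, abs=1e-12)
        assert gs == pytest.approx(gs_slow, abs=1e-12)

    def test_nonpositive_profile_warns_and_zeroes(self):
        thetas = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        prof = RingProfile(radius=3, thetas_rad=thetas, samples=np.zeros(16))
        with pytest.warns(UserWarning, match="non-positive"):
            assert anisotropy_moments(prof) == (0.0, 0.0)

    def test_series_fit_recovers_coefficients(self):
        thetas = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        prof = RingProfile(
            radius=4, thetas_rad=thetas, samples=1.0 + 0.3 * np.cos(2 * thetas) - 0.1 * np.sin(2 * thetas)
        )
        a0, a2, b2 = fit_ring_series(prof)
        assert a0 == pytest.approx(2.0, abs=1e-9)  # model a0/2 + ...
        assert a2 == pytest.approx(0.3, abs=1e-9)
        assert b2 == pytest.approx(-0.1, abs=1e-9)


class TestSpectrum:
    def test_identical_pair_zero_spectrum(self, rng):
        img = fd.Image2D(values=rng.uniform(1, 2, size=(64, 64)))
        spec = fd.spectrum(fd.anisotropy_image_pair(img, img))
        np.testing.assert_allclose(spec.gamma_c, 0, atol=1e-12)
        np.testing.assert_allclose(spec.gamma_s, 0, atol=1e-12)
        assert spec.frequencies[0] == 1  # DC excluded

    def test_free_dye_pair_flat_about_zero(self, demo_field):
        """Unpolarised emission (s=0): both moment spectra stay within 0.05 of
        zero at every frequency, the free-dye signature."""
        h, v = fd.simulate_polarised_pair(demo_field, 0.0, seed=17)
        spec = fd.spectrum(fd.anisotropy_image_pair(h, v))
        assert np.abs(spec.gamma_c).max() < 0.05
        assert np.abs(spec.gamma_s).max() < 0.05

    def test_emission_parallel_to_fibres_positive_cosine(self, polarised_pair):
        """Emission polarised along fibres: gamma_c > 0 at intermediate
        frequencies and ~0 at the highest (noise-dominated) rings."""
        h, v = polarised_pair
        spec = fd.spectrum(fd.anisotropy_image_pair(h, v))
        mid = (spec.frequencies >= 5) & (spec.frequencies <= 50)
        high = spec.frequencies >= 200
        assert spec.gamma_c[mid].mean() > 0.1
        assert abs(spec.gamma_c[high].mean()) < 0.02
        assert abs(spec.gamma_s[mid].mean()) < 0.02  # axes aligned with polariser

    def test_misalignment_robustness(self, polarised_pair):
        """Translating one channel by up to 2 px barely changes the moments:
        position lives in the phase, which FA discards."""
        h, v = polarised_pair
        base = fd.spectrum(fd.anisotropy_image_pair(h, v), r_min=5, r_max=50)
        rolled = fd.Image2D(values=np.roll(v.values, (2, 1), axis=(0, 1)))
        shifted = fd.spectrum(fd.anisotropy_image_pair(h, rolled), r_min=5, r_max=50)
        np.testing.assert_allclose(shifted.gamma_c, base.gamma_c, atol=1e-12)
        from scipy.ndimage import shift as ndshift

        sub = fd.Image2D(values=ndshift(v.values, (1.3, 0.7), order=3, mode="nearest"))
        spec_sub = fd.spectrum(fd.anisotropy_image_pair(h, sub), r_min=5, r_max=50)
        assert np.abs(spec_sub.gamma_c - base.gamma_c).max() < 0.02

    def test_point_symmetry_of_fa(self, demo_image):
        """Real input: FA is point-symmetric about the centre, so profiles
        satisfy FA(theta) = FA(theta+pi)."""
        fa = fd.anisotropy_image_single(demo_image)
        prof = extract_ring(fa, 20, n_angles=360)
        np.testing.assert_allclose(prof.samples[:180], prof.samples[180:], rtol=1e-9)

    def test_average_spectra(self, rng):
        img1 = fd.Image2D(values=rng.uniform(1, 2, size=(64, 64)))
        img2 = fd.Image2D(values=rng.uniform(1, 2, size=(64, 64)))
        s1 = fd.spectrum(fd.anisotropy_image_single(img1))
        s2 = fd.spectrum(fd.anisotropy_image_single(img2))
        avg = average_spectra([s1, s2])
        np.testing.assert_allclose(avg.gamma_c, (s1.gamma_c + s2.gamma_c) / 2)


class TestPerrin:
    def test_fast_rotation_kills_anisotropy(self):
        r = fd.perrin_anisotropy(fd.PerrinParams(r0=0.4, tau_f=1.0, tau_rot=1e-6))
        assert r == pytest.approx(0.0, abs=1e-6)

    def test_equal_times_halve(self):
        assert fd.perrin_anisotropy(fd.PerrinParams(0.4, 2.0, 2.0)) == pytest.approx(0.2)

    def test_immobilised_limit(self):
        r = fd.perrin_anisotropy(fd.PerrinParams(r0=0.4, tau_f=1e-9, tau_rot=10.0))
        assert r == pytest.approx(0.4, rel=1e-6)

    def test_invalid_times_rejected(self):
        with pytest.raises(ValueError):
            fd.PerrinParams(0.4, -1.0, 1.0)
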