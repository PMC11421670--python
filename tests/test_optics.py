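"""Wave-optics core: chromatic defocus, pupil phase, PSFs, MTFs."""

import math

import numpy as np
import pytest

from chromacc.optics import (
    ARCMIN_PER_RAD,
    EyeModel,
    GridConfig,
    OPTICS_WAVELENGTHS_NM,
    PSFGrid,
    build_otf_library,
    chromatic_defocus,
    mono_psf,
    poly_psf,
    psf_to_mtf,
    pupil_phase,
    spectral_weights,
    zernike,
)
from chromacc.spectra import LED_PRIMARIES, Spectrum, gaussian_led_spectrum

from _oracles import circular_mtf, quadrature_psf

EYE5 = EyeModel(pupil_diameter_mm=5.0)
GRID256 = GridConfig(n=256)
GRID512 = GridConfig(n=512)


class TestChromaticDefocus:
    def test_reference_wavelength_near_zero(self):
        assert abs(chromatic_defocus(0.580)) < 1e-3

    def test_green_orange_difference(self):
        d = chromatic_defocus(0.527) - chromatic_defocus(0.588)
        assert d == pytest.approx(-0.330, abs=1e-3)

    def test_strictly_increasing_over_visible_range(self):
        wl = np.linspace(0.400, 0.700, 301)
        d = chromatic_defocus(wl)
        assert np.all(np.diff(d) > 0)
        assert chromatic_defocus(0.700) > chromatic_defocus(0.400)

    def test_rejects_wavelength_near_singularity(self):
        with pytest.raises(ValueError, match="µm"):
            chromatic_defocus(0.25)


class TestPupilPhase:
    def test_diffraction_limited_phase_is_zero(self):
        r = np.linspace(0, EYE5.pupil_radius_m, 50)
        th = np.linspace(0, 2 * math.pi, 50)
        assert np.all(pupil_phase(EYE5, 550.0, 0.0, r, th) == 0.0)

    def test_defocus_phase_proportional_to_r_squared(self):
        r = np.linspace(0, EYE5.pupil_radius_m, 50)
        th = np.zeros_like(r)
        ph = pupil_phase(EYE5, 550.0, 0.5, r, th)
        np.testing.assert_allclose(ph, ph[-1] * (r / r[-1]) ** 2, atol=1e-12)

    def test_peak_to_valley_matches_standard_relation(self):
        dF, lam = 0.75, 632.8e-9
        R = EYE5.pupil_radius_m
        ph = pupil_phase(EYE5, 632.8, dF, np.array([0.0, R]), np.zeros(2))
        assert ph[1] - ph[0] == pytest.approx(math.pi * dF * R**2 / lam, rel=1e-9)

    def test_zernike_invalid_index_rejected(self):
        with pytest.raises(ValueError, match="Zernike"):
            zernike(3, 2, np.array([0.5]), np.array([0.0]))

    def test_zernike_defocus_term_rms_normalized(self):
        # unit-variance normalization: <Z²> = 1 over the unit disc
        rng = np.random.default_rng(0)
        rho = np.sqrt(rng.uniform(0, 1, 200_000))
        th = rng.uniform(0, 2 * math.pi, 200_000)
        for (n, m) in [(2, 0), (3, 1), (4, 0), (2, -2)]:
            z = zernike(n, m, rho, th)
            assert np.mean(z**2) == pytest.approx(1.0, abs=0.02)


class TestMonoPSF:
    def test_normalized_odd_and_centred(self):
        psf = mono_psf(EYE5, 550.0, 0.0, GRID256)
        n = psf.intensity.shape[0]
        assert n % 2 == 1
        assert psf.intensity.sum() == pytest.approx(1.0, abs=1e-12)
        peak = np.unravel_index(np.argmax(psf.intensity), psf.intensity.shape)
        assert peak == (psf.centre, psf.centre)

    def test_defocus_lowers_peak_intensity(self):
        dl = mono_psf(EYE5, 550.0, 0.0, GRID256)
        df = mono_psf(EYE5, 550.0, 0.5, GRID256)
        assert df.intensity.max() < dl.intensity.max()

    def test_airy_first_zero_scales_with_wavelength(self):
        # radius of the first dark ring grows as 1.22 λ/d
        grid = GridConfig(n=512, pitch_arcmin=0.05)
        for wl in (450.0, 550.0, 650.0):
            psf = mono_psf(EYE5, wl, 0.0, grid)
            c = psf.centre
            profile = psf.intensity[c, c:]
            mins = [
                i
                for i in range(1, 40)
                if profile[i] < profile[i - 1] and profile[i] <= profile[i + 1]
            ]
            expected = 1.22 * wl * 1e-9 / (5e-3) * ARCMIN_PER_RAD
            measured = mins[0] * psf.pitch_arcmin
            assert measured == pytest.approx(expected, rel=0.08)

    def test_sampling_bounds_enforced(self):
        with pytest.raises(ValueError, match="padding"):
            GridConfig(n=64, pitch_arcmin=0.25).pupil_samples(EYE5, 400.0)
        with pytest.raises(ValueError, match="pitch"):
            GridConfig(n=512, pitch_arcmin=0.3).pitch_rad(EYE5)
        with pytest.raises(ValueError, match="16"):
            GridConfig(n=128, pitch_arcmin=0.02).pupil_samples(EYE5, 700.0)

    def test_matches_brute_force_quadrature_on_random_cases(self):
        """Transform-based PSF vs direct quadrature of the pupil integral."""
        rng = np.random.default_rng(42)
        grid = GridConfig(n=1024, pitch_arcmin=0.12)
        for case in range(5):
            dF = float(rng.uniform(-0.3, 0.3))
            zern = {}
            if case >= 1:
                zern[(4, 0)] = float(rng.uniform(-0.05, 0.05))
            if case >= 3:
                zern[(3, 1)] = float(rng.uniform(-0.05, 0.05))
            eye = EyeModel(pupil_diameter_mm=5.0, zernike_um=zern)
            psf = mono_psf(eye, 550.0, dF, grid)
            c = psf.centre
            pitch_rad = psf.pitch_arcmin / ARCMIN_PER_RAD
            offs = np.arange(-3, 4)
            OX, OY = np.meshgrid(offs, offs, indexing="xy")
            tx, ty = OX * pitch_rad, OY * pitch_rad
            impl = psf.intensity[c + OY, c + OX]
            oracle = quadrature_psf(eye, 550.0, dF, tx, ty)
            impl = impl / impl.max()
            oracle = oracle / oracle.max()
            assert np.max(np.abs(impl - oracle)) < 1e-3


class TestMTF:
    def test_dl_mtf_matches_circular_aperture_closed_form(self):
        psf = mono_psf(EYE5, 550.0, 0.0, GRID512)
        mtf = psf_to_mtf(psf)
        cutoff = 5e-3 / 550e-9 * math.pi / 180.0  # cycles/deg
        nu = mtf.frequencies_cpd / cutoff
        keep = mtf.frequencies_cpd <= cutoff
        assert np.max(np.abs(mtf.modulation[keep] - circular_mtf(nu[keep]))) < 0.01

    def test_mtf_starts_at_unity_and_reaches_60cpd(self):
        mtf = psf_to_mtf(mono_psf(EYE5, 550.0, 0.3, GRID256))
        assert mtf.modulation[0] == pytest.approx(1.0)
        assert mtf.frequencies_cpd[-1] >= 60.0

    def test_defocused_mtf_below_dl_everywhere(self):
        dl = psf_to_mtf(mono_psf(EYE5, 550.0, 0.0, GRID256))
        df = psf_to_mtf(mono_psf(EYE5, 550.0, 0.4, GRID256))
        assert np.all(df.modulation <= dl.modulation + 1e-6)


class TestPolyPSF:
    def test_single_line_spectrum_equals_mono(self, curves):
        wl = OPTICS_WAVELENGTHS_NM
        vals = np.zeros_like(wl)
        vals[wl == 550.0] = 1.0
        line = Spectrum(wl, vals, "line550")
        b = 0.1
        poly = poly_psf(EYE5, line, curves, b, grid=GRID256)
        dF = chromatic_defocus(0.550) - b
        mono = mono_psf(EYE5, 550.0, dF, GRID256)
        np.testing.assert_allclose(poly.intensity, mono.intensity, atol=1e-12)

    def test_two_line_spectrum_is_weighted_sum(self, curves):
        wl = OPTICS_WAVELENGTHS_NM
        v1 = np.zeros_like(wl)
        v1[wl == 500.0] = 1.0
        v2 = np.zeros_like(wl)
        v2[wl == 600.0] = 1.0
        both = Spectrum(wl, v1 + v2, "two-line")
        poly = poly_psf(EYE5, both, curves, 0.0, grid=GRID256)
        w = spectral_weights(both, curves, "luminance")
        parts = []
        for wli, wi in zip(wl, w):
            if wi > 0:
                dF = chromatic_defocus(wli * 1e-3)
                parts.append(wi * mono_psf(EYE5, wli, dF, GRID256).intensity)
        expected = sum(parts)
        expected /= expected.sum()
        np.testing.assert_allclose(poly.intensity, expected, rtol=1e-9, atol=1e-12)

    def test_red_led_through_focus_peak_near_demand(self, curves):
        """Peak retinal intensity is maximal when the red LED is in focus."""
        red = gaussian_led_spectrum(LED_PRIMARIES["red"])
        demand = chromatic_defocus(0.660)
        sweep = np.arange(demand - 0.3, demand + 0.3 + 1e-9, 0.05)
        peaks = [
            poly_psf(EYE5, red, curves, b, grid=GRID256).intensity.max()
            for b in sweep
        ]
        best = sweep[int(np.argmax(peaks))]
        assert abs(best - demand) <= 0.1

    def test_zero_weighted_spectrum_rejected(self, curves):
        wl = OPTICS_WAVELENGTHS_NM
        vals = np.zeros_like(wl)
        vals[0] = 1.0  # 400 nm: outside every channel's support? V(400) > 0
        # construct a spectrum entirely outside the optics grid instead
        spec = Spectrum(np.arange(750.0, 781.0), np.ones(31), "ir")
        with pytest.raises(ValueError, match="zero"):
            spectral_weights(spec, curves, "luminance")


class TestOTFLibrary:
    def test_poly_mtf_matches_direct_psf_route(self, curves, lib5):
        """Library route and explicit poly-PSF route agree on the MTF."""
        red = gaussian_led_spectrum(LED_PRIMARIES["red"])
        w = spectral_weights(red, curves, "luminance", lib5.wavelengths_nm)
        ib = int(np.argmin(np.abs(lib5.baseline_D - 0.3)))
        b = float(lib5.baseline_D[ib])
        mtf_lib = lib5.poly_mtf(w)[ib]
        psf = poly_psf(lib5.eye, red, curves, b, grid=lib5.grid)
        mtf_direct = psf_to_mtf(psf)
        n = min(mtf_lib.size, mtf_direct.modulation.size)
        assert np.max(np.abs(mtf_lib[:n] - mtf_direct.modulation[:n])) < 5e-3

    def test_rejects_non_axisymmetric_eye(self):
        eye = EyeModel(pupil_diameter_mm=5.0, zernike_um={(3, 1): 0.1})
        with pytest.raises(ValueError, match="axisymmetric"):
            build_otf_library(eye, GRID256, np.array([0.0, 0.01, 0.02]))

    def test_energy_conservation_through_combination(self, curves):
        red = gaussian_led_spectrum(LED_PRIMARIES["red"])
        psf = poly_psf(EYE5, red, curves, 0.0, grid=GRID256)
        assert psf.intensity.sum() == pytest.approx(1.0, abs=1e-12)


class TestPSFGridType:
    def test_requires_odd_square_normalized(self):
        with pytest.raises(ValueError, match="odd"):
            PSFGrid(np.ones((4, 4)) / 16.0, 0.1)
        with pytest.raises(ValueError, match="normalized"):
            PSFGrid(np.ones((3, 3)), 0.1)
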