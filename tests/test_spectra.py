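"""Spectra, reference curves and the two-primary stimulus design."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromacc.spectra import (
    DEFAULT_GRID_NM,
    LED_PAIRS,
    LED_PRIMARIES,
    LEDPrimary,
    MixtureDesign,
    Spectrum,
    experiment_splits,
    gaussian_led_spectrum,
    generate_experiment_set,
    mix_spectra,
    relative_luminance,
    scale_to_luminance,
    stimulus_set_to_frame,
)


class TestSpectrumType:
    def test_rejects_nonuniform_grid(self):
        with pytest.raises(ValueError, match="uniform"):
            Spectrum(np.array([400.0, 401.0, 403.0]), np.ones(3))

    def test_rejects_negative_values(self):
        with pytest.raises(ValueError, match="non-negative"):
            Spectrum(np.array([400.0, 401.0]), np.array([1.0, -0.1]))

    def test_rejects_all_zero(self):
        with pytest.raises(ValueError, match="positive"):
            Spectrum(np.array([400.0, 401.0]), np.zeros(2))

    def test_csv_round_trip(self, tmp_path):
        spec = gaussian_led_spectrum(LED_PRIMARIES["green"])
        path = tmp_path / "green.csv"
        spec.to_csv(path)
        back = Spectrum.from_csv(path, label="green")
        np.testing.assert_allclose(back.values, spec.values, rtol=1e-9)


class TestGaussianLED:
    def test_peak_normalized_to_one(self):
        spec = gaussian_led_spectrum(LED_PRIMARIES["red"])
        assert spec.values[spec.wavelengths_nm == 660.0][0] == pytest.approx(1.0)

    def test_fwhm_definition(self):
        grid = np.arange(380.0, 780.5, 0.5)
        spec = gaussian_led_spectrum(LEDPrimary("red", 660.0, 25.0), grid)
        for wl in (660.0 - 12.5, 660.0 + 12.5):
            v = spec.values[spec.wavelengths_nm == wl][0]
            assert v == pytest.approx(0.5, abs=1e-6)

    @pytest.mark.parametrize("name", list(LED_PRIMARIES))
    def test_tails_below_two_permille_at_three_fwhm(self, name):
        led = LED_PRIMARIES[name]
        spec = gaussian_led_spectrum(led)
        for sign in (-1, 1):
            wl = led.peak_nm + sign * 3 * led.fwhm_nm
            if DEFAULT_GRID_NM[0] <= wl <= DEFAULT_GRID_NM[-1]:
                v = np.interp(wl, spec.wavelengths_nm, spec.values)
                assert v < 0.002

    def test_peak_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside the grid"):
            gaussian_led_spectrum(LED_PRIMARIES["red"], np.arange(380.0, 600.0))


class TestPhotometry:
    def test_luminance_linear_in_spectrum(self, curves):
        spec = gaussian_led_spectrum(LED_PRIMARIES["orange"])
        lum = relative_luminance(spec, curves)
        assert relative_luminance(spec.scaled(2.0), curves) == pytest.approx(2 * lum)

    def test_green_more_luminous_than_red_at_equal_radiance(self, curves):
        red = gaussian_led_spectrum(LED_PRIMARIES["red"])
        green = gaussian_led_spectrum(LED_PRIMARIES["green"])
        assert relative_luminance(green, curves) > relative_luminance(red, curves)

    def test_scale_round_trip(self, curves):
        spec = gaussian_led_spectrum(LED_PRIMARIES["blue"])
        scaled = scale_to_luminance(spec, 10.0, curves)
        assert relative_luminance(scaled, curves) == pytest.approx(10.0, rel=1e-9)
        halved = scale_to_luminance(scaled, 5.0, curves)
        np.testing.assert_allclose(halved.values, scaled.values / 2, rtol=1e-9)

    def test_zero_target_gives_zero_spectrum(self, curves):
        spec = gaussian_led_spectrum(LED_PRIMARIES["red"])
        z = scale_to_luminance(spec, 0.0, curves)
        assert not np.any(z.values)

    def test_zero_spectrum_with_positive_target_rejected(self, curves):
        z = gaussian_led_spectrum(LED_PRIMARIES["red"]).scaled(0.0)
        with pytest.raises(ValueError, match="zero-luminance"):
            scale_to_luminance(z, 5.0, curves)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        la=st.floats(0.1, 15.0),
        lb=st.floats(0.1, 15.0),
    )
    def test_mixture_luminances_add(self, la, lb):
        curves = _CURVES
        red = gaussian_led_spectrum(LED_PRIMARIES["red"])
        blue = gaussian_led_spectrum(LED_PRIMARIES["blue"])
        mixed = mix_spectra(red, blue, la, lb, curves)
        assert relative_luminance(mixed, curves) == pytest.approx(la + lb, rel=1e-9)

    def test_removing_one_component_recovers_the_other(self, curves):
        red = gaussian_led_spectrum(LED_PRIMARIES["red"])
        blue = gaussian_led_spectrum(LED_PRIMARIES["blue"])
        mixed = mix_spectra(red, blue, 8.75, 1.25, curves)
        alone = mix_spectra(red, blue, 8.75, 0.0, curves)
        scaled = scale_to_luminance(red, 8.75, curves)
        np.testing.assert_allclose(alone.values, scaled.values, rtol=1e-12)
        np.testing.assert_allclose(
            mixed.values - scale_to_luminance(blue, 1.25, curves).values,
            scaled.values,
            rtol=1e-9,
            atol=1e-12,
        )

    def test_mismatched_grids_rejected(self, curves):
        red = gaussian_led_spectrum(LED_PRIMARIES["red"])
        blue = gaussian_led_spectrum(
            LED_PRIMARIES["blue"], np.arange(380.0, 781.0, 2.0)
        )
        with pytest.raises(ValueError, match="grid"):
            mix_spectra(red, blue, 5.0, 5.0, curves)


class TestReferenceCurves:
    def test_curves_nonnegative_and_peak_normalized(self, curves):
        for name in ("vlambda", "cone_L", "cone_M", "cone_S", "d65"):
            spec = getattr(curves, name if name != "vlambda" else "vlambda")
            assert np.all(spec.values >= 0)
            assert spec.values.max() == pytest.approx(1.0)
            assert spec.wavelengths_nm[0] <= 400 and spec.wavelengths_nm[-1] >= 700

    def test_vlambda_peak_in_green(self, curves):
        wl = curves.vlambda.wavelengths_nm
        peak = wl[np.argmax(curves.vlambda.values)]
        assert 540 <= peak <= 570

    def test_tables_immutable(self, curves):
        with pytest.raises(ValueError):
            curves.vlambda.values[0] = 2.0


class TestExperimentSet:
    def test_counts(self, experiment_set):
        assert len(experiment_set) == 47
        assert sum(1 for e in experiment_set if len(e.pair) == 2) == 42

    def test_all_luminances_ten(self, experiment_set, curves):
        for e in experiment_set:
            assert relative_luminance(e.spectrum, curves) == pytest.approx(
                10.0, rel=1e-9
            )

    def test_six_pairs_seven_splits(self, experiment_set):
        mixtures = [e for e in experiment_set if len(e.pair) == 2]
        pairs = {e.pair for e in mixtures}
        assert pairs == set(LED_PAIRS)
        for pair in LED_PAIRS:
            splits = [e.lum_long for e in mixtures if e.pair == pair]
            assert splits == [s for s, _ in experiment_splits()]

    def test_deterministic_and_order_stable(self, curves, experiment_set):
        again = generate_experiment_set(curves)
        assert [e.label for e in again] == [e.label for e in experiment_set]
        for a, b in zip(again, experiment_set):
            np.testing.assert_array_equal(a.spectrum.values, b.spectrum.values)

    def test_long_format_export(self, experiment_set):
        frame = stimulus_set_to_frame(experiment_set[:2])
        assert list(frame.columns) == [
            "label",
            "pair",
            "lum_long",
            "lum_short",
            "wavelength_nm",
            "value",
        ]
        assert frame.label.nunique() == 2

    def test_mixture_design_validates_total(self):
        with pytest.raises(ValueError, match="sum"):
            MixtureDesign(("red", "blue"), (5.0, 4.0))


_CURVES = None


def setup_module(module):
    from chromacc.spectra import ReferenceCurves

    module._CURVES = ReferenceCurves()
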