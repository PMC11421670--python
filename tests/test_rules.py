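"""Accommodation-prediction rules over through-focus sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromacc.optics import EyeModel, GridConfig, chromatic_defocus
from chromacc.rules import (
    DEFAULT_SWEEP_GRID,
    PredictionResult,
    ThroughFocusSweep,
    mixture_response_curve,
    parse_metric,
    predict_equate_lm,
    predict_global,
    predict_local,
    sweep_from_library,
    through_focus_sweep,
)
from chromacc.spectra import (
    LED_PRIMARIES,
    gaussian_led_spectrum,
    mix_spectra,
    scale_to_luminance,
)

EYE5 = EyeModel(pupil_diameter_mm=5.0)


def _demand(nm: float) -> float:
    return chromatic_defocus(nm * 1e-3)


def _led(name: str, curves):
    return scale_to_luminance(gaussian_led_spectrum(LED_PRIMARIES[name]), 10.0, curves)


def _mixture(a: str, b: str, lum_a: float, curves):
    return mix_spectra(
        gaussian_led_spectrum(LED_PRIMARIES[a]),
        gaussian_led_spectrum(LED_PRIMARIES[b]),
        lum_a,
        10.0 - lum_a,
        curves,
        f"{a}-{b}_{lum_a}",
    )


class TestParseMetric:
    def test_contrast_spec(self):
        assert parse_metric("contrast@4") == ("contrast", 4.0)
        assert parse_metric("contrast@2.5cpd") == ("contrast", 2.5)

    def test_unknown_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            parse_metric("sharpness")


class TestSweeps:
    def test_single_red_vsr_peaks_near_demand(self, curves, lib5):
        sweep = sweep_from_library(lib5, _led("red", curves), curves, "vsr")
        res = predict_global(sweep)
        assert not res.ambiguous
        assert res.predicted_defocus_D[0] == pytest.approx(_demand(660.0), abs=0.05)

    def test_equal_mixture_has_two_vsr_peaks(self, curves, lib5):
        sweep = sweep_from_library(
            lib5, _mixture("red", "blue", 5.0, curves), curves, "vsr"
        )
        v = sweep.values
        interior_peaks = [
            i
            for i in range(1, v.size - 1)
            if v[i] > v[i - 1] and v[i] >= v[i + 1] and v[i] > 0.5 * v.max()
        ]
        assert len(interior_peaks) == 2

    def test_r50_sweep_inverted_relative_to_vsr_monochromatic(self, curves):
        """R50 minima sit where VSR peaks for a narrowband source."""
        grid_D = np.arange(-0.2, 0.85, 0.05)
        red = _led("red", curves)
        cfg = GridConfig(n=256)
        vsr = through_focus_sweep(EYE5, red, curves, "vsr", grid_D=grid_D, grid=cfg)
        r50s = through_focus_sweep(EYE5, red, curves, "r50", grid_D=grid_D, grid=cfg)
        best_v = grid_D[int(np.argmax(vsr.values))]
        best_r = grid_D[int(np.argmin(r50s.values))]
        assert abs(best_v - best_r) <= 0.1
        assert r50s.minimizing

    def test_lib_metric_sweep_peaks_near_demand(self, curves):
        grid_D = np.arange(0.0, 0.65, 0.05)
        red = _led("red", curves)
        sweep = through_focus_sweep(
            EYE5, red, curves, "lib", grid_D=grid_D, grid=GridConfig(n=256)
        )
        res = predict_global(sweep)
        assert res.predicted_defocus_D[0] == pytest.approx(_demand(660.0), abs=0.1)

    def test_sweep_validation(self):
        with pytest.raises(ValueError, match="uniform"):
            ThroughFocusSweep(np.array([0.0, 0.1, 0.3]), np.ones(3), "vsr")
        with pytest.raises(ValueError, match="finite"):
            ThroughFocusSweep(
                np.array([0.0, 0.1, 0.2]), np.array([1.0, np.nan, 1.0]), "vsr"
            )


class TestPredictGlobal:
    def test_mixture_never_predicts_midway(self, curves, lib5):
        """The VSR optimum sits at one primary demand, never between them."""
        d_red, d_blue = _demand(660.0), _demand(461.0)
        for lum_red in (8.75, 6.25, 5.0, 3.75, 1.25):
            sweep = sweep_from_library(
                lib5, _mixture("red", "blue", lum_red, curves), curves, "vsr"
            )
            pred = predict_global(sweep).single()
            near_red = abs(pred - d_red) < 0.1
            near_blue = abs(pred - d_blue) < 0.1
            assert near_red or near_blue
            if lum_red > 5.0:
                assert near_red
            elif lum_red < 5.0:
                assert near_blue

    def test_exact_symmetric_tie_is_flagged(self):
        g = np.arange(-1.0, 1.0001, 0.01)
        vals = np.exp(-((np.abs(g) - 0.5) ** 2) / 0.01)
        res = predict_global(ThroughFocusSweep(g, vals, "vsr"))
        assert res.ambiguous
        assert len(res.predicted_defocus_D) == 2
        np.testing.assert_allclose(
            sorted(np.abs(res.predicted_defocus_D)), [0.5, 0.5], atol=0.01
        )

    def test_constant_sweep_is_ambiguous(self):
        g = np.arange(0.0, 0.1, 0.01)
        res = predict_global(ThroughFocusSweep(g, np.ones_like(g), "vsr"))
        assert res.ambiguous and res.predicted_defocus_D == ()

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        scale=st.floats(0.1, 50.0),
        offset=st.floats(0.0, 5.0),
        seed=st.integers(0, 1000),
    )
    def test_invariant_to_positive_affine_rescaling(self, scale, offset, seed):
        rng = np.random.default_rng(seed)
        g = np.arange(-0.5, 0.5001, 0.01)
        vals = rng.random(g.size) + 0.1
        a = predict_global(ThroughFocusSweep(g, vals, "vsr"))
        b = predict_global(ThroughFocusSweep(g, scale * vals + offset, "vsr"))
        assert a.ambiguous == b.ambiguous
        np.testing.assert_allclose(a.predicted_defocus_D, b.predicted_defocus_D)


class TestPredictLocal:
    def test_stays_on_red_peak_from_red_start(self, curves, lib5):
        sweep = sweep_from_library(
            lib5, _mixture("red", "blue", 3.75, curves), curves, "vsr"
        )
        res = predict_local(sweep, _demand(660.0))
        assert res.predicted_defocus_D[0] == pytest.approx(_demand(660.0), abs=0.1)
        # global rule would go to the blue peak for a blue-majority mixture
        res_g = predict_global(sweep).single()
        assert abs(res_g - _demand(461.0)) < 0.1

    def test_unimodal_sweep_matches_global(self, curves, lib5):
        sweep = sweep_from_library(lib5, _led("green", curves), curves, "vsr")
        local = predict_local(sweep, 0.5)
        global_ = predict_global(sweep)
        assert local.predicted_defocus_D[0] == pytest.approx(
            global_.predicted_defocus_D[0], abs=0.02
        )

    def test_saddle_start_breaks_toward_lower_effort(self):
        g = np.arange(-1.0, 1.0001, 0.01)
        vals = np.exp(-((g - 0.3) ** 2) / 0.02) + 2 * np.exp(-((g + 0.7) ** 2) / 0.02)
        sweep = ThroughFocusSweep(g, vals, "vsr")
        # the valley between the peaks lies near −0.2; start exactly there
        valley = g[
            int(np.argmin(np.where((g > -0.7) & (g < 0.3), vals, np.inf)))
        ]
        res = predict_local(sweep, float(valley))
        assert res.predicted_defocus_D[0] == pytest.approx(0.3, abs=0.05)

    def test_start_outside_grid_rejected(self):
        g = np.arange(0.0, 0.1, 0.01)
        sweep = ThroughFocusSweep(g, np.linspace(1, 2, g.size), "vsr")
        with pytest.raises(ValueError, match="outside"):
            predict_local(sweep, 5.0)


class TestEquateLM:
    def test_mixture_crossing_near_demand_midpoint(self, curves, lib5):
        mid = 0.5 * (_demand(660.0) + _demand(461.0))
        res = predict_equate_lm(
            EYE5, _mixture("red", "blue", 5.0, curves), curves, "vsr", library=lib5
        )
        assert not res.ambiguous
        assert res.predicted_defocus_D[0] == pytest.approx(mid, abs=0.1)

    def test_single_led_is_ambiguous(self, curves, lib5):
        res = predict_equate_lm(EYE5, _led("red", curves), curves, "vsr", library=lib5)
        assert res.ambiguous

    def test_constant_channel_offset_gives_no_crossing(self):
        """Synthetic L ≡ M + large offset: empty, flagged result."""
        g = DEFAULT_SWEEP_GRID
        base = np.exp(-(g**2))
        res = PredictionResult("equate_lm", (), True)
        d = (base + 0.5) - base  # constant 0.5 > any tolerance, no sign change
        assert not np.any(np.diff(np.sign(d)) != 0)
        assert res.ambiguous and res.predicted_defocus_D == ()

    def test_multiple_predictions_require_flag(self):
        with pytest.raises(ValueError, match="ambiguity"):
            PredictionResult("equate_lm", (0.1, 0.2), False)


class TestResponseCurves:
    def test_vsr_curve_steps_at_equal_luminance(self, curves, lib5):
        curve = mixture_response_curve(
            EYE5, ("red", "blue"), curves, "global", "vsr", 9, library=lib5
        )
        separation = abs(_demand(660.0) - _demand(461.0))
        assert curve.max_jump_D > 0.8 * separation
        assert abs(curve.jump_at_lum_long - 5.0) <= 0.625

    def test_contrast2_curve_near_linear_for_red_green(self, curves, lib5):
        curve = mixture_response_curve(
            EYE5, ("red", "green"), curves, "global", "contrast@2", 9, library=lib5
        )
        assert curve.linearity_r2 > 0.95

    def test_equate_lm_curve_flat_near_midpoint(self, curves, lib5):
        curve = mixture_response_curve(
            EYE5, ("red", "blue"), curves, "equate_lm", "vsr", 7, library=lib5
        )
        mid = 0.5 * (_demand(660.0) + _demand(461.0))
        preds = np.asarray(curve.predicted_D)
        assert np.all(np.isfinite(preds))
        assert np.max(np.abs(preds - mid)) < 0.15

    def test_vsr_step_exceeds_contrast2_smoothness_across_pairs(self, curves, lib5):
        """Step-vs-smooth dichotomy: VSR jumps exceed 2-cpd jumps per pair."""
        for pair in (("red", "blue"), ("red", "green"), ("orange", "violet")):
            c_vsr = mixture_response_curve(
                EYE5, pair, curves, "global", "vsr", 9, library=lib5
            )
            c_2 = mixture_response_curve(
                EYE5, pair, curves, "global", "contrast@2", 9, library=lib5
            )
            assert c_vsr.max_jump_D > c_2.max_jump_D

    def test_monochromatic_rules_agree_on_primary_demand(self, curves, lib5):
        """Unique-prediction rules land on the demand for a single LED."""
        d = _demand(527.0)
        green = _led("green", curves)
        for metric in ("vsr", "strehl", "contrast@8"):
            sweep = sweep_from_library(lib5, green, curves, metric)
            assert predict_global(sweep).single() == pytest.approx(d, abs=0.05)

    def test_unknown_pair_rejected(self, curves, lib5):
        with pytest.raises(ValueError, match="pairs"):
            mixture_response_curve(
                EYE5, ("blue", "red"), curves, "global", "vsr", 9, library=lib5
            )
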