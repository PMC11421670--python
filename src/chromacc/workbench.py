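"""Reproducible experiment drivers tying the modules together.

High-level runs behind the analysis scripts and the CLI: figure-style
through-focus sweep bundles, prediction curves for all six LED pairs, the
D65 daylight comparison (luminance-channel optimum vs EquateLM crossing),
and full synthetic end-to-end sessions.  Every run can echo its full
configuration to JSON for reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import NeuralWeighting
from .optics import (
    EyeModel,
    GridConfig,
    MonoOTFLibrary,
    build_otf_library,
    chromatic_defocus,
)
from .rules import (
    DEFAULT_SWEEP_GRID,
    mixture_response_curve,
    predict_equate_lm,
    predict_global,
    sweep_from_library,
)
from .spectra import (
    LED_PAIRS,
    LED_PRIMARIES,
    ReferenceCurves,
    figure_splits,
    gaussian_led_spectrum,
    mix_spectra,
    scale_to_luminance,
)

__all__ = [
    "RunConfig",
    "demand_table",
    "reproduce_sweep_figures",
    "reproduce_prediction_curves",
    "d65_comparison",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one reproduction run.

    The experiment reproductions use a 5-mm pupil; the daylight comparison a
    6-mm pupil.  The polychromatic summation runs over 400–700 nm in 5-nm
    steps; the default through-focus grid is −1.5…+1.5 D at 0.01 D.
    """

    pupil_mm: float = 5.0
    grid_n: int = 256
    defocus_min_D: float = -1.5
    defocus_max_D: float = 1.5
    defocus_step_D: float = 0.01
    n_splits: int = 9
    metrics: tuple[str, ...] = ("vsr", "contrast@2", "contrast@4", "contrast@8", "contrast@16")
    seed: int = 0

    @property
    def defocus_grid(self) -> np.ndarray:
        return np.arange(
            self.defocus_min_D, self.defocus_max_D + 1e-9, self.defocus_step_D
        )

    def eye(self) -> EyeModel:
        return EyeModel(pupil_diameter_mm=self.pupil_mm)

    def grid(self) -> GridConfig:
        return GridConfig(n=self.grid_n)

    def echo(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(
            json.dumps(dataclasses.asdict(self), indent=2), encoding="utf-8"
        )


def _library(cfg: RunConfig, lib: MonoOTFLibrary | None = None) -> MonoOTFLibrary:
    if lib is not None:
        return lib
    return build_otf_library(cfg.eye(), cfg.grid(), cfg.defocus_grid)


def demand_table() -> pd.DataFrame:
    """Primary demands of the five LEDs on the defocus-relative-to-580 axis."""
    rows = []
    for name, led in LED_PRIMARIES.items():
        d = chromatic_defocus(led.peak_nm * 1e-3)
        rows.append(
            {
                "led": name,
                "peak_nm": led.peak_nm,
                "demand_D": d,
                "demand_rel_orange_D": d - chromatic_defocus(0.588),
            }
        )
    return pd.DataFrame(rows)


def _pair_mixture(pair, lum_long, curves):
    led_a = gaussian_led_spectrum(LED_PRIMARIES[pair[0]])
    led_b = gaussian_led_spectrum(LED_PRIMARIES[pair[1]])
    total = 10.0
    if lum_long >= total:
        return scale_to_luminance(led_a, total, curves)
    if lum_long <= 0:
        return scale_to_luminance(led_b, total, curves)
    return mix_spectra(led_a, led_b, lum_long, total - lum_long, curves)


def reproduce_sweep_figures(
    cfg: RunConfig,
    curves: ReferenceCurves | None = None,
    pair: tuple[str, str] = ("red", "blue"),
    library: MonoOTFLibrary | None = None,
) -> pd.DataFrame:
    """Through-focus tables per mixture: luminance-channel metrics plus
    L/M-channel visual Strehl (the Figs 9/12/15-style bundles)."""
    curves = curves or ReferenceCurves()
    lib = _library(cfg, library)
    rows = []
    for lum_long, _ in figure_splits(cfg.n_splits):
        spec = _pair_mixture(pair, lum_long, curves)
        for metric in cfg.metrics:
            sweep = sweep_from_library(lib, spec, curves, metric)
            rows.append(
                pd.DataFrame(
                    {
                        "pair": "-".join(pair),
                        "lum_long": lum_long,
                        "metric": metric,
                        "channel": "luminance",
                        "defocus_D": sweep.defocus_grid_D,
                        "value": sweep.values,
                    }
                )
            )
        for ch in ("L", "M"):
            sweep = sweep_from_library(lib, spec, curves, "vsr", channel=ch)
            rows.append(
                pd.DataFrame(
                    {
                        "pair": "-".join(pair),
                        "lum_long": lum_long,
                        "metric": "vsr",
                        "channel": ch,
                        "defocus_D": sweep.defocus_grid_D,
                        "value": sweep.values,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def reproduce_prediction_curves(
    cfg: RunConfig,
    curves: ReferenceCurves | None = None,
    rules: tuple[str, ...] = ("global:vsr", "global:contrast@2", "global:contrast@4",
                              "global:contrast@8", "global:contrast@16", "equate_lm:vsr"),
    library: MonoOTFLibrary | None = None,
) -> pd.DataFrame:
    """Six-pair prediction curves per rule with shape summaries
    (the Figs 10/13/16-style bundles)."""
    curves = curves or ReferenceCurves()
    lib = _library(cfg, library)
    eye = cfg.eye()
    rows = []
    for rule_spec in rules:
        rule, metric = rule_spec.split(":")
        for pair in LED_PAIRS:
            curve = mixture_response_curve(
                eye,
                pair,
                curves,
                rule=rule,
                metric=metric,
                n_splits=cfg.n_splits,
                grid_D=cfg.defocus_grid,
                library=lib,
            )
            for lum, pred, amb in zip(curve.lum_long, curve.predicted_D, curve.ambiguous):
                rows.append(
                    {
                        "rule": rule_spec,
                        "pair": "-".join(pair),
                        "lum_long": lum,
                        "predicted_D": pred,
                        "ambiguous": amb,
                        "max_jump_D": curve.max_jump_D,
                        "jump_at_lum_long": curve.jump_at_lum_long,
                        "linearity_r2": curve.linearity_r2,
                    }
                )
    return pd.DataFrame(rows)


def d65_comparison(
    cfg: RunConfig | None = None,
    curves: ReferenceCurves | None = None,
    library: MonoOTFLibrary | None = None,
    lca_q: tuple[float, float, float] | None = None,
) -> dict:
    """Daylight check of the EquateLM rule against luminance-VSR optimization.

    Runs a D65 through-focus sweep with a 6-mm pupil: returns the
    luminance-channel VSR optimum, the defocus where L- and M-cone VSR are
    equal, and the underlying sweeps.  Both land near −0.1 D (in-focus
    wavelength ≈ 560 nm) for the natural-LCA eye.
    """
    cfg = cfg or RunConfig(pupil_mm=6.0)
    curves = curves or ReferenceCurves()
    if library is None:
        eye = EyeModel(pupil_diameter_mm=cfg.pupil_mm, lca_q=lca_q or EyeModel().lca_q)
        library = build_otf_library(eye, cfg.grid(), cfg.defocus_grid)
    eye = library.eye
    d65 = curves.d65
    sweep_v = sweep_from_library(library, d65, curves, "vsr", "luminance")
    opt = predict_global(sweep_v).single()
    res = predict_equate_lm(eye, d65, curves, "vsr", library=library)
    crossing = res.single() if res.predicted_defocus_D else float("nan")
    sweep_L = sweep_from_library(library, d65, curves, "vsr", "L")
    sweep_M = sweep_from_library(library, d65, curves, "vsr", "M")
    sweep_S = sweep_from_library(library, d65, curves, "vsr", "S")
    return {
        "vsr_optimum_D": float(opt),
        "equate_lm_crossing_D": float(crossing),
        "crossing_ambiguous": res.ambiguous,
        "sweeps": {
            "luminance": sweep_v,
            "L": sweep_L,
            "M": sweep_M,
            "S": sweep_S,
        },
    }
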