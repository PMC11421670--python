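"""Accommodation-prediction rules over through-focus image-quality sweeps.

Three families of hypotheses about what the accommodation system optimizes:

* global / local maximization of an image-quality metric (visual Strehl,
  MTF-area Strehl, light-in-the-bucket, R50) in the luminance channel;
* maximization of contrast at a single spatial frequency ("contrast@f");
* the EquateLM rule — accommodate where L-cone and M-cone image quality are
  equal, exploiting the sign information in chromatic aberration.

All sweeps run on the baseline-defocus axis (diopters relative to 580 nm;
wavelength λ in focus at D(λ)).  For metrics where smaller is better (R50)
the optimizers minimize.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .metrics import (
    DL_MTF_FLOOR,
    NeuralWeighting,
    lib as lib_metric,
    r50 as r50_metric,
)
from .optics import (
    EyeModel,
    GridConfig,
    MonoOTFLibrary,
    RadialMTF,
    build_otf_library,
    poly_psf,
    spectral_weights,
)
from .spectra import LED_PAIRS, ReferenceCurves, Spectrum, figure_splits

__all__ = [
    "DEFAULT_SWEEP_GRID",
    "ThroughFocusSweep",
    "PredictionResult",
    "ResponseCurve",
    "parse_metric",
    "through_focus_sweep",
    "sweep_from_library",
    "predict_global",
    "predict_local",
    "predict_equate_lm",
    "mixture_response_curve",
]

#: default through-focus grid: −1.5 … +1.5 D in 0.01 D steps
DEFAULT_SWEEP_GRID = np.arange(-1.5, 1.5 + 1e-9, 0.01)

#: peaks within this relative tolerance of the best value count as ties
TIE_REL_TOL = 0.005

#: channels are indistinguishable when max |L − M| falls below this fraction
#: of the larger channel's maximum
EQUATE_LM_DEGENERACY_TOL = 0.01

#: crossings where both channels sit below this fraction of their maxima are
#: numerical noise between near-zero curves, not a usable cue
EQUATE_LM_FLOOR_FRACTION = 0.02

_MINIMIZING_METRICS = {"r50"}


def parse_metric(metric: str) -> tuple[str, float | None]:
    """Split a metric spec into (name, frequency): 'contrast@4' → ('contrast', 4.0)."""
    m = re.fullmatch(r"contrast@([0-9.]+)(?:cpd)?", metric)
    if m:
        return "contrast", float(m.group(1))
    if metric in ("vsr", "strehl", "lib", "r50"):
        return metric, None
    raise ValueError(f"unknown metric spec {metric!r}")


@dataclass(frozen=True)
class ThroughFocusSweep:
    """Metric values over a uniform baseline-defocus grid."""

    defocus_grid_D: np.ndarray
    values: np.ndarray
    metric: str
    channel: str = "luminance"
    label: str = ""

    def __post_init__(self) -> None:
        g = np.asarray(self.defocus_grid_D, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if g.ndim != 1 or g.shape != v.shape or g.size < 3:
            raise ValueError("grid and values must be matching 1-D arrays")
        d = np.diff(g)
        if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6):
            raise ValueError("defocus grid must be strictly increasing and uniform")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("sweep values must be finite and non-negative")
        g.flags.writeable = False
        v.flags.writeable = False
        object.__setattr__(self, "defocus_grid_D", g)
        object.__setattr__(self, "values", v)

    @property
    def minimizing(self) -> bool:
        return parse_metric(self.metric)[0] in _MINIMIZING_METRICS


@dataclass(frozen=True)
class PredictionResult:
    """One rule's predicted accommodation (baseline-defocus axis)."""

    rule: str
    predicted_defocus_D: tuple[float, ...]
    ambiguous: bool
    metric: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        if len(self.predicted_defocus_D) > 1 and not self.ambiguous:
            raise ValueError("multiple predictions require the ambiguity flag")

    def single(self) -> float:
        """Force one value: the prediction with the lowest accommodative
        effort (|defocus| closest to 0) when ambiguous."""
        if not self.predicted_defocus_D:
            raise ValueError("no prediction available")
        return min(self.predicted_defocus_D, key=abs)


@dataclass(frozen=True)
class ResponseCurve:
    """Predicted accommodation per luminance split for one LED pair."""

    pair: tuple[str, str]
    lum_long: tuple[float, ...]
    predicted_D: tuple[float, ...]
    ambiguous: tuple[bool, ...]
    rule: str
    max_jump_D: float = field(default=0.0)
    jump_at_lum_long: float = field(default=float("nan"))
    linearity_r2: float = field(default=float("nan"))


# ---------------------------------------------------------------------------
# Sweeps


def _metric_values_from_mtfs(
    mtf: np.ndarray,
    dl: np.ndarray,
    freq: np.ndarray,
    metric: str,
    weighting: NeuralWeighting,
) -> np.ndarray:
    """Vectorized metric evaluation over (n_baseline, n_freq) MTF stacks."""
    name, f0 = parse_metric(metric)
    if name == "vsr":
        ncsf = np.where(dl >= DL_MTF_FLOOR, weighting.csf(freq) / np.maximum(dl, DL_MTF_FLOOR), 0.0)
        den = np.trapezoid(ncsf * dl * freq, freq)
        return np.trapezoid(ncsf * mtf * freq, freq, axis=1) / den
    if name == "strehl":
        den = np.trapezoid(dl * freq, freq)
        return np.trapezoid(mtf * freq, freq, axis=1) / den
    if name == "contrast":
        if not (freq[0] <= f0 <= freq[-1]):
            raise ValueError(f"frequency {f0} cpd beyond the MTF grid")
        i = int(np.searchsorted(freq, f0))
        if i == 0:
            return mtf[:, 0].copy()
        t = (f0 - freq[i - 1]) / (freq[i] - freq[i - 1])
        return (1 - t) * mtf[:, i - 1] + t * mtf[:, i]
    raise ValueError(f"metric {metric!r} is not MTF-based; use the PSF path")


def sweep_from_library(
    lib: MonoOTFLibrary,
    spectrum: Spectrum,
    curves: ReferenceCurves,
    metric: str,
    channel: str = "luminance",
    weighting: NeuralWeighting | None = None,
) -> ThroughFocusSweep:
    """Through-focus sweep of an MTF-based metric using a radial OTF library."""
    w = spectral_weights(spectrum, curves, channel, lib.wavelengths_nm)
    mtf = lib.poly_mtf(w)
    dl = lib.poly_dl_mtf(w)
    vals = _metric_values_from_mtfs(mtf, dl, lib.freq_cpd, metric, weighting or NeuralWeighting())
    return ThroughFocusSweep(
        lib.baseline_D.copy(), vals, metric, channel, spectrum.label
    )


def through_focus_sweep(
    eye: EyeModel,
    spectrum: Spectrum,
    curves: ReferenceCurves,
    metric: str,
    channel: str = "luminance",
    grid_D: np.ndarray = DEFAULT_SWEEP_GRID,
    grid: GridConfig | None = None,
    library: MonoOTFLibrary | None = None,
    weighting: NeuralWeighting | None = None,
) -> ThroughFocusSweep:
    """Evaluate a metric at every baseline defocus on the grid.

    MTF-based metrics (vsr, strehl, contrast@f) run through a radial OTF
    library (built on demand when not supplied).  PSF-domain metrics (lib,
    r50) compute a polychromatic PSF per grid point — substantially slower,
    so coarse grids are advisable there.
    """
    name, _ = parse_metric(metric)
    grid = grid or GridConfig(n=256)
    if name in ("vsr", "strehl", "contrast"):
        if library is None:
            library = build_otf_library(eye, grid, np.asarray(grid_D, dtype=float))
        return sweep_from_library(library, spectrum, curves, metric, channel, weighting)

    from .metrics import dl_core_radius_arcmin  # PSF path

    vals = np.empty(len(grid_D))
    dl_ref = poly_psf(eye, spectrum, curves, 0.0, channel, grid, dl_reference=True)
    for i, b in enumerate(np.asarray(grid_D, dtype=float)):
        psf = poly_psf(eye, spectrum, curves, b, channel, grid)
        vals[i] = lib_metric(psf, dl_ref) if name == "lib" else r50_metric(psf)
    return ThroughFocusSweep(np.asarray(grid_D, float), vals, metric, channel, spectrum.label)


# ---------------------------------------------------------------------------
# Prediction rules


def _parabolic_refine(grid: np.ndarray, vals: np.ndarray, i: int) -> float:
    if i == 0 or i == vals.size - 1:
        return float(grid[i])
    denom = vals[i - 1] - 2 * vals[i] + vals[i + 1]
    if denom == 0:
        return float(grid[i])
    off = 0.5 * (vals[i - 1] - vals[i + 1]) / denom
    off = float(np.clip(off, -0.5, 0.5))
    return float(grid[i] + off * (grid[1] - grid[0]))


def _local_optima(vals: np.ndarray) -> list[int]:
    """Indices of local maxima, plateau- and endpoint-aware."""
    idx = []
    n = vals.size
    i = 0
    while i < n:
        j = i
        while j + 1 < n and vals[j + 1] == vals[i]:
            j += 1
        left_ok = i == 0 or vals[i - 1] < vals[i]
        right_ok = j == n - 1 or vals[j + 1] < vals[j]
        if left_ok and right_ok:
            idx.append((i + j) // 2)
        i = j + 1
    return idx


def predict_global(
    sweep: ThroughFocusSweep, tie_rel_tol: float = TIE_REL_TOL, rule: str = "global"
) -> PredictionResult:
    """Argmax (argmin for R50) with parabolic refinement and tie detection.

    Local optima within ``tie_rel_tol`` of the best value are reported
    together with the ambiguity flag set: FFT-level numeric noise must not
    silently pick a side between near-equal peaks.
    """
    vals = -sweep.values if sweep.minimizing else sweep.values
    if np.allclose(vals, vals[0], rtol=1e-12, atol=1e-15):
        return PredictionResult(
            rule, tuple(), True, sweep.metric, sweep.channel
        )
    peaks = _local_optima(vals)
    best = max(vals[i] for i in peaks)
    span = best - vals.min()
    keep = [i for i in peaks if best - vals[i] <= tie_rel_tol * abs(span)]
    preds = tuple(
        sorted(_parabolic_refine(sweep.defocus_grid_D, vals, i) for i in keep)
    )
    return PredictionResult(rule, preds, len(preds) > 1, sweep.metric, sweep.channel)


def predict_local(sweep: ThroughFocusSweep, start_defocus_D: float) -> PredictionResult:
    """Hill-climb from a starting point to the nearest local optimum.

    Models an accommodation system following the local image-quality
    gradient (e.g. via microfluctuations) and getting stuck there.  When the
    start sits exactly on a local minimum between two peaks, the tie is
    broken toward lower |defocus|.
    """
    g = sweep.defocus_grid_D
    if not (g[0] <= start_defocus_D <= g[-1]):
        raise ValueError("start defocus lies outside the sweep grid")
    vals = -sweep.values if sweep.minimizing else sweep.values
    i = int(np.argmin(np.abs(g - start_defocus_D)))
    while True:
        left = vals[i - 1] if i > 0 else -np.inf
        right = vals[i + 1] if i < vals.size - 1 else -np.inf
        if left <= vals[i] and right <= vals[i]:
            break
        if left > vals[i] and right > vals[i]:
            # exact saddle: prefer the lower-effort direction
            i = i - 1 if abs(g[i - 1]) <= abs(g[i + 1]) else i + 1
        elif right > vals[i]:
            i += 1
        else:
            i -= 1
    return PredictionResult(
        "local",
        (_parabolic_refine(g, vals, i),),
        False,
        sweep.metric,
        sweep.channel,
    )


def predict_equate_lm(
    eye: EyeModel,
    spectrum: Spectrum,
    curves: ReferenceCurves,
    metric: str = "vsr",
    grid_D: np.ndarray = DEFAULT_SWEEP_GRID,
    library: MonoOTFLibrary | None = None,
    grid: GridConfig | None = None,
    weighting: NeuralWeighting | None = None,
) -> PredictionResult:
    """Defocus where L-cone and M-cone image quality cross over.

    All sign changes of (L − M) are returned, linearly interpolated between
    grid samples; multiple crossings mean the cue is ambiguous.  When the
    two channels are indistinguishable over the whole sweep (narrowband
    spectra) the result is fully ambiguous with no usable crossing.
    Crossings where both channels sit below a small fraction of their peak
    values are discarded as numerical noise between near-zero curves.
    """
    kw = dict(grid_D=grid_D, library=library, grid=grid, weighting=weighting)
    sweep_L = through_focus_sweep(eye, spectrum, curves, metric, "L", **kw)
    sweep_M = through_focus_sweep(eye, spectrum, curves, metric, "M", **kw)
    L, M = sweep_L.values, sweep_M.values
    g = sweep_L.defocus_grid_D
    scale = max(L.max(), M.max())
    if scale <= 0 or np.max(np.abs(L - M)) < EQUATE_LM_DEGENERACY_TOL * scale:
        return PredictionResult("equate_lm", tuple(), True, metric, "L-M")
    d = L - M
    crossings = []
    floor = EQUATE_LM_FLOOR_FRACTION * scale
    for k in np.where(np.diff(np.sign(d)) != 0)[0]:
        if max(L[k], M[k]) < floor and max(L[k + 1], M[k + 1]) < floor:
            continue
        x = g[k] + (g[k + 1] - g[k]) * d[k] / (d[k] - d[k + 1])
        crossings.append(float(x))
    return PredictionResult(
        "equate_lm", tuple(sorted(crossings)), len(crossings) != 1, metric, "L-M"
    )


# ---------------------------------------------------------------------------
# Response curves across mixture ratios


def _rule_prediction(
    eye,
    spectrum,
    curves,
    rule: str,
    metric: str,
    grid_D,
    library,
    grid,
    weighting,
) -> PredictionResult:
    if rule == "equate_lm":
        return predict_equate_lm(
            eye, spectrum, curves, metric, grid_D, library, grid, weighting
        )
    sweep = through_focus_sweep(
        eye,
        spectrum,
        curves,
        metric,
        "luminance",
        grid_D,
        grid,
        library,
        weighting,
    )
    if rule == "global":
        return predict_global(sweep)
    raise ValueError(f"unknown rule {rule!r}")


def mixture_response_curve(
    eye: EyeModel,
    pair: tuple[str, str],
    curves: ReferenceCurves,
    rule: str = "global",
    metric: str = "vsr",
    n_splits: int = 9,
    grid_D: np.ndarray = DEFAULT_SWEEP_GRID,
    library: MonoOTFLibrary | None = None,
    grid: GridConfig | None = None,
    weighting: NeuralWeighting | None = None,
) -> ResponseCurve:
    """Prediction per luminance split for one LED pair, plus shape summary.

    ``n_splits=9`` reproduces the figure-style nine equal steps from
    completely long-wavelength to completely short; ``n_splits=7`` matches
    the experiment's mixture design (no pure-LED endpoints).  Ambiguous
    predictions are recorded per split and forced to a single value (lowest
    accommodative effort) for the curve itself.
    """
    if pair not in LED_PAIRS:
        raise ValueError(f"{pair!r} is not one of the experiment's LED pairs")
    from .spectra import (
        LED_PRIMARIES,
        TOTAL_LUMINANCE_CDM2,
        experiment_splits,
        gaussian_led_spectrum,
        mix_spectra,
        scale_to_luminance,
    )

    splits = figure_splits(n_splits) if n_splits != 7 else experiment_splits()
    led_a = gaussian_led_spectrum(LED_PRIMARIES[pair[0]])
    led_b = gaussian_led_spectrum(LED_PRIMARIES[pair[1]])

    lums, preds, ambig = [], [], []
    for lum_long, lum_short in splits:
        if lum_short == 0:
            spec = scale_to_luminance(led_a, TOTAL_LUMINANCE_CDM2, curves)
        elif lum_long == 0:
            spec = scale_to_luminance(led_b, TOTAL_LUMINANCE_CDM2, curves)
        else:
            spec = mix_spectra(led_a, led_b, lum_long, lum_short, curves)
        spec = Spectrum(
            spec.wavelengths_nm, spec.values, f"{pair[0]}-{pair[1]}_{lum_long:.2f}"
        )
        res = _rule_prediction(
            eye, spec, curves, rule, metric, grid_D, library, grid, weighting
        )
        lums.append(lum_long)
        if res.predicted_defocus_D:
            preds.append(res.single())
            ambig.append(res.ambiguous)
        else:
            preds.append(float("nan"))
            ambig.append(True)
    preds_arr = np.asarray(preds)
    lums_arr = np.asarray(lums)
    ok = np.isfinite(preds_arr)
    jumps = np.abs(np.diff(preds_arr[ok]))
    if jumps.size:
        j = int(np.argmax(jumps))
        max_jump = float(jumps[j])
        jump_at = float(0.5 * (lums_arr[ok][j] + lums_arr[ok][j + 1]))
    else:
        max_jump, jump_at = 0.0, float("nan")
    if ok.sum() >= 3 and np.ptp(preds_arr[ok]) > 0:
        r = np.corrcoef(lums_arr[ok], preds_arr[ok])[0, 1]
        r2 = float(r * r)
    else:
        r2 = float("nan")
    return ResponseCurve(
        pair=pair,
        lum_long=tuple(lums),
        predicted_D=tuple(preds),
        ambiguous=tuple(ambig),
        rule=f"{rule}:{metric}",
        max_jump_D=max_jump,
        jump_at_lum_long=jump_at,
        linearity_r2=r2,
    )
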