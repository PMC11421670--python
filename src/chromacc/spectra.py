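"""Illuminant spectra, CIE reference curves and the two-primary stimulus set.

The experiment illuminates a fixation target with pairs of narrowband LEDs
(red 660, orange 588, green 527, blue 461, violet 441 nm) mixed at a fixed
total luminance of 10 cd/m² in 1.25 cd/m² steps.  This module represents
sampled spectra, embeds the CIE reference curves used to weight them
photometrically, and builds the full 47-spectrum stimulus set (42 mixtures
plus the five single LEDs).

Photometry is relative throughout: "cd/m²" labels are carried on the numbers
but only luminance ratios are meaningful, so the maximal-luminous-efficacy
constant is absorbed into the unit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "LEDPrimary",
    "MixtureDesign",
    "ReferenceCurves",
    "StimulusEntry",
    "LED_PRIMARIES",
    "LED_PAIRS",
    "DEFAULT_GRID_NM",
    "gaussian_led_spectrum",
    "relative_luminance",
    "scale_to_luminance",
    "mix_spectra",
    "generate_experiment_set",
    "experiment_splits",
    "figure_splits",
    "stimulus_set_to_frame",
]

#: default fine wavelength grid for spectra, nm
DEFAULT_GRID_NM = np.arange(380.0, 781.0, 1.0)

#: total stimulus luminance of the experiment, cd/m² (relative photometry)
TOTAL_LUMINANCE_CDM2 = 10.0

#: luminance step of the mixture design, cd/m²
LUMINANCE_STEP_CDM2 = 1.25


@dataclass(frozen=True)
class Spectrum:
    """A relative radiance distribution sampled on a uniform wavelength grid."""

    wavelengths_nm: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or v.ndim != 1 or wl.size != v.size or wl.size < 2:
            raise ValueError("wavelengths and values must be 1-D of equal length >= 2")
        if wl[0] < 380.0 - 1e-9 or wl[-1] > 780.0 + 1e-9:
            raise ValueError("wavelength grid must lie within [380, 780] nm")
        d = np.diff(wl)
        if np.any(d <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
            raise ValueError("wavelength grid must be uniformly spaced")
        if np.any(v < 0):
            raise ValueError("spectral values must be non-negative")
        if not np.any(v > 0):
            raise ValueError("spectrum must contain at least one positive value")
        wl.flags.writeable = False
        v.flags.writeable = False
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", v)

    @property
    def step_nm(self) -> float:
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])

    def resample(self, grid_nm: np.ndarray, label: str | None = None) -> "Spectrum":
        """Linear interpolation onto a new uniform grid; zero outside support."""
        grid = np.asarray(grid_nm, dtype=float)
        vals = np.interp(grid, self.wavelengths_nm, self.values, left=0.0, right=0.0)
        if not np.any(vals > 0):
            raise ValueError("resampled spectrum has no overlap with the new grid")
        return Spectrum(grid, vals, self.label if label is None else label)

    def scaled(self, factor: float, label: str | None = None) -> "Spectrum":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return _scaled_allow_zero(self, factor, label)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["wavelength_nm", "value"])
            for wl, v in zip(self.wavelengths_nm, self.values):
                w.writerow([f"{wl:g}", f"{v:.10g}"])

    @classmethod
    def from_csv(cls, path, label: str = "") -> "Spectrum":
        wl, vals = [], []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "wavelength_nm" not in reader.fieldnames:
                raise ValueError("spectrum CSV requires a 'wavelength_nm,value' header")
            for row in reader:
                wl.append(float(row["wavelength_nm"]))
                vals.append(float(row["value"]))
        return cls(np.array(wl), np.array(vals), label)


def _scaled_allow_zero(spec: Spectrum, factor: float, label: str | None) -> Spectrum:
    # Spectrum requires one positive value; an all-zero spectrum (target
    # luminance 0) is still a legitimate product of scaling, so bypass that
    # single check here.
    out = object.__new__(Spectrum)
    object.__setattr__(out, "wavelengths_nm", spec.wavelengths_nm)
    vals = np.asarray(spec.values) * float(factor)
    vals.flags.writeable = False
    object.__setattr__(out, "values", vals)
    object.__setattr__(out, "label", spec.label if label is None else label)
    return out


@dataclass(frozen=True)
class LEDPrimary:
    """A narrowband LED described by its peak wavelength and bandwidth."""

    name: str
    peak_nm: float
    fwhm_nm: float = 25.0

    def __post_init__(self) -> None:
        if not (10.0 <= self.fwhm_nm <= 80.0):
            raise ValueError("LED FWHM must lie within [10, 80] nm")


#: the five experiment primaries; peak wavelengths from the apparatus,
#: Gaussian bandwidth defaulting to 25 nm (measured curves span ~20-50 nm FWHM)
LED_PRIMARIES: dict[str, LEDPrimary] = {
    "red": LEDPrimary("red", 660.0),
    "orange": LEDPrimary("orange", 588.0),
    "green": LEDPrimary("green", 527.0),
    "blue": LEDPrimary("blue", 461.0),
    "violet": LEDPrimary("violet", 441.0),
}

#: the six LED pairs of the experiment, long-wavelength member first
LED_PAIRS: tuple[tuple[str, str], ...] = (
    ("red", "green"),
    ("red", "blue"),
    ("red", "violet"),
    ("orange", "blue"),
    ("orange", "violet"),
    ("green", "violet"),
)


@dataclass(frozen=True)
class MixtureDesign:
    """Two primaries and their target luminances at fixed total luminance."""

    pair: tuple[str, str]
    luminances_cdm2: tuple[float, float]
    total_cdm2: float = TOTAL_LUMINANCE_CDM2

    def __post_init__(self) -> None:
        for name in self.pair:
            if name not in LED_PRIMARIES:
                raise ValueError(f"unknown LED primary {name!r}")
        la, lb = self.luminances_cdm2
        if la < 0 or lb < 0:
            raise ValueError("luminances must be non-negative")
        if abs((la + lb) - self.total_cdm2) > 1e-9 * max(self.total_cdm2, 1.0):
            raise ValueError("mixture luminances must sum to the total luminance")


class ReferenceCurves:
    """Embedded CIE reference curves, peak-normalized.

    ``vlambda`` is the CIE 1924/1931 2° photopic luminous efficiency function
    (the ȳ colour-matching function).  Cone sensitivities are obtained from
    the embedded 1931 colour-matching functions through the Smith–Pokorny /
    Boynton transform, so that L + M reproduces V(λ) exactly; S follows z̄.
    ``d65`` is the CIE standard daylight illuminant.  All curves are stored
    on the tabulated 10-nm grid and sampled by linear interpolation.
    """

    def __init__(self) -> None:
        cmf = _load_table("cie_1931_2deg_cmf_10nm.csv", ("wavelength_nm", "xbar", "ybar", "zbar"))
        wl = cmf[:, 0]
        xbar, ybar, zbar = cmf[:, 1], cmf[:, 2], cmf[:, 3]
        lcone = 0.15514 * xbar + 0.54312 * ybar - 0.03286 * zbar
        mcone = -0.15514 * xbar + 0.45684 * ybar + 0.03286 * zbar
        scone = zbar.copy()
        # the transform leaves tiny negative lobes at the spectral extremes
        lcone = np.clip(lcone, 0.0, None)
        mcone = np.clip(mcone, 0.0, None)
        d65 = _load_table("cie_d65_10nm.csv", ("wavelength_nm", "value"))
        self._wl = wl
        self._curves = {
            "vlambda": ybar / ybar.max(),
            "cone_L": lcone / lcone.max(),
            "cone_M": mcone / mcone.max(),
            "cone_S": scone / scone.max(),
        }
        self._d65_wl = d65[:, 0]
        self._d65 = d65[:, 1] / d65[:, 1].max()
        for arr in (self._wl, self._d65_wl, self._d65, *self._curves.values()):
            arr.flags.writeable = False

    def sample(self, name: str, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Sample a named curve (vlambda / cone_L / cone_M / cone_S) at given λ."""
        wl = np.asarray(wavelengths_nm, dtype=float)
        if name == "d65":
            return np.interp(wl, self._d65_wl, self._d65, left=0.0, right=0.0)
        if name not in self._curves:
            raise KeyError(f"unknown reference curve {name!r}")
        return np.interp(wl, self._wl, self._curves[name], left=0.0, right=0.0)

    @property
    def vlambda(self) -> Spectrum:
        return Spectrum(self._wl, self._curves["vlambda"], "vlambda")

    @property
    def cone_L(self) -> Spectrum:
        return Spectrum(self._wl, self._curves["cone_L"], "cone_L")

    @property
    def cone_M(self) -> Spectrum:
        return Spectrum(self._wl, self._curves["cone_M"], "cone_M")

    @property
    def cone_S(self) -> Spectrum:
        return Spectrum(self._wl, self._curves["cone_S"], "cone_S")

    @property
    def d65(self) -> Spectrum:
        return Spectrum(self._d65_wl, self._d65, "d65")


def _load_table(name: str, columns: Sequence[str]) -> np.ndarray:
    src = resources.files("chromacc.data").joinpath(name)
    with src.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        rows = [[float(row[c]) for c in columns] for row in reader]
    return np.asarray(rows, dtype=float)


def gaussian_led_spectrum(
    primary: LEDPrimary, grid_nm: np.ndarray = DEFAULT_GRID_NM
) -> Spectrum:
    """Analytic Gaussian stand-in for a measured LED radiance curve.

    Peak value 1 at ``primary.peak_nm`` with the stated full width at half
    maximum.  The measured curves are published only graphically, so a
    Gaussian profile is used as a documented approximation.
    """
    grid = np.asarray(grid_nm, dtype=float)
    if not (grid[0] <= primary.peak_nm <= grid[-1]):
        raise ValueError(
            f"LED peak {primary.peak_nm} nm lies outside the grid "
            f"[{grid[0]}, {grid[-1]}] nm"
        )
    sigma = primary.fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    vals = np.exp(-0.5 * ((grid - primary.peak_nm) / sigma) ** 2)
    return Spectrum(grid, vals, primary.name)


def relative_luminance(spectrum: Spectrum, curves: ReferenceCurves) -> float:
    """Grid-weighted sum of spectrum × V(λ); linear in the spectrum."""
    v = curves.sample("vlambda", spectrum.wavelengths_nm)
    if not np.any(v > 0):
        raise ValueError("V(λ) does not overlap the spectrum's wavelength grid")
    return float(np.sum(spectrum.values * v) * spectrum.step_nm)


def scale_to_luminance(
    spectrum: Spectrum, target_cdm2: float, curves: ReferenceCurves
) -> Spectrum:
    """Rescale so that :func:`relative_luminance` equals ``target_cdm2``."""
    if target_cdm2 < 0:
        raise ValueError("target luminance must be non-negative")
    if target_cdm2 == 0:
        return _scaled_allow_zero(spectrum, 0.0, spectrum.label)
    lum = relative_luminance(spectrum, curves)
    if lum <= 0:
        raise ValueError("cannot scale a zero-luminance spectrum to a positive target")
    return _scaled_allow_zero(spectrum, target_cdm2 / lum, spectrum.label)


def mix_spectra(
    a: Spectrum,
    b: Spectrum,
    lum_a: float,
    lum_b: float,
    curves: ReferenceCurves,
    label: str = "",
) -> Spectrum:
    """Sum of the two spectra individually scaled to the requested luminances."""
    if a.wavelengths_nm.shape != b.wavelengths_nm.shape or not np.allclose(
        a.wavelengths_nm, b.wavelengths_nm
    ):
        raise ValueError("mixture components must share the same wavelength grid")
    sa = scale_to_luminance(a, lum_a, curves)
    sb = scale_to_luminance(b, lum_b, curves)
    return Spectrum(a.wavelengths_nm, sa.values + sb.values, label)


def experiment_splits() -> list[tuple[float, float]]:
    """The seven (long, short) luminance splits of the experiment design."""
    longs = np.arange(8.75, 1.25 - 1e-9, -LUMINANCE_STEP_CDM2)
    return [(float(l), float(TOTAL_LUMINANCE_CDM2 - l)) for l in longs]


def figure_splits(n: int = 9) -> list[tuple[float, float]]:
    """n equal steps from completely long-wavelength to completely short."""
    longs = np.linspace(TOTAL_LUMINANCE_CDM2, 0.0, n)
    return [(float(l), float(TOTAL_LUMINANCE_CDM2 - l)) for l in longs]


@dataclass(frozen=True)
class StimulusEntry:
    """One labelled test spectrum of the stimulus set."""

    label: str
    pair: tuple[str, ...]
    lum_long: float
    lum_short: float
    spectrum: Spectrum


def generate_experiment_set(
    curves: ReferenceCurves,
    grid_nm: np.ndarray = DEFAULT_GRID_NM,
    fwhm_nm: dict[str, float] | None = None,
) -> list[StimulusEntry]:
    """Build the 47 test spectra: 5 single LEDs + 6 pairs × 7 mixtures.

    Every spectrum has relative luminance 10 (cd/m², relative photometry).
    Deterministic and order-stable: singles first (descending peak
    wavelength), then pairs in :data:`LED_PAIRS` order with the
    long-wavelength luminance descending from 8.75 to 1.25.
    """
    leds = {}
    for name, primary in LED_PRIMARIES.items():
        if fwhm_nm and name in fwhm_nm:
            primary = LEDPrimary(name, primary.peak_nm, fwhm_nm[name])
        leds[name] = gaussian_led_spectrum(primary, grid_nm)

    entries: list[StimulusEntry] = []
    for name in ("red", "orange", "green", "blue", "violet"):
        spec = scale_to_luminance(leds[name], TOTAL_LUMINANCE_CDM2, curves)
        entries.append(
            StimulusEntry(
                label=f"{name}_10.00",
                pair=(name,),
                lum_long=TOTAL_LUMINANCE_CDM2,
                lum_short=0.0,
                spectrum=Spectrum(spec.wavelengths_nm, spec.values, f"{name}_10.00"),
            )
        )
    for pair in LED_PAIRS:
        for lum_long, lum_short in experiment_splits():
            MixtureDesign(pair, (lum_long, lum_short))  # validates the design
            label = f"{pair[0]}-{pair[1]}_{lum_long:.2f}-{lum_short:.2f}"
            spec = mix_spectra(
                leds[pair[0]], leds[pair[1]], lum_long, lum_short, curves, label
            )
            entries.append(StimulusEntry(label, pair, lum_long, lum_short, spec))
    return entries


def stimulus_set_to_frame(entries: Iterable[StimulusEntry]):
    """Long-format export: label,pair,lum_long,lum_short,wavelength_nm,value."""
    import pandas as pd

    rows = []
    for e in entries:
        pair = "-".join(e.pair)
        for wl, v in zip(e.spectrum.wavelengths_nm, e.spectrum.values):
            rows.append((e.label, pair, e.lum_long, e.lum_short, wl, v))
    return pd.DataFrame(
        rows, columns=["label", "pair", "lum_long", "lum_short", "wavelength_nm", "value"]
    )
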