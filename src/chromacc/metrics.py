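"""Retinal image-quality metrics: Strehl, visual Strehl, LIB, R50, contrast.

All metrics compare an aberrated (or chromatically blurred polychromatic)
PSF/MTF against the equivalent diffraction-limited reference: a zero-phase
pupil of the same diameter with every wavelength in focus (chromatic
aberration removed) and the same spectral weighting — the most favourable
reference the same pupil could achieve.

Area integrals under radial MTFs use the radially symmetric 2-D form
∫ MTF(f) · 2πf df, so azimuthally averaged curves are integrated
consistently with the underlying 2-D transforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .optics import PSFGrid, RadialMTF

__all__ = [
    "NeuralWeighting",
    "MetricValue",
    "csf",
    "strehl_from_mtf",
    "visual_strehl",
    "lib",
    "r50",
    "contrast_at",
    "encircled_energy",
    "dl_core_radius_arcmin",
]


@dataclass(frozen=True)
class NeuralWeighting:
    """Contrast-sensitivity parameterization CSF(f) = a(b + c·s·f)·e^−(c·s·f)^p.

    Defaults reproduce the classic fit a=2.6, b=0.0192, c=0.114, p=1.1 with
    scale factor s=1.  The neural CSF divides out the diffraction-limited
    optics: nCSF(f) = CSF(f) / MTF_DL(f).
    """

    a: float = 2.6
    b: float = 0.0192
    c: float = 0.114
    exponent: float = 1.1
    s: float = 1.0

    def csf(self, frequency_cpd: float | np.ndarray) -> float | np.ndarray:
        f = np.asarray(frequency_cpd, dtype=float)
        if np.any(f < 0):
            raise ValueError("spatial frequency must be non-negative")
        x = self.c * self.s * f
        out = self.a * (self.b + x) * np.exp(-(x**self.exponent))
        return float(out) if np.isscalar(frequency_cpd) else out


def csf(frequency_cpd: float | np.ndarray, weighting: NeuralWeighting | None = None):
    """Behavioural contrast sensitivity at a spatial frequency (cpd)."""
    return (weighting or NeuralWeighting()).csf(frequency_cpd)


@dataclass(frozen=True)
class MetricValue:
    """A named scalar image-quality value at one through-focus position."""

    metric: str
    value: float
    channel: str = "luminance"
    baseline_defocus_D: float = 0.0

    def __post_init__(self) -> None:
        if self.metric in ("strehl", "vsr", "lib"):
            if not (0.0 < self.value <= 1.0 + 1e-9):
                raise ValueError(f"{self.metric} must lie in (0, 1], got {self.value}")
        elif self.metric == "r50":
            if self.value <= 0:
                raise ValueError("r50 must be positive")


#: diffraction-limited MTF below this modulation is treated as beyond the
#: effective cutoff; the nCSF weighting is zeroed there rather than dividing
#: by vanishing modulation
DL_MTF_FLOOR = 1e-3


def _check_shared_grid(mtf: RadialMTF, mtf_dl: RadialMTF) -> np.ndarray:
    if mtf.frequencies_cpd.shape != mtf_dl.frequencies_cpd.shape or not np.allclose(
        mtf.frequencies_cpd, mtf_dl.frequencies_cpd
    ):
        raise ValueError("the two MTFs must share a frequency grid")
    return mtf.frequencies_cpd


def strehl_from_mtf(mtf: RadialMTF, mtf_dl: RadialMTF) -> float:
    """MTF-area Strehl ratio: ∫MTF·2πf df over ∫MTF_DL·2πf df."""
    f = _check_shared_grid(mtf, mtf_dl)
    den = np.trapezoid(mtf_dl.modulation * f, f)
    if den <= 0:
        raise ValueError("diffraction-limited MTF has zero area")
    return float(np.trapezoid(mtf.modulation * f, f) / den)


def visual_strehl(
    mtf: RadialMTF, mtf_dl: RadialMTF, weighting: NeuralWeighting | None = None
) -> float:
    """Visual Strehl ratio: the MTF-area ratio weighted by the neural CSF.

    nCSF = CSF / MTF_DL, so the integrand reduces to CSF · MTF / MTF_DL; the
    weighting is zeroed beyond the diffraction-limited cutoff.
    """
    f = _check_shared_grid(mtf, mtf_dl)
    w = weighting or NeuralWeighting()
    dl = mtf_dl.modulation
    ncsf = np.where(dl >= DL_MTF_FLOOR, w.csf(f) / np.maximum(dl, DL_MTF_FLOOR), 0.0)
    den = np.trapezoid(ncsf * dl * f, f)
    if den <= 0:
        raise ValueError("diffraction-limited weighted MTF has zero area")
    return float(np.trapezoid(ncsf * mtf.modulation * f, f) / den)


def _radial_profile(psf: PSFGrid) -> tuple[np.ndarray, np.ndarray]:
    n = psf.intensity.shape[0]
    c = psf.centre
    idx = np.arange(n) - c
    X, Y = np.meshgrid(idx, idx, indexing="xy")
    rpix = np.rint(np.hypot(X, Y)).astype(int)
    nb = c + 1
    mask = rpix < nb
    sums = np.bincount(rpix[mask], weights=psf.intensity[mask], minlength=nb)
    counts = np.bincount(rpix[mask], minlength=nb)
    return np.arange(nb) * psf.pitch_arcmin, sums / counts


def dl_core_radius_arcmin(dl_reference: PSFGrid) -> float:
    """Radius of the diffraction-limited PSF core: the first local minimum of
    the radial intensity profile, refined parabolically."""
    radii, prof = _radial_profile(dl_reference)
    for i in range(1, prof.size - 1):
        if prof[i] <= prof[i - 1] and prof[i] < prof[i + 1]:
            denom = prof[i - 1] - 2 * prof[i] + prof[i + 1]
            off = 0.5 * (prof[i - 1] - prof[i + 1]) / denom if denom > 0 else 0.0
            return float(radii[i] + off * dl_reference.pitch_arcmin)
    raise ValueError(
        "no local minimum found in the DL radial profile; the core is not "
        "resolvable on this grid"
    )


def _peak_index(psf: PSFGrid) -> tuple[int, int]:
    # centre of the peak plateau, so flat-topped profiles (e.g. a uniform
    # disc) are centred rather than anchored at the first maximal pixel
    arr = psf.intensity
    ys, xs = np.nonzero(arr >= arr.max() * (1.0 - 1e-12))
    return int(round(ys.mean())), int(round(xs.mean()))


def encircled_energy(psf: PSFGrid, radius_arcmin: float, centre: str = "peak") -> float:
    """Energy inside a circle of the given radius, centred at the PSF peak.

    Uses the cumulative energy over pixel radii with linear interpolation, so
    the result varies smoothly with the radius (sub-pixel resolution).
    """
    if centre == "peak":
        cy, cx = _peak_index(psf)
    else:
        cy = cx = psf.centre
    n = psf.intensity.shape[0]
    idx = np.arange(n)
    X, Y = np.meshgrid(idx - cx, idx - cy, indexing="xy")
    r = np.hypot(X, Y).ravel() * psf.pitch_arcmin
    e = psf.intensity.ravel()
    order = np.argsort(r)
    r_sorted = r[order]
    cum = np.cumsum(e[order])
    i = np.searchsorted(r_sorted, radius_arcmin, side="right")
    if i <= 0:
        return 0.0
    if i >= r_sorted.size:
        return float(cum[-1])
    # interpolate across the boundary ring
    r0, r1 = r_sorted[i - 1], r_sorted[i]
    c0, c1 = cum[i - 1], cum[i]
    frac = 0.0 if r1 == r0 else (radius_arcmin - r0) / (r1 - r0)
    return float(c0 + frac * (c1 - c0))


def lib(psf: PSFGrid, dl_reference: PSFGrid) -> float:
    """Light-in-the-bucket: energy within the diffraction-limited core.

    The core radius is the first minimum of the DL reference's radial
    profile; the circle is centred at the evaluated PSF's peak pixel.
    """
    if not math.isclose(psf.pitch_arcmin, dl_reference.pitch_arcmin, rel_tol=1e-9):
        raise ValueError("PSF and DL reference must share the pixel pitch")
    return encircled_energy(psf, dl_core_radius_arcmin(dl_reference))


def r50(psf: PSFGrid) -> float:
    """Radius (arcmin) of the circle containing 50% of the PSF energy,
    centred at the PSF peak, with sub-pixel linear interpolation."""
    cy, cx = _peak_index(psf)
    n = psf.intensity.shape[0]
    if cy in (0, n - 1) or cx in (0, n - 1):
        raise ValueError("PSF peak lies on the grid boundary")
    idx = np.arange(n)
    X, Y = np.meshgrid(idx - cx, idx - cy, indexing="xy")
    r = np.hypot(X, Y).ravel() * psf.pitch_arcmin
    order = np.argsort(r)
    r_sorted = r[order]
    cum = np.cumsum(psf.intensity.ravel()[order])
    i = int(np.searchsorted(cum, 0.5))
    if i == 0:
        return float(r_sorted[0])
    c0, c1 = cum[i - 1], cum[i]
    frac = 0.0 if c1 == c0 else (0.5 - c0) / (c1 - c0)
    return float(r_sorted[i - 1] + frac * (r_sorted[i] - r_sorted[i - 1]))


def contrast_at(mtf: RadialMTF, frequency_cpd: float) -> float:
    """Modulation read off the MTF at a frequency, linearly interpolated."""
    f = mtf.frequencies_cpd
    if not (f[0] <= frequency_cpd <= f[-1]):
        raise ValueError(
            f"frequency {frequency_cpd} cpd lies beyond the MTF grid "
            f"[{f[0]}, {f[-1]}]"
        )
    return float(np.interp(frequency_cpd, f, mtf.modulation))
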