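"""Monochromatic and polychromatic PSF/MTF computation for a model eye.

The eye is modelled as a circular pupil with a wavefront phase made of a
defocus term plus an ANSI/OSA Zernike expansion, imaged by Fourier optics:
the PSF is the squared modulus of the Fourier transform of the generalized
pupil function.  Longitudinal chromatic aberration follows the empirical
hyperbola D(λ) = q1 − q2/(λ − q3) (λ in µm, diopters relative to 580 nm).

Axis convention
---------------
Through-focus quantities are parameterized by a single scalar ``defocus_D``
("baseline defocus relative to 580 nm"), the x-axis of all through-focus
curves.  A wavelength λ is exactly in focus when ``defocus_D == D(λ)``; the
monochromatic defocus entering the pupil phase is ``ΔF = D(λ) − defocus_D``.
On this axis the red LED's demand is positive (≈ +0.31 D) and the violet
LED's negative (≈ −1.06 D), matching the sign of the accommodation change
needed relative to the 580-nm reference.

Sampling
--------
PSFs for all wavelengths share one angular pixel pitch.  The pupil-plane
sample spacing therefore varies with λ (dx = λ / (n · pitch)); the default
pitch is chosen from the shortest wavelength so the pupil autocorrelation
(OTF support) always fits inside the grid (zero-padding factor ≥ 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .spectra import ReferenceCurves, Spectrum

__all__ = [
    "LCA_Q_DEFAULT",
    "REFERENCE_WAVELENGTH_NM",
    "OPTICS_WAVELENGTHS_NM",
    "EyeModel",
    "GridConfig",
    "PSFGrid",
    "RadialMTF",
    "chromatic_defocus",
    "zernike",
    "pupil_phase",
    "mono_psf",
    "poly_psf",
    "psf_to_mtf",
    "spectral_weights",
    "MonoOTFLibrary",
    "build_otf_library",
]

#: LCA hyperbola constants (q1, q2, q3); zero at the 580-nm reference
LCA_Q_DEFAULT: tuple[float, float, float] = (1.7312, 0.63346, 0.21410)

REFERENCE_WAVELENGTH_NM = 580.0

#: wavelength grid of the polychromatic summation: 400–700 nm in 5-nm steps
OPTICS_WAVELENGTHS_NM = np.arange(400.0, 700.0 + 1e-9, 5.0)

ARCMIN_PER_RAD = 60.0 * 180.0 / math.pi
CPD_PER_CYC_PER_RAD = math.pi / 180.0  # cycles/rad → cycles/deg


def chromatic_defocus(
    wavelength_um: float | np.ndarray,
    q: tuple[float, float, float] = LCA_Q_DEFAULT,
) -> float | np.ndarray:
    """Chromatic defocus D(λ) = q1 − q2/(λ − q3), diopters relative to 580 nm.

    ``wavelength_um`` is in microns and must lie in (q3 + 0.05, 1.0); the
    hyperbola has a singularity at q3 ≈ 214 nm.
    """
    lam = np.asarray(wavelength_um, dtype=float)
    q1, q2, q3 = q
    if np.any(lam <= q3 + 0.05) or np.any(lam >= 1.0):
        raise ValueError(
            f"wavelength must lie in ({q3 + 0.05:.3f}, 1.0) µm, got {wavelength_um}"
        )
    out = q1 - q2 / (lam - q3)
    return float(out) if np.isscalar(wavelength_um) else out


@dataclass(frozen=True)
class EyeModel:
    """Pupil diameter, Zernike phase coefficients and LCA constants.

    ``zernike_um`` maps ANSI/OSA double indices (n, m) to coefficients in
    microns (unit-variance normalization).  With no coefficients and zero
    defocus the phase is identically zero: a diffraction-limited eye.
    """

    pupil_diameter_mm: float = 5.0
    zernike_um: Mapping[tuple[int, int], float] = field(default_factory=dict)
    lca_q: tuple[float, float, float] = LCA_Q_DEFAULT
    reference_wavelength_nm: float = REFERENCE_WAVELENGTH_NM

    def __post_init__(self) -> None:
        if not (1.0 < self.pupil_diameter_mm < 9.0):
            raise ValueError("pupil diameter must lie in (1, 9) mm")
        for (n, m) in self.zernike_um:
            if n < 0 or abs(m) > n or (n - abs(m)) % 2:
                raise ValueError(f"invalid Zernike index (n={n}, m={m})")

    @property
    def pupil_radius_m(self) -> float:
        return self.pupil_diameter_mm * 1e-3 / 2.0

    def is_axisymmetric(self) -> bool:
        """True when all Zernike terms have azimuthal frequency m == 0."""
        return all(m == 0 for (_, m), c in self.zernike_um.items() if c != 0.0)


@dataclass(frozen=True)
class GridConfig:
    """Pupil/PSF sampling configuration.

    ``n`` is the FFT grid side.  ``pitch_arcmin`` is the PSF pixel pitch; if
    None it is derived as λ_min / (pad_min · pupil diameter) so the shortest
    wavelength still has OTF support inside the grid.  Validation enforces a
    pitch ≤ 0.25 arcmin and a PSF Nyquist frequency ≥ 120 cpd.
    """

    n: int = 512
    pitch_arcmin: float | None = None
    pad_min: float = 2.0
    wl_min_nm: float = 400.0

    def pitch_rad(self, eye: EyeModel) -> float:
        d = eye.pupil_diameter_mm * 1e-3
        if self.pitch_arcmin is None:
            pitch = self.wl_min_nm * 1e-9 / (self.pad_min * d)
        else:
            pitch = self.pitch_arcmin / ARCMIN_PER_RAD
        if pitch * ARCMIN_PER_RAD > 0.25 + 1e-12:
            raise ValueError(
                f"PSF pixel pitch {pitch * ARCMIN_PER_RAD:.3f} arcmin exceeds the "
                "0.25 arcmin sampling bound"
            )
        nyq_cpd = 1.0 / (2.0 * pitch) * CPD_PER_CYC_PER_RAD
        if nyq_cpd < 120.0:
            raise ValueError(
                f"PSF Nyquist frequency {nyq_cpd:.1f} cpd is below the 120 cpd bound"
            )
        return pitch

    def pupil_samples(self, eye: EyeModel, wavelength_nm: float) -> float:
        """Number of samples across the pupil diameter at this wavelength."""
        pitch = self.pitch_rad(eye)
        d = eye.pupil_diameter_mm * 1e-3
        M = self.n * pitch * d / (wavelength_nm * 1e-9)
        if M < 16.0:
            raise ValueError(
                f"pupil resolved by only {M:.1f} samples at {wavelength_nm:g} nm "
                "(bound: ≥ 16); decrease the pitch or increase n"
            )
        if M > self.n / 2.0 + 1e-9:
            raise ValueError(
                f"pupil spans {M:.1f} of {self.n} samples at {wavelength_nm:g} nm, "
                "leaving a zero-padding factor < 2 (OTF support would alias); "
                "increase the pitch or n"
            )
        return M

    def freq_step_cpd(self, eye: EyeModel) -> float:
        return 1.0 / (self.n * self.pitch_rad(eye)) * CPD_PER_CYC_PER_RAD


@dataclass(frozen=True)
class PSFGrid:
    """A 2-D point-spread function with angular pixel pitch.

    ``intensity`` is square and odd-sided (well-defined centre pixel) and
    sums to 1.
    """

    intensity: np.ndarray
    pitch_arcmin: float
    tag: str = ""
    channel: str = "none"

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1] or arr.shape[0] % 2 == 0:
            raise ValueError("PSF must be square with an odd side")
        if np.any(arr < -1e-12):
            raise ValueError("PSF intensity must be non-negative")
        s = arr.sum()
        if not math.isclose(s, 1.0, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(f"PSF must be normalized to unit sum (got {s!r})")
        arr.flags.writeable = False
        object.__setattr__(self, "intensity", arr)

    @property
    def centre(self) -> int:
        return self.intensity.shape[0] // 2


@dataclass(frozen=True)
class RadialMTF:
    """Azimuthally averaged modulation vs spatial frequency (cpd)."""

    frequencies_cpd: np.ndarray
    modulation: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_cpd, dtype=float)
        m = np.asarray(self.modulation, dtype=float)
        if f.ndim != 1 or f.shape != m.shape:
            raise ValueError("frequency and modulation arrays must match")
        if f[0] != 0.0 or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must increase from 0")
        if not math.isclose(m[0], 1.0, rel_tol=1e-9):
            raise ValueError("modulation at 0 cpd must equal 1")
        if f[-1] < 60.0:
            raise ValueError("frequency grid must extend to at least 60 cpd")
        f.flags.writeable = False
        m.flags.writeable = False
        object.__setattr__(self, "frequencies_cpd", f)
        object.__setattr__(self, "modulation", m)


# ---------------------------------------------------------------------------
# Zernike polynomials (ANSI/OSA double index, unit-variance normalization)


def zernike(n: int, m: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Zernike polynomial Z_n^m on the unit disc, RMS-normalized."""
    if n < 0 or abs(m) > n or (n - abs(m)) % 2:
        raise ValueError(f"invalid Zernike index (n={n}, m={m})")
    am = abs(m)
    R = np.zeros_like(rho)
    for k in range((n - am) // 2 + 1):
        c = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + am) // 2 - k)
                * math.factorial((n - am) // 2 - k)
            )
        )
        R = R + c * rho ** (n - 2 * k)
    norm = math.sqrt(2.0 * (n + 1)) if m != 0 else math.sqrt(n + 1.0)
    if m > 0:
        ang = np.cos(am * theta)
    elif m < 0:
        ang = np.sin(am * theta)
    else:
        ang = np.ones_like(theta)
    return norm * R * ang


def pupil_phase(
    eye: EyeModel,
    wavelength_nm: float,
    defocus_D: float,
    r_m: np.ndarray,
    theta: np.ndarray,
) -> np.ndarray:
    """Wavefront phase (radians) over the pupil at radius ``r_m`` (metres).

    ``defocus_D`` here is the *monochromatic* defocus ΔF entering the pupil
    function.  The phase is π·ΔF·r²/λ plus the Zernike expansion converted
    from microns of wavefront to radians at this wavelength; it is zero
    everywhere for a diffraction-limited eye.
    """
    if abs(defocus_D) > 10.0:
        raise ValueError("|defocus| must not exceed 10 D")
    lam = wavelength_nm * 1e-9
    phase = math.pi * defocus_D * np.asarray(r_m, dtype=float) ** 2 / lam
    if eye.zernike_um:
        rho = np.asarray(r_m, dtype=float) / eye.pupil_radius_m
        for (n, m), c_um in eye.zernike_um.items():
            if c_um:
                phase = phase + (2.0 * math.pi / lam) * c_um * 1e-6 * zernike(
                    n, m, rho, theta
                )
    return phase


# ---------------------------------------------------------------------------
# PSF computation


def _pupil_geometry(eye: EyeModel, grid: GridConfig, wavelength_nm: float):
    """Pupil-plane coordinates and antialiased aperture for one wavelength."""
    grid.pupil_samples(eye, wavelength_nm)  # validates the sampling bounds
    pitch = grid.pitch_rad(eye)
    lam = wavelength_nm * 1e-9
    dx = lam / (grid.n * pitch)
    c = np.arange(grid.n) - grid.n // 2
    X, Y = np.meshgrid(c * dx, c * dx, indexing="xy")
    r = np.hypot(X, Y)
    theta = np.arctan2(Y, X)
    R = eye.pupil_radius_m
    # grey-pixel aperture edge: linear coverage ramp one sample wide
    amp = np.clip(0.5 + (R - r) / dx, 0.0, 1.0)
    return amp, r, theta, pitch, dx


def _psf_array(eye, grid, wavelength_nm, defocus_mono_D) -> tuple[np.ndarray, float]:
    amp, r, theta, pitch, _ = _pupil_geometry(eye, grid, wavelength_nm)
    phase = pupil_phase(eye, wavelength_nm, defocus_mono_D, r, theta)
    field = amp * np.exp(1j * phase)
    A = np.fft.fft2(field)
    psf = np.abs(A) ** 2
    psf = np.fft.fftshift(psf)
    return psf, pitch


def _crop_odd(psf: np.ndarray) -> np.ndarray:
    # even FFT grid → centre at n//2; drop row/col 0 for a symmetric odd grid
    if psf.shape[0] % 2 == 0:
        psf = psf[1:, 1:]
    return psf


def mono_psf(
    eye: EyeModel,
    wavelength_nm: float,
    defocus_D: float,
    grid: GridConfig = GridConfig(),
    channel: str = "none",
) -> PSFGrid:
    """Monochromatic PSF at a single wavelength and monochromatic defocus ΔF."""
    psf, pitch = _psf_array(eye, grid, wavelength_nm, defocus_D)
    psf = _crop_odd(psf)
    psf = psf / psf.sum()
    return PSFGrid(psf, pitch * ARCMIN_PER_RAD, tag=f"{wavelength_nm:g}nm", channel=channel)


def spectral_weights(
    spectrum: Spectrum,
    curves: ReferenceCurves,
    channel: str = "luminance",
    wavelengths_nm: np.ndarray = OPTICS_WAVELENGTHS_NM,
) -> np.ndarray:
    """Normalized per-wavelength weights: spectrum × channel sensitivity.

    ``channel`` is one of luminance / L / M / S.  Weights are renormalized to
    unit sum so that differently weighted channels are directly comparable.
    """
    curve_name = {
        "luminance": "vlambda",
        "L": "cone_L",
        "M": "cone_M",
        "S": "cone_S",
    }.get(channel)
    if curve_name is None:
        raise ValueError(f"unknown channel {channel!r}")
    vals = np.interp(
        wavelengths_nm, spectrum.wavelengths_nm, spectrum.values, left=0.0, right=0.0
    )
    w = vals * curves.sample(curve_name, wavelengths_nm)
    total = w.sum()
    if total <= 0:
        raise ValueError("spectrum is entirely zero after channel weighting")
    return w / total


def poly_psf(
    eye: EyeModel,
    spectrum: Spectrum,
    curves: ReferenceCurves,
    baseline_defocus_D: float,
    channel: str = "luminance",
    grid: GridConfig = GridConfig(),
    wavelengths_nm: np.ndarray = OPTICS_WAVELENGTHS_NM,
    dl_reference: bool = False,
) -> PSFGrid:
    """Polychromatic PSF: channel-weighted sum of monochromatic PSFs.

    For each wavelength the monochromatic defocus is ΔF = D(λ) − baseline,
    so the PSF describes an eye accommodated to ``baseline_defocus_D`` on
    the defocus-relative-to-580-nm axis.  With ``dl_reference=True`` the
    pupil phase is zeroed and every wavelength is in focus: the equivalent
    diffraction-limited eye used as the metric reference.
    """
    w = spectral_weights(spectrum, curves, channel, wavelengths_nm)
    dl_eye = EyeModel(eye.pupil_diameter_mm, {}, eye.lca_q, eye.reference_wavelength_nm)
    acc = None
    for wl, wi in zip(wavelengths_nm, w):
        if wi <= 0:
            continue
        if dl_reference:
            psf, pitch = _psf_array(dl_eye, grid, wl, 0.0)
        else:
            dF = chromatic_defocus(wl * 1e-3, eye.lca_q) - baseline_defocus_D
            psf, pitch = _psf_array(eye, grid, wl, dF)
        psf = _crop_odd(psf)
        psf /= psf.sum()
        acc = wi * psf if acc is None else acc + wi * psf
    acc = acc / acc.sum()
    return PSFGrid(
        acc, grid.pitch_rad(eye) * ARCMIN_PER_RAD, tag="polychromatic", channel=channel
    )


def psf_to_mtf(psf: PSFGrid, max_freq_cpd: float | None = None) -> RadialMTF:
    """Azimuthal average of the 2-D Fourier amplitude of the PSF.

    With non-axisymmetric aberrations this is an orientation average,
    appropriate for the broad-orientation Maltese-cross stimulus.
    """
    arr = psf.intensity
    F = np.fft.fft2(np.fft.ifftshift(arr))
    mag = np.abs(F)
    n = arr.shape[0]
    fx = np.fft.fftfreq(n) * n
    RX, RY = np.meshgrid(fx, fx, indexing="xy")
    ridx = np.rint(np.hypot(RX, RY)).astype(int)
    nb = n // 2 + 1
    mask = ridx < nb
    sums = np.bincount(ridx[mask], weights=mag[mask], minlength=nb)
    counts = np.bincount(ridx[mask], minlength=nb)
    prof = sums / counts
    pitch_rad = psf.pitch_arcmin / ARCMIN_PER_RAD
    df_cpd = 1.0 / (n * pitch_rad) * CPD_PER_CYC_PER_RAD
    freqs = np.arange(nb) * df_cpd
    prof = prof / prof[0]
    if max_freq_cpd is not None:
        keep = freqs <= max_freq_cpd
        freqs, prof = freqs[keep], prof[keep]
    return RadialMTF(freqs, np.clip(prof, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Radial OTF library: the fast path for through-focus sweeps


@dataclass(frozen=True)
class MonoOTFLibrary:
    """Radial monochromatic OTFs tabulated over (wavelength, baseline).

    ``otf[i, j, k]`` is the real radial OTF of wavelength ``wavelengths_nm[i]``
    at monochromatic defocus D(λᵢ) − ``baseline_D[j]``, sampled at frequency
    ``freq_cpd[k]``; ``dl_otf`` holds the in-focus (ΔF = 0, zero-phase)
    references.  Valid only for axisymmetric eyes, where the OTF is real and
    rotationally symmetric so radial profiles combine linearly across
    wavelengths; polychromatic MTF(f) = |Σ w_λ · OTF_λ(f)|.
    """

    eye: EyeModel
    grid: GridConfig
    wavelengths_nm: np.ndarray
    baseline_D: np.ndarray
    freq_cpd: np.ndarray
    otf: np.ndarray
    dl_otf: np.ndarray

    def poly_mtf(self, weights: np.ndarray) -> np.ndarray:
        """Polychromatic MTF per baseline: shape (n_baseline, n_freq)."""
        return np.abs(np.einsum("w,wbf->bf", weights, self.otf))

    def poly_dl_mtf(self, weights: np.ndarray) -> np.ndarray:
        """Diffraction-limited (all wavelengths in focus) polychromatic MTF."""
        return np.abs(weights @ self.dl_otf)


def _radial_bin_setup(n: int):
    fx = np.fft.fftfreq(n) * n
    RX, RY = np.meshgrid(fx, fx, indexing="xy")
    ridx = np.rint(np.hypot(RX, RY)).astype(int)
    nb = n // 2 + 1
    mask = ridx < nb
    counts = np.bincount(ridx[mask], minlength=nb)
    return ridx, mask, counts, nb


def build_otf_library(
    eye: EyeModel,
    grid: GridConfig,
    baseline_D: np.ndarray,
    wavelengths_nm: np.ndarray = OPTICS_WAVELENGTHS_NM,
    chunk: int = 24,
    single_precision: bool = True,
) -> MonoOTFLibrary:
    """Tabulate radial monochromatic OTFs for every (λ, baseline) pair.

    The through-focus machinery reuses this library across spectra and
    channels: a polychromatic MTF is a weighted sum over its first axis.
    Single precision is the default; OTF round-off (~1e-6) is far below the
    metric tolerances the library serves.
    """
    import scipy.fft as _fft

    if not eye.is_axisymmetric():
        raise ValueError(
            "the radial OTF library requires an axisymmetric eye (Zernike m == 0 "
            "terms only); use poly_psf + psf_to_mtf for the general case"
        )
    baseline_D = np.asarray(baseline_D, dtype=float)
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    steps = np.diff(baseline_D)
    uniform = steps.size > 0 and np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12)
    cdtype = np.complex64 if single_precision else np.complex128
    n = grid.n
    ridx, mask, counts, nb = _radial_bin_setup(n)
    ridx_m = ridx[mask]

    otf = np.empty((wavelengths_nm.size, baseline_D.size, nb))
    dl = np.empty((wavelengths_nm.size, nb))

    for i, wl in enumerate(wavelengths_nm):
        amp, r, theta, pitch, _ = _pupil_geometry(eye, grid, wl)
        lam = wl * 1e-9
        static = np.zeros_like(r)
        if eye.zernike_um:
            rho = r / eye.pupil_radius_m
            for (nz, mz), c_um in eye.zernike_um.items():
                if c_um:
                    static += (2 * math.pi / lam) * c_um * 1e-6 * zernike(nz, mz, rho, theta)
        dF_all = chromatic_defocus(wl * 1e-3, eye.lca_q) - baseline_D
        r2 = r * r
        # uniform baseline grid → successive defocus phases differ by a fixed
        # factor, so build each chunk by a running phase multiply instead of a
        # fresh complex exponential per plane
        estep = (
            np.exp(-1j * (math.pi / lam) * steps[0] * r2).astype(cdtype)
            if uniform
            else None
        )
        for j0 in range(0, dF_all.size, chunk):
            dF = dF_all[j0 : j0 + chunk]
            fields = np.empty((dF.size, n, n), dtype=cdtype)
            fields[0] = amp * np.exp(1j * ((math.pi / lam) * dF[0] * r2 + static))
            if uniform:
                for jj in range(1, dF.size):
                    np.multiply(fields[jj - 1], estep, out=fields[jj])
            else:
                for jj in range(1, dF.size):
                    fields[jj] = amp * np.exp(
                        1j * ((math.pi / lam) * dF[jj] * r2 + static)
                    )
            A = _fft.fft2(fields, axes=(-2, -1), overwrite_x=True)
            psf = A.real**2 + A.imag**2
            psf /= psf.sum(axis=(-2, -1), keepdims=True)
            O = _fft.fft2(psf.astype(cdtype), axes=(-2, -1), overwrite_x=True).real
            flat_idx = (
                ridx_m[None, :] + nb * np.arange(O.shape[0])[:, None]
            ).ravel()
            sums = np.bincount(
                flat_idx, weights=O[:, mask].ravel(), minlength=nb * O.shape[0]
            ).reshape(O.shape[0], nb)
            otf[i, j0 : j0 + dF.size] = sums / counts
        # zero-phase in-focus reference at this wavelength (double precision)
        A = np.fft.fft2(amp)
        psf0 = A.real**2 + A.imag**2
        psf0 /= psf0.sum()
        O0 = np.fft.fft2(psf0).real
        sums = np.bincount(ridx_m, weights=O0[mask], minlength=nb)
        dl[i] = sums / counts

    df_cpd = grid.freq_step_cpd(eye)
    freqs = np.arange(nb) * df_cpd
    return MonoOTFLibrary(
        eye=eye,
        grid=grid,
        wavelengths_nm=wavelengths_nm,
        baseline_D=baseline_D,
        freq_cpd=freqs,
        otf=otf,
        dl_otf=dl,
    )
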