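"""Independent numerical oracles for the wave-optics tests.

These deliberately avoid the FFT pipeline under test: the pupil integral is
evaluated by direct Gauss–Legendre quadrature over the pupil disc, and the
diffraction-limited references come from the closed-form Airy/circular-
aperture expressions.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import j0, j1, roots_legendre


def quadrature_psf(
    eye,
    wavelength_nm: float,
    defocus_D: float,
    theta_x: np.ndarray,
    theta_y: np.ndarray,
    n_radial: int = 96,
    n_angular: int = 192,
) -> np.ndarray:
    """Brute-force pupil integral |A(θx, θy)|² on given field angles (rad).

    Matches the FFT sign convention: A = ∫∫ P(x, y) e^{−i2π(xθx + yθy)/λ} dA
    with P = e^{iφ} over the pupil disc.
    """
    from chromacc.optics import pupil_phase

    lam = wavelength_nm * 1e-9
    R = eye.pupil_radius_m
    # Gauss-Legendre in r² (uniform-area mapping), trapezoid in angle
    u, wu = roots_legendre(n_radial)
    r = R * np.sqrt(0.5 * (u + 1.0))
    wr = 0.5 * wu * R**2 / 2.0  # ∫ r dr = ∫ d(r²)/2
    ang = np.linspace(0.0, 2 * math.pi, n_angular, endpoint=False)
    wa = 2 * math.pi / n_angular
    rr, aa = np.meshgrid(r, ang, indexing="ij")
    x = rr * np.cos(aa)
    y = rr * np.sin(aa)
    phi = pupil_phase(eye, wavelength_nm, defocus_D, rr, aa)
    w2d = (wr[:, None] * wa) * np.ones_like(aa)
    out = np.empty(np.shape(theta_x), dtype=float)
    tx = np.atleast_1d(np.asarray(theta_x, float)).ravel()
    ty = np.atleast_1d(np.asarray(theta_y, float)).ravel()
    vals = []
    for txi, tyi in zip(tx, ty):
        kern = np.exp(1j * (phi - 2 * math.pi * (x * txi + y * tyi) / lam))
        vals.append(abs((kern * w2d).sum()) ** 2)
    return np.asarray(vals).reshape(np.shape(theta_x))


def airy_encircled_energy(v: float) -> float:
    """Fraction of Airy-pattern energy within reduced radius v = π·d·θ/λ."""
    return 1.0 - j0(v) ** 2 - j1(v) ** 2


AIRY_FIRST_ZERO_V = 3.8317059702075125  # first zero of J1


def airy_core_energy() -> float:
    """Encircled energy within the first Airy minimum (≈ 0.8378)."""
    return airy_encircled_energy(AIRY_FIRST_ZERO_V)


def airy_half_energy_radius_rad(wavelength_m: float, pupil_diameter_m: float) -> float:
    """Radius (rad) containing 50% of the Airy pattern energy (closed form,
    solved numerically on the encircled-energy expression)."""
    from scipy.optimize import brentq

    v50 = brentq(lambda v: airy_encircled_energy(v) - 0.5, 0.5, AIRY_FIRST_ZERO_V)
    return v50 * wavelength_m / (math.pi * pupil_diameter_m)


def circular_mtf(nu: np.ndarray) -> np.ndarray:
    """Diffraction-limited MTF of a circular aperture vs normalized frequency."""
    nu = np.clip(np.asarray(nu, dtype=float), 0.0, None)
    out = np.zeros_like(nu)
    m = nu < 1.0
    out[m] = (2.0 / math.pi) * (
        np.arccos(nu[m]) - nu[m] * np.sqrt(1.0 - nu[m] ** 2)
    )
    return out
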