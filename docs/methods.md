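# Methods

## The model

`chromacc` models a single accommodating eye viewing a back-illuminated
target under mixtures of narrowband LED primaries, and asks where different
candidate control rules would drive accommodation.

**Wave optics.** The eye is a circular pupil (default diameter 5 mm for the
experiment reproductions, 6 mm for the daylight comparison) with a
generalized pupil function `P = A·exp(iφ)`. The aperture `A` is a top-hat
disc with a one-sample linear ("grey-pixel") edge ramp, which keeps the
diffraction-limited MTF within 1% of the circular-aperture closed form. The
phase is a defocus term plus an ANSI/OSA Zernike expansion with
unit-variance normalization and coefficients in microns:

    φ(r) = π·ΔF·r²/λ + (2π/λ)·Σ c_nm·Z_nm(r/R, θ)

with `r` and `λ` in metres and `ΔF` in diopters. (This is the standard
defocus-phase relation, i.e. wavefront `W = ΔF·r²/2`; a printed variant of
this expression that divides by `ΔF` is dimensionally inconsistent and is
not used.) The PSF is the squared modulus of the Fourier transform of `P`,
verified against direct Gauss–Legendre quadrature of the pupil integral to
1e−3 of the peak.

**Chromatic aberration.** Longitudinal chromatic aberration follows the
empirical hyperbola

    D(λ) = q1 − q2/(λ − q3),   q = (1.7312, 0.63346, 0.21410), λ in µm,

zero at the 580-nm reference. All through-focus axes use a single scalar
"defocus relative to 580 nm": wavelength λ is in focus when the axis value
equals `D(λ)`, and the monochromatic defocus entering the pupil phase is
`ΔF = D(λ) − axis`. On this axis the red LED's demand is +0.31 D and the
violet LED's −1.06 D; responses relative to the orange pretrial subtract
`D(0.588) = +0.037 D`.

**Polychromatic PSFs.** Monochromatic PSFs are computed at 400–700 nm in
5-nm steps, weighted by the test spectrum times a channel sensitivity
(V(λ), or an L/M/S cone fundamental), renormalized to unit weight sum, and
summed. All wavelengths share one angular pixel pitch by scaling the
pupil-plane sample spacing with λ, so the summation needs no resampling.

**Through-focus machinery.** For an axisymmetric eye the OTF is real and
rotationally symmetric, so the package tabulates radial monochromatic OTFs
over (wavelength × baseline-defocus) once per pupil configuration and forms
any spectrum's or channel's polychromatic MTF as `|Σ w_λ·OTF_λ|` — a matrix
product. Every sweep, prediction curve and the D65 comparison reuse one
such library; PSF-domain metrics (LIB, R50) and non-axisymmetric eyes take
the direct per-baseline PSF route instead.

## Image-quality metrics

* **Strehl (MTF-area form):** ratio of `∫ MTF(f)·2πf df` to the
  diffraction-limited value. The 2πf weight makes the integral of the
  azimuthally averaged curve consistent with the underlying 2-D transform.
  This area form equals the central-intensity Strehl only while the OTF is
  non-negative (defocus ≲ 0.6λ of W020); the mutual-oracle test covers that
  regime.
* **Visual Strehl (VSR):** the same ratio with the integrand weighted by
  the neural CSF, `nCSF(f) = CSF(f)/MTF_DL(f)`, where
  `CSF(f) = 2.6(0.0192 + 0.114·s·f)·exp(−(0.114·s·f)^1.1)` with scale
  factor `s = 1` (exposed as a parameter). The denominator uses the
  diffraction-limited MTF of the same pupil — dividing by the aberrated MTF
  would cancel the eye's optics out of the metric entirely — and the
  weighting is zeroed where `MTF_DL < 1e−3` (the effective cutoff).
* **Diffraction-limited reference:** a zero-phase pupil of the same
  diameter with *every* wavelength in focus and the same spectral
  weighting — the most favourable equivalent eye. This polychromatic DL
  reference is used for Strehl, VSR and the LIB core.
* **LIB:** energy within the DL core (first minimum of the DL radial
  profile, parabolic sub-pixel refinement), circle centred at the evaluated
  PSF's peak pixel; flat peak plateaus are centred on their centroid.
* **R50:** smallest radius containing 50% of the energy, centred at the
  peak, linear interpolation over the sorted-radius cumulative sum.
  Encircled-energy grids need a wide angular extent: the Airy tail carries
  ~2/(πv) of the energy, so a grid truncated at reduced radius v inflates
  normalized core fractions by that fraction.
* **contrast@f:** modulation read off the radial MTF by linear
  interpolation.

## Prediction rules

* **Global:** argmax (argmin for R50) with parabolic refinement. Local
  optima within 0.5% of the best are reported together with an ambiguity
  flag, so FFT-level noise never silently picks a side; when a curve needs
  one value per split, ties resolve to the lowest accommodative effort
  (|defocus| closest to 0).
* **Local:** hill-climb from a starting state to the nearest local
  optimum; an exact saddle start moves toward lower effort.
* **EquateLM:** sign changes of (L-channel − M-channel) metric values,
  linearly interpolated. All crossings are returned; any count other than
  one is flagged ambiguous. Channels whose maximum difference is below 1%
  of the larger channel are fully degenerate (no usable cue). Crossings
  where both channels sit below 2% of their peak are discarded: they are
  numerical noise between near-zero quality curves, not a cue an observer
  could use. Under the default LED model this floor leaves exactly one
  crossing per red–blue mixture (valley levels 5–8% of peak) while single
  LEDs retain multiple high-level crossings and are therefore ambiguous —
  the behaviour expected of a narrowband stimulus, where the two cone
  channels see essentially the same image.
* **Curves:** nine equal splits reproduce the figure-style sweeps
  (including the pure LEDs and the even split); seven splits match the
  experiment design. Shape summaries: largest between-split jump, its
  location, and a linearity score (squared correlation of prediction vs
  split).

## Stimuli and spectra

LED radiance curves are published only graphically, so primaries are
Gaussian profiles with the stated peaks (660/588/527/461/441 nm) and a
default 25-nm FWHM (configurable per LED within the measured 20–50 nm
range). Photometry is relative: spectra are scaled so that
`Σ S(λ)V(λ)Δλ` equals the nominal luminance, and only ratios matter.

Embedded reference tables (10-nm tabulations, linearly interpolated): the
CIE 1931 2° colour-matching functions (ȳ = the 1924 photopic V(λ)) and the
D65 spectral power distribution. Cone fundamentals are derived from the
colour-matching functions via the Smith–Pokorny/Boynton transform, so
L + M = V(λ) exactly and the peaks (≈566/541/445 nm) match classical
fundamentals; the S cone follows z̄. The sensitivity of the daylight
results to this choice is modest but real — transforms whose L/M peaks sit
a few nm redder shift the D65 L/M crossing by roughly +0.01 D per 2 nm —
which is why the crossing is quoted with a ±0.02 D band.

## Trace analysis

PowerRef-style traces are sampled at 50 Hz (configurable; all window
arithmetic derives from the rate). Cleaning masks missing-pupil runs plus
80 ms before and 160 ms after (rounded outward to whole samples) and
|refraction| > 20 D samples individually; masked samples are excluded, not
interpolated. Static responses are the trial mean over its final 1500 ms
minus the preceding pretrial mean over its final 1000 ms. Within-trial
variance is the mean per-trial sample variance; between-trial variance the
unbiased variance of per-trial relative responses (≥2 trials). Aggregation
reports grand means of observer means with SEM across observers. One-way
ANOVA and Levene tests per LED pair are delegated to scipy.stats.

## Synthetic observers

The generator emulates the statistical structure the pipeline assumes —
not the full physiology of accommodation:

| parameter | default | why |
|---|---|---|
| gain | 0.6 | partial LCA compensation at a 3-D viewing distance |
| bias κ | 2.0 | long-wavelength-biased, not-quite-linear blending |
| sample noise | 0.15 D | photorefraction-typical per-sample scatter |
| microfluctuation | 0.1 D at 1.5 Hz | low-frequency accommodative wobble |
| blink rate / duration | 0.25 Hz / 150 ms | ordinary blinking, pupil lost |
| drift | 0.05 D/min | slow head-position/fatigue drift |
| response lag τ | 200 ms | first-order step response |

Ground truth: singles respond `gain·(D(λ) − D(0.588))`; mixtures blend the
two primary responses with weight `w = L_long^κ/(L_long^κ + L_short^κ)`.
The switching variant instead draws each trial's response from one primary
with logistic probability in the luminance split. The lag constant is set
so the residual transient inside the analysis windows stays below 1e−3 D
(at 300 ms it would reach ≈5e−3 D for violet-dominant spectra and dominate
noiseless recovery error); 200 ms is still within the physiological range
of accommodation time constants. An optional knob scales microfluctuation
amplitude with short-wavelength luminance (off by default) to emulate the
greater variability seen for short wavelengths.

What passing tests show — and don't: the pipeline recovers known static
responses unbiasedly under blinks, noise, drift and lag, and the
between-trial variance diagnostic separates switching from
weighted-average behaviour (hump excess threshold 0.02 D², an order of
magnitude above the weighted observer's trial-to-trial variance and far
below the ≈0.1 D² bimodal variance of a switching observer). Real traces
add autorefractor calibration error, instruction effects, fatigue
structure and non-sinusoidal microfluctuations that the generator does not
model.

## Numerical choices

* Pupil grids: 512² for single-PSF work, 256² for through-focus libraries;
  PSF pixel pitch auto-set to λ_min/(2·pupil) (≈0.14 arcmin at 5 mm),
  bounds enforced (pitch ≤ 0.25′, Nyquist ≥ 120 cpd, ≥16 samples across
  the pupil, padding factor ≥ 2).
* Through-focus grid: −1.5…+1.5 D in 0.01 D steps, parabolic refinement of
  optima; beyond ≈2 D of monochromatic defocus at 5 mm the PSF's geometric
  extent approaches the grid edge and deep-tail sweep values become
  approximate (predictions live near the demands, well inside that range).
* OTF libraries run in single precision (round-off ~1e−6, far below metric
  tolerances); single PSFs in double precision.
* Rendering convolves in the transform domain with full linear output (no
  circular wrap; flux conserved exactly); PSF kernels are resampled to the
  stimulus scale by exact area integration of the cumulative image.
* The Maltese cross uses 45° wedge arms (the printed target's taper is not
  published), 1.5° across in a 2.6° field; the two-wavelength demo uses
  460/530 nm over 1.6°.

## Known limitations

* No Stiles–Crawford apodization, scatter, off-axis imaging, temporal
  accommodation dynamics, or binocular/vergence effects.
* Gaussian LED profiles are a documented stand-in for the measured,
  asymmetric spectra; quantities that depend on the LEDs' spectral tails —
  notably how far EquateLM crossings drift with luminance ratio — inherit
  that approximation.
* The higher-order-aberration survey is supported generically (any
  Zernike set) but no specific aberration census is reproduced; figure
  reproductions default to a defocus-only eye.
* Colorimetric rendering (XYZ/chromaticity) and LED drive (PWM/flicker)
  modelling are out of scope.
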