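"""Synthetic observers and PowerRef-style sessions with known ground truth.

The generator emulates the statistical structure the trace pipeline
assumes: a static observer whose response to each test spectrum is a
luminance-weighted blend of the two primary demands with incomplete
compensation for chromatic aberration, sampled as noisy 50-Hz refraction
traces with a first-order response lag, sinusoidal accommodative
microfluctuations, slow drift and Poisson-scheduled blinks.

Ground truth (all responses relative to the orange pretrial):

* single LED at peak λ:  gain · (D(λ) − D(588 nm))
* mixture:               gain · (w·d_long + (1−w)·d_short)  with
  w = L_long^κ / (L_long^κ + L_short^κ)

κ = 1 gives plain luminance weighting; κ > 1 biases the blend toward the
more luminous primary, reproducing the long-wavelength bias of the observed
responses.  A switching variant draws each trial's response from one of the
two primaries instead, with logistic probability in the luminance split —
the behaviour the between-trial variance diagnostic is designed to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .optics import chromatic_defocus
from .spectra import LED_PRIMARIES, StimulusEntry
from .traces import DEFAULT_SAMPLE_RATE_HZ, RefractionTrace, TrialRecord

__all__ = [
    "SyntheticObserver",
    "SessionConfig",
    "PRESETS",
    "true_response",
    "simulate_session",
    "simulate_switching_observer",
    "fit_observer",
    "has_central_hump",
]

ORANGE_PEAK_UM = LED_PRIMARIES["orange"].peak_nm * 1e-3


@dataclass(frozen=True)
class SyntheticObserver:
    """Static response model plus trace-level noise parameters.

    gain
        fraction of the LCA demand difference actually accommodated (0–1);
        0.6 reflects the partial compensation observed at a 3-D viewing
        distance.
    bias_kappa
        long-wavelength weighting exponent for mixtures (≥ 1); 2 gives the
        not-quite-linear, longer-wavelength-biased blend.
    noise_sd_D
        per-sample measurement noise (D), photorefraction-typical 0.15.
    microfluct_amp_D, microfluct_hz
        sinusoidal accommodative microfluctuation (amplitude in D and its
        frequency); phase is randomized per session.
    blink_rate_hz, blink_dur_ms
        Poisson blink schedule; blinks mark pupil_found = False.
    drift_D_per_min
        slow linear session drift (head position, fatigue).
    response_tau_ms
        first-order lag of the accommodation step response.  200 ms leaves
        a residual transient below 1e-3 D inside the analysis windows while
        still exercising the settling-time exclusions.
    short_wavelength_noise
        optional scaling of the microfluctuation amplitude with the
        luminance fraction of the shorter-wavelength primary (off by 0).
    """

    gain: float = 0.6
    bias_kappa: float = 2.0
    noise_sd_D: float = 0.15
    microfluct_amp_D: float = 0.1
    microfluct_hz: float = 1.5
    blink_rate_hz: float = 0.25
    blink_dur_ms: float = 150.0
    drift_D_per_min: float = 0.05
    response_tau_ms: float = 200.0
    short_wavelength_noise: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gain <= 1.0):
            raise ValueError("gain must lie in [0, 1]")
        if self.bias_kappa < 1.0:
            raise ValueError("bias_kappa must be ≥ 1")
        for name in (
            "noise_sd_D",
            "microfluct_amp_D",
            "microfluct_hz",
            "blink_rate_hz",
            "blink_dur_ms",
            "drift_D_per_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SessionConfig:
    """Timing of one session: pretrial/trial durations and sampling."""

    pretrial_ms: float = 2500.0
    trial_ms: float = 2500.0
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ

    @property
    def trial_pair_ms(self) -> float:
        return self.pretrial_ms + self.trial_ms

    def session_duration_s(self, n_trials: int) -> float:
        return n_trials * self.trial_pair_ms / 1000.0


PRESETS: dict[str, SyntheticObserver] = {
    "default": SyntheticObserver(),
    "noiseless": SyntheticObserver(
        noise_sd_D=0.0,
        microfluct_amp_D=0.0,
        blink_rate_hz=0.0,
        drift_D_per_min=0.0,
    ),
    "switching": SyntheticObserver(),  # use with simulate_switching_observer
}


def _primary_demand(name: str, q) -> float:
    return chromatic_defocus(LED_PRIMARIES[name].peak_nm * 1e-3, q) - chromatic_defocus(
        ORANGE_PEAK_UM, q
    )


def true_response(
    observer: SyntheticObserver,
    entry: StimulusEntry,
    q=None,
) -> float:
    """Closed-form ground-truth static response for one stimulus entry."""
    from .optics import LCA_Q_DEFAULT

    q = q or LCA_Q_DEFAULT
    if len(entry.pair) == 1:
        return observer.gain * _primary_demand(entry.pair[0], q)
    if len(entry.pair) != 2:
        raise ValueError(f"unknown stimulus entry {entry.label!r}")
    d_long = _primary_demand(entry.pair[0], q)
    d_short = _primary_demand(entry.pair[1], q)
    k = observer.bias_kappa
    ll, ls = entry.lum_long, entry.lum_short
    w = ll**k / (ll**k + ls**k)
    return observer.gain * (w * d_long + (1.0 - w) * d_short)


def _short_fraction(entry: StimulusEntry) -> float:
    total = entry.lum_long + entry.lum_short
    return entry.lum_short / total if total > 0 else 0.0


def _simulate_segment(
    level_start: float,
    level_target: float,
    duration_ms: float,
    t_session_ms: float,
    observer: SyntheticObserver,
    cfg: SessionConfig,
    phase: float,
    rng: np.random.Generator,
    fluct_scale: float = 1.0,
) -> RefractionTrace:
    dt = 1000.0 / cfg.sample_rate_hz
    n = int(round(duration_ms / dt))
    t = np.arange(n) * dt
    tau = max(observer.response_tau_ms, 1e-9)
    level = level_target + (level_start - level_target) * np.exp(-t / tau)
    t_abs = t_session_ms + t
    fluct = (
        fluct_scale
        * observer.microfluct_amp_D
        * np.sin(2 * math.pi * observer.microfluct_hz * t_abs / 1000.0 + phase)
    )
    drift = observer.drift_D_per_min * t_abs / 60000.0
    noise = rng.normal(0.0, observer.noise_sd_D, n) if observer.noise_sd_D else 0.0
    refraction = level + fluct + drift + noise
    pupil = np.ones(n, dtype=bool)
    if observer.blink_rate_hz > 0:
        t_blink = 0.0
        while True:
            t_blink += rng.exponential(1000.0 / observer.blink_rate_hz)
            if t_blink >= duration_ms:
                break
            i0 = int(t_blink / dt)
            i1 = int((t_blink + observer.blink_dur_ms) / dt) + 1
            pupil[i0 : min(i1, n)] = False
    return RefractionTrace(t, refraction, pupil)


def _session_records(
    observer: SyntheticObserver,
    entries: list[StimulusEntry],
    cfg: SessionConfig,
    rng: np.random.Generator,
    target_fn,
    session_id: str,
    observer_id: str,
) -> list[TrialRecord]:
    order = rng.permutation(len(entries))
    phase = rng.uniform(0.0, 2 * math.pi)
    records = []
    level = 0.0  # accommodation state entering the session, relative to orange
    t_session = 0.0
    for idx in order:
        entry = entries[idx]
        target = target_fn(entry, rng)
        fl = 1.0 + observer.short_wavelength_noise * _short_fraction(entry)
        pre = _simulate_segment(
            level, 0.0, cfg.pretrial_ms, t_session, observer, cfg, phase, rng, fl
        )
        level_end_pre = 0.0 + (level - 0.0) * math.exp(
            -cfg.pretrial_ms / max(observer.response_tau_ms, 1e-9)
        )
        t_session += cfg.pretrial_ms
        tri = _simulate_segment(
            level_end_pre, target, cfg.trial_ms, t_session, observer, cfg, phase, rng, fl
        )
        level = target + (level_end_pre - target) * math.exp(
            -cfg.trial_ms / max(observer.response_tau_ms, 1e-9)
        )
        t_session += cfg.trial_ms
        records.append(
            TrialRecord(
                pretrial=pre,
                trial=tri,
                spectrum_label=entry.label,
                session_id=session_id,
                observer_id=observer_id,
            )
        )
    return records


def simulate_session(
    observer: SyntheticObserver,
    entries: list[StimulusEntry],
    seed: int,
    cfg: SessionConfig = SessionConfig(),
    session_id: str = "s0",
    observer_id: str = "o0",
) -> list[TrialRecord]:
    """One session: a pretrial+trial pair per stimulus in seeded-random order."""
    rng = np.random.default_rng(seed)

    def target(entry, _rng):
        return true_response(observer, entry)

    return _session_records(observer, entries, cfg, rng, target, session_id, observer_id)


def simulate_switching_observer(
    observer: SyntheticObserver,
    entries: list[StimulusEntry],
    seed: int,
    switch_sharpness: float = 8.0,
    cfg: SessionConfig = SessionConfig(),
    session_id: str = "s0",
    observer_id: str = "o0",
) -> list[TrialRecord]:
    """Session whose per-trial response is one primary or the other.

    For mixtures the long-wavelength primary's response is chosen with
    logistic probability p = σ(sharpness · (L_long − L_short) / L_total);
    infinite sharpness gives a hard switch at the equal-luminance split.
    Everything else matches :func:`simulate_session`.
    """
    rng = np.random.default_rng(seed)
    from .optics import LCA_Q_DEFAULT

    def target(entry, rng_):
        if len(entry.pair) == 1:
            return observer.gain * _primary_demand(entry.pair[0], LCA_Q_DEFAULT)
        d_long = observer.gain * _primary_demand(entry.pair[0], LCA_Q_DEFAULT)
        d_short = observer.gain * _primary_demand(entry.pair[1], LCA_Q_DEFAULT)
        x = (entry.lum_long - entry.lum_short) / (entry.lum_long + entry.lum_short)
        if math.isinf(switch_sharpness):
            p = 0.5 if x == 0 else (1.0 if x > 0 else 0.0)
        else:
            p = 1.0 / (1.0 + math.exp(-switch_sharpness * x))
        return d_long if rng_.random() < p else d_short

    return _session_records(observer, entries, cfg, rng, target, session_id, observer_id)


def fit_observer(
    mean_by_label: dict[str, float],
    entries: list[StimulusEntry],
) -> tuple[float, float]:
    """Least-squares re-fit of (gain, κ) from per-spectrum mean responses."""
    from scipy.optimize import least_squares

    ent = {e.label: e for e in entries}
    labels = [lab for lab in mean_by_label if lab in ent]
    y = np.array([mean_by_label[lab] for lab in labels])

    def resid(p):
        g, k = p
        obs = SyntheticObserver(gain=min(max(g, 0.0), 1.0), bias_kappa=max(k, 1.0))
        return np.array([true_response(obs, ent[lab]) for lab in labels]) - y

    sol = least_squares(resid, x0=[0.5, 1.5], bounds=([0.0, 1.0], [1.0, 10.0]))
    return float(sol.x[0]), float(sol.x[1])


def has_central_hump(
    variance_by_split: dict[float, float], min_excess_D2: float = 0.02
) -> bool:
    """Switching diagnostic on between-trial variances over luminance splits.

    True when the variance at the most even split exceeds the mean of the
    two extreme-split variances by ``min_excess_D2``.  The default excess
    (0.02 D²) sits an order of magnitude above the trial-to-trial variance
    a weighted-average observer shows at default noise, and well below the
    ≈0.1 D² bimodal variance a switching observer produces at 50/50.
    """
    splits = sorted(variance_by_split)
    if len(splits) < 3:
        raise ValueError("need at least three splits for the hump diagnostic")
    centre = min(splits, key=lambda s: abs(s - 5.0))
    v_c = variance_by_split[centre]
    v_ends = 0.5 * (variance_by_split[splits[0]] + variance_by_split[splits[-1]])
    return bool(v_c - v_ends > min_excess_D2)
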