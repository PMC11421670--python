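"""Autorefractor-trace cleaning, static responses and variance decomposition.

Mirrors the experiment's analysis of PowerRef-style refraction traces:

* samples where the pupil was not found are treated as blinks and excluded
  together with 80 ms before and 160 ms after;
* clearly erroneous refraction values (|refraction| > 20 D) are excluded;
* each 2.5-s trial is reduced to the mean over its final 1.5 s (the first
  1000 ms allow the response to settle), each 2.5-s orange pretrial to the
  mean over its final 1.0 s (first 1500 ms excluded);
* the static response is the trial mean minus the preceding pretrial mean,
  removing slow per-session offsets;
* per-spectrum within-trial variance (mean of per-trial sample variances)
  and between-trial variance (unbiased variance of the per-trial relative
  responses) separate moment-to-moment wobble from trial-to-trial switching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SAMPLE_RATE_HZ",
    "RefractionTrace",
    "TrialRecord",
    "StaticResponse",
    "clean_trace",
    "static_response",
    "variance_decomposition",
    "aggregate_responses",
    "spectrum_effect_tests",
    "session_to_frame",
    "session_from_frame",
]

DEFAULT_SAMPLE_RATE_HZ = 50.0

BLINK_PRE_MS = 80.0
BLINK_POST_MS = 160.0
REFRACTION_LIMIT_D = 20.0

TRIAL_EXCLUDE_MS = 1000.0
PRETRIAL_EXCLUDE_MS = 1500.0


@dataclass(frozen=True)
class RefractionTrace:
    """Uniformly sampled refraction measurements with pupil-found flags."""

    time_ms: np.ndarray
    refraction_D: np.ndarray
    pupil_found: np.ndarray
    excluded: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ms, dtype=float)
        r = np.asarray(self.refraction_D, dtype=float)
        p = np.asarray(self.pupil_found, dtype=bool)
        if t.ndim != 1 or t.shape != r.shape or t.shape != p.shape:
            raise ValueError("time, refraction and pupil arrays must match")
        d = np.diff(t)
        if t.size >= 2 and (np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6)):
            raise ValueError("trace must be uniformly sampled")
        if np.any(~np.isfinite(r[p])):
            raise ValueError("refraction must be finite where the pupil was found")
        ex = (
            np.zeros(t.shape, dtype=bool)
            if self.excluded is None
            else np.asarray(self.excluded, dtype=bool)
        )
        if ex.shape != t.shape:
            raise ValueError("exclusion mask must match the trace length")
        object.__setattr__(self, "time_ms", t)
        object.__setattr__(self, "refraction_D", r)
        object.__setattr__(self, "pupil_found", p)
        object.__setattr__(self, "excluded", ex)

    @property
    def sample_interval_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])

    @property
    def valid(self) -> np.ndarray:
        return ~self.excluded


@dataclass(frozen=True)
class TrialRecord:
    """A pretrial/trial trace pair labelled with its test spectrum."""

    pretrial: RefractionTrace
    trial: RefractionTrace
    spectrum_label: str
    session_id: str = ""
    observer_id: str = ""


@dataclass(frozen=True)
class StaticResponse:
    """Windowed means of one trial, normalised to its orange pretrial."""

    spectrum_label: str
    trial_mean_D: float
    pretrial_mean_D: float
    relative_D: float
    within_trial_variance_D2: float
    n_valid_samples: int
    session_id: str = ""
    observer_id: str = ""
    valid: bool = True


def clean_trace(trace: RefractionTrace) -> RefractionTrace:
    """Apply the blink and out-of-range exclusion rules.

    Missing-pupil runs are masked together with 80 ms before and 160 ms
    after (windows rounded outward to whole samples); |refraction| > 20 D
    samples are masked individually.  Idempotent.  An entirely masked trace
    is returned flagged, not raised.
    """
    dt = trace.sample_interval_ms
    pre = math.ceil(BLINK_PRE_MS / dt)
    post = math.ceil(BLINK_POST_MS / dt)
    blink = ~trace.pupil_found
    mask = blink.copy()
    idx = np.flatnonzero(blink)
    for i in idx:
        mask[max(0, i - pre) : i + post + 1] = True
    with np.errstate(invalid="ignore"):
        bad = np.abs(trace.refraction_D) > REFRACTION_LIMIT_D
    mask |= np.asarray(bad) & np.isfinite(trace.refraction_D)
    mask |= ~np.isfinite(trace.refraction_D)
    return RefractionTrace(
        trace.time_ms,
        trace.refraction_D,
        trace.pupil_found,
        mask | trace.excluded,
    )


def _window_mean(trace: RefractionTrace, exclude_ms: float) -> tuple[float, float, int]:
    """Mean, variance and count over valid samples after the settling window.

    The window starts ``exclude_ms`` after the segment's first timestamp.
    """
    t0 = trace.time_ms[0]
    keep = (trace.time_ms >= t0 + exclude_ms) & trace.valid
    vals = trace.refraction_D[keep]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan"), float("nan"), 0
    var = float(np.var(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), var, int(vals.size)


def static_response(record: TrialRecord, cleaned: bool = False) -> StaticResponse:
    """Trial mean (final 1500 ms) minus pretrial mean (final 1000 ms).

    Traces are cleaned first unless ``cleaned=True``.  Masked samples are
    excluded from all statistics (no interpolation).  A trial with no valid
    samples in either window is returned flagged invalid.
    """
    pre = record.pretrial if cleaned else clean_trace(record.pretrial)
    tri = record.trial if cleaned else clean_trace(record.trial)
    pre_mean, _, n_pre = _window_mean(pre, PRETRIAL_EXCLUDE_MS)
    tri_mean, tri_var, n_tri = _window_mean(tri, TRIAL_EXCLUDE_MS)
    ok = n_pre > 0 and n_tri > 0
    return StaticResponse(
        spectrum_label=record.spectrum_label,
        trial_mean_D=tri_mean,
        pretrial_mean_D=pre_mean,
        relative_D=tri_mean - pre_mean if ok else float("nan"),
        within_trial_variance_D2=tri_var,
        n_valid_samples=n_tri,
        session_id=record.session_id,
        observer_id=record.observer_id,
        valid=ok,
    )


def variance_decomposition(responses: Iterable[StaticResponse]) -> pd.DataFrame:
    """Within- and between-trial variance per spectrum.

    ``within`` is the mean of the per-trial sample variances; ``between``
    the unbiased (n−1) variance of per-trial relative responses, undefined
    (NaN, flagged) with fewer than two valid trials.
    """
    rows = []
    frame = pd.DataFrame(
        [
            {
                "spectrum_label": r.spectrum_label,
                "relative_D": r.relative_D,
                "within": r.within_trial_variance_D2,
                "valid": r.valid,
            }
            for r in responses
        ]
    )
    for label, g in frame[frame.valid].groupby("spectrum_label", sort=False):
        n = len(g)
        rows.append(
            {
                "spectrum_label": label,
                "n_trials": n,
                "within_trial_variance_D2": float(g["within"].mean()),
                "between_trial_variance_D2": float(g["relative_D"].var(ddof=1))
                if n >= 2
                else float("nan"),
                "between_defined": n >= 2,
            }
        )
    return pd.DataFrame(rows)


def aggregate_responses(responses: Iterable[StaticResponse]) -> pd.DataFrame:
    """Grand mean and SEM across observers of per-observer mean responses.

    Each observer contributes one mean per spectrum; the SEM is across
    observers and undefined (NaN, flagged) for a single observer.
    """
    frame = pd.DataFrame(
        [
            {
                "spectrum_label": r.spectrum_label,
                "observer_id": r.observer_id,
                "relative_D": r.relative_D,
            }
            for r in responses
            if r.valid
        ]
    )
    per_obs = (
        frame.groupby(["spectrum_label", "observer_id"], sort=False)["relative_D"]
        .mean()
        .reset_index()
    )
    rows = []
    for label, g in per_obs.groupby("spectrum_label", sort=False):
        n = len(g)
        rows.append(
            {
                "spectrum_label": label,
                "n_observers": n,
                "mean_relative_D": float(g["relative_D"].mean()),
                "sem_D": float(g["relative_D"].std(ddof=1) / math.sqrt(n))
                if n >= 2
                else float("nan"),
                "sem_defined": n >= 2,
            }
        )
    return pd.DataFrame(rows)


def spectrum_effect_tests(
    responses: Iterable[StaticResponse],
    labels_by_pair: Mapping[tuple[str, str], Sequence[str]],
) -> pd.DataFrame:
    """Per-pair one-way ANOVA and Levene tests over luminance ratio.

    Delegated to scipy.stats; these standard tests are reported, not
    re-derived.  ``labels_by_pair`` maps each LED pair to its spectrum
    labels in split order.
    """
    from scipy import stats

    frame = pd.DataFrame(
        [
            {"spectrum_label": r.spectrum_label, "relative_D": r.relative_D}
            for r in responses
            if r.valid
        ]
    )
    rows = []
    for pair, labels in labels_by_pair.items():
        groups = [
            frame.loc[frame.spectrum_label == lab, "relative_D"].to_numpy()
            for lab in labels
        ]
        groups = [g for g in groups if g.size >= 2]
        if len(groups) < 2:
            continue
        f_stat, f_p = stats.f_oneway(*groups)
        l_stat, l_p = stats.levene(*groups)
        rows.append(
            {
                "pair": "-".join(pair),
                "anova_F": float(f_stat),
                "anova_p": float(f_p),
                "levene_W": float(l_stat),
                "levene_p": float(l_p),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV round-trip


def session_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Flatten a session to time_ms,refraction_D,pupil_found rows with
    trial/segment labels (long format, one file per session)."""
    rows = []
    for i, rec in enumerate(records):
        for segment, tr in (("pretrial", rec.pretrial), ("trial", rec.trial)):
            for t, r, p in zip(tr.time_ms, tr.refraction_D, tr.pupil_found):
                rows.append(
                    (i, rec.spectrum_label, segment, t, r, int(p), rec.session_id, rec.observer_id)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "trial_index",
            "spectrum_label",
            "segment",
            "time_ms",
            "refraction_D",
            "pupil_found",
            "session_id",
            "observer_id",
        ],
    )


def session_from_frame(frame: pd.DataFrame) -> list[TrialRecord]:
    records = []
    for idx, g in frame.groupby("trial_index", sort=True):
        segs = {}
        label = str(g["spectrum_label"].iloc[0])
        for segment, sg in g.groupby("segment", sort=False):
            segs[segment] = RefractionTrace(
                sg["time_ms"].to_numpy(float),
                sg["refraction_D"].to_numpy(float),
                sg["pupil_found"].to_numpy().astype(bool),
            )
        records.append(
            TrialRecord(
                pretrial=segs["pretrial"],
                trial=segs["trial"],
                spectrum_label=label,
                session_id=str(g["session_id"].iloc[0]),
                observer_id=str(g["observer_id"].iloc[0]),
            )
        )
    return records
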