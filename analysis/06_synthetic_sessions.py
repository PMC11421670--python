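#!/usr/bin/env python
"""Simulate PowerRef-style sessions for a synthetic cohort.

Five weighted-average observers (gain 0.6, long-wavelength bias κ = 2) each
complete 12 sessions of the 47-spectrum protocol at default noise, plus one
switching observer for the variance diagnostic.  Traces are written as
per-session CSVs with the generator's ground truth alongside.
"""

import json
from pathlib import Path

from chromacc.spectra import ReferenceCurves, generate_experiment_set
from chromacc.synth import PRESETS, simulate_session, simulate_switching_observer, true_response
from chromacc.traces import session_to_frame

OUT = Path(__file__).resolve().parents[1] / "results" / "sessions"
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    entries = generate_experiment_set(ReferenceCurves())
    obs = PRESETS["default"]
    n = 0
    for o in range(5):
        for s in range(12):
            recs = simulate_session(
                obs, entries, seed=SEED + o * 100 + s,
                session_id=f"s{s}", observer_id=f"o{o}",
            )
            session_to_frame(recs).to_csv(OUT / f"obs{o}_session{s:02d}.csv", index=False)
            n += 1
    rb = [e for e in entries if e.pair == ("red", "blue")]
    for s in range(12):
        recs = simulate_switching_observer(
            obs, rb, seed=SEED + 9000 + s, session_id=f"s{s}", observer_id="switcher",
        )
        session_to_frame(recs).to_csv(OUT / f"switcher_session{s:02d}.csv", index=False)
        n += 1
    truth = {e.label: true_response(obs, e) for e in entries}
    (OUT / "ground_truth.json").write_text(
        json.dumps({"seed": SEED, "gain": obs.gain, "kappa": obs.bias_kappa,
                    "truth_D": truth}, indent=2)
    )
    print(f"wrote {n} session CSVs to {OUT}")


if __name__ == "__main__":
    main()
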