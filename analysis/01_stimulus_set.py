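#!/usr/bin/env python
"""Build the 47-spectrum stimulus set and the LED demand table.

Five narrowband LEDs (red 660 / orange 588 / green 527 / blue 461 /
violet 441 nm) are paired six ways; each pair is mixed at seven luminance
splits (1.25 … 8.75 cd/m² in 1.25 steps) at a constant 10 cd/m² total,
giving 42 mixtures plus the five single LEDs.  Writes the set in long
format plus each LED's accommodation demand relative to 580 nm.
"""

from pathlib import Path

from chromacc.spectra import ReferenceCurves, generate_experiment_set, stimulus_set_to_frame
from chromacc.workbench import demand_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    curves = ReferenceCurves()
    entries = generate_experiment_set(curves)
    frame = stimulus_set_to_frame(entries)
    frame.to_csv(OUT / "stimulus_set.csv", index=False)
    demands = demand_table()
    demands.to_csv(OUT / "led_demands.csv", index=False)
    n_mix = sum(1 for e in entries if len(e.pair) == 2)
    print(f"stimulus set: {len(entries)} spectra ({n_mix} mixtures + "
          f"{len(entries) - n_mix} single LEDs)")
    print(demands.to_string(index=False, float_format=lambda x: f"{x:+.3f}"))


if __name__ == "__main__":
    main()
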