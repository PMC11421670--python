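#!/usr/bin/env python
"""Through-focus image-quality sweeps for red-blue mixtures.

For nine luminance splits from completely red to completely blue, sweeps
visual Strehl and single-frequency contrast (2/4/8/16 cpd) in the luminance
channel, plus L- and M-cone visual Strehl, over −1.5…+1.5 D (relative to
580 nm) with a 5-mm pupil.  The headline structure: VSR shows two separate
peaks (one per primary demand) whose relative height tracks the luminance
ratio, while 2-cpd contrast collapses to a single peak that glides between
the demands.
"""

from pathlib import Path

import numpy as np

from chromacc.spectra import ReferenceCurves
from chromacc.workbench import RunConfig, reproduce_sweep_figures

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = RunConfig(pupil_mm=5.0, grid_n=256)
    cfg.echo(OUT)
    frame = reproduce_sweep_figures(cfg, ReferenceCurves(), pair=("red", "blue"))
    frame.to_csv(OUT / "sweeps_red-blue.csv", index=False)

    even = frame[(frame.lum_long == 5.0) & (frame.metric == "vsr")
                 & (frame.channel == "luminance")]
    v = even.value.to_numpy()
    g = even.defocus_D.to_numpy()
    peaks = [g[i] for i in range(1, v.size - 1)
             if v[i] > v[i - 1] and v[i] >= v[i + 1] and v[i] > 0.5 * v.max()]
    print(f"wrote {OUT / 'sweeps_red-blue.csv'} ({len(frame)} rows)")
    print(f"50/50 red-blue VSR peaks at {[f'{p:+.2f} D' for p in peaks]} "
          "(red demand +0.31 D, blue demand -0.83 D)")


if __name__ == "__main__":
    main()
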