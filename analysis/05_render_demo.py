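#!/usr/bin/env python
"""Two-wavelength retinal rendering demo (460 + 530 nm Maltese crosses).

Renders the cross as seen through the model eye when focused on the
460-nm component versus focused midway between the two wavelengths'
demands, and compares fine-detail (8–16 cpd) spectral power.  Focusing on
one wavelength keeps more high-frequency content in the summed image than
splitting the difference — the qualitative reason image-quality
maximization predicts accommodation at one primary.
"""

from pathlib import Path

import imageio.v3 as iio
import pandas as pd

from chromacc.imaging import octave_band_power, two_wavelength_demo
from chromacc.optics import EyeModel
from chromacc.spectra import ReferenceCurves

OUT = Path(__file__).resolve().parents[1] / "results" / "render_demo"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    images = two_wavelength_demo(EyeModel(), ReferenceCurves(), resolution=256)
    rows = []
    for (focus, comp), img in images.items():
        arr = img.pixels / img.pixels.max()
        iio.imwrite(OUT / f"{focus}_{comp}.png", (arr * 255).astype("uint8"))
        hf = octave_band_power(img, [(8, 16)])[0]
        rows.append({"focus": focus, "component": comp, "power_8_16cpd": hf})
    stats = pd.DataFrame(rows)
    stats.to_csv(OUT / "power_stats.csv", index=False)
    piv = stats.pivot(index="component", columns="focus", values="power_8_16cpd")
    print(piv.to_string(float_format=lambda x: f"{x:.3g}"))
    gain = piv.loc["sum", "short"] / piv.loc["sum", "mid"]
    print(f"summed-image fine-detail power, focus-on-460 vs focus-midway: ×{gain:.2f}")


if __name__ == "__main__":
    main()
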