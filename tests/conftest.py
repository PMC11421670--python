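import numpy as np
import pytest

from chromacc.optics import EyeModel, GridConfig, build_otf_library
from chromacc.rules import DEFAULT_SWEEP_GRID
from chromacc.spectra import ReferenceCurves, generate_experiment_set


@pytest.fixture(scope="session")
def curves():
    return ReferenceCurves()


@pytest.fixture(scope="session")
def experiment_set(curves):
    return generate_experiment_set(curves)


@pytest.fixture(scope="session")
def lib5(curves):
    """Radial OTF library, 5-mm pupil (experiment reproductions)."""
    return build_otf_library(
        EyeModel(pupil_diameter_mm=5.0), GridConfig(n=256), DEFAULT_SWEEP_GRID
    )


@pytest.fixture(scope="session")
def lib6(curves):
    """Radial OTF library, 6-mm pupil (D65 daylight comparison)."""
    return build_otf_library(
        EyeModel(pupil_diameter_mm=6.0), GridConfig(n=256), DEFAULT_SWEEP_GRID
    )
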