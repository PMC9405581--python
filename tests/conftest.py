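import numpy as np
import pytest

from ppgforge.features import detect_fiducials
from ppgforge.tissue import LayerSpec, TissueModel, LAYER_NAMES
from ppgforge.waveform import AGE_TEMPLATES, synthesize_record


@pytest.fixture(scope="session")
def control_records():
    """Clean control records (no noise, no filter) for the four age templates."""
    return {
        age: synthesize_record(params, hr=75.0, fs=120.0, duration=30.0, ac=1.0, dc=0.0)
        for age, params in AGE_TEMPLATES.items()
    }


@pytest.fixture(scope="session")
def control_fiducials(control_records):
    return {age: detect_fiducials(rec, 75.0) for age, rec in control_records.items()}


def uniform_slab(mua: float, mus: float, total_mm: float, g: float = 0.0, n: float = 1.0) -> TissueModel:
    """Six equal layers with identical optics: an effectively homogeneous slab."""
    t = total_mm / 6
    layers = tuple(
        LayerSpec(name, t, i * t, mua, mus, g=g, n=n)
        for i, name in enumerate(LAYER_NAMES)
    )
    return TissueModel(layers, age=30.0, vfm=0.0, wavelength=515.0, state="rest", n_ambient=1.0)
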