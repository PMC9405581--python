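"""Six-layer optical model of the volar fingertip.

The model stacks, from the surface down: epidermis, papillary dermis, upper
blood net dermis, reticular dermis, deep blood net dermis, and subcutaneous
fat.  Geometry and optical coefficients depend on three subject/device
factors:

* **age** — total dermal thickness thins linearly with age (anchored at
  0.75 mm for a 61-year-old, 0.0044 mm per year), split into the four
  dermal sublayers by fixed volume fractions; vessel compliance (the
  systolic blood-volume surge) also declines with age.
* **volume fraction melanosomes (VFM)** — the epidermal absorption
  coefficient is a linear mixture of melanosome absorption,
  ``mua_mel(lambda) = 6.6e10 * lambda**-3.33`` (cm^-1, lambda in nm), and a
  melanin-free baseline back-solved from the tabulated VFM = 0.03 value, so
  the tabulated constants remain authoritative.
* **wavelength** — scattering and baseline absorption are tabulated at
  515, 660 and 880 nm.

A cardiac pulse is represented by a second model ("pulse" state) in which
only the four dermal sublayers' absorption is raised, reflecting the extra
oxygenated blood at the systolic peak.  The tabulated pulsed coefficients
correspond to the youngest (23-year-old) subject, whose blood-volume surge
is 1.124x; for other ages the blood-borne part of the absorption increment
is rescaled by the age-specific surge factor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import numpy as np

__all__ = [
    "LayerSpec",
    "TissueModel",
    "LAYER_NAMES",
    "SUBLAYER_NAMES",
    "load_constants",
    "dermal_sublayer_thicknesses",
    "epidermal_mua",
    "melanosome_mua",
    "pulse_blood_factor",
    "build_tissue_model",
]

LAYER_NAMES = (
    "epidermis",
    "papillary_dermis",
    "upper_blood_net",
    "reticular_dermis",
    "deep_blood_net",
    "subcutis",
)
#: the four dermal sublayers whose absorption pulsates
SUBLAYER_NAMES = LAYER_NAMES[1:5]

State = Literal["rest", "pulse"]

_CONSTANTS = None


def load_constants() -> dict:
    """Load the tabulated optical/geometric constants (cached)."""
    global _CONSTANTS
    if _CONSTANTS is None:
        with resources.files(__package__).joinpath("data/optical_constants.json").open() as fh:
            _CONSTANTS = json.load(fh)
    return _CONSTANTS


@dataclass(frozen=True)
class LayerSpec:
    """One homogeneous tissue layer.

    Thickness and depth are in mm; ``mua``/``mus`` in cm^-1; ``g`` is the
    scattering anisotropy and ``n`` the refractive index.
    """

    name: str
    thickness: float
    start_depth: float
    mua: float
    mus: float
    g: float = 0.9
    n: float = 1.4

    def __post_init__(self) -> None:
        if self.name not in LAYER_NAMES:
            raise ValueError(f"unknown layer name {self.name!r}")
        if self.thickness <= 0:
            raise ValueError("layer thickness must be positive")
        if self.mua < 0 or self.mus < 0:
            raise ValueError("optical coefficients must be non-negative")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError("anisotropy g must lie in [-1, 1]")


@dataclass(frozen=True)
class TissueModel:
    """Ordered six-layer model for one (age, VFM, wavelength, state)."""

    layers: tuple[LayerSpec, ...]
    age: float
    vfm: float
    wavelength: float
    state: State
    n_ambient: float = 1.0

    def __post_init__(self) -> None:
        if len(self.layers) != 6:
            raise ValueError("a TissueModel has exactly six layers")
        if tuple(l.name for l in self.layers) != LAYER_NAMES:
            raise ValueError("layers out of order")
        depth = 0.0
        for l in self.layers:
            if abs(l.start_depth - depth) > 1e-9:
                raise ValueError("layers are not contiguous")
            depth += l.thickness

    @property
    def total_thickness(self) -> float:
        """Total model depth in mm."""
        return sum(l.thickness for l in self.layers)

    def layer_arrays(self) -> dict[str, np.ndarray]:
        """Layer properties as arrays (thickness in cm) for the transport kernels."""
        return {
            "thickness_cm": np.array([l.thickness for l in self.layers]) / 10.0,
            "mua": np.array([l.mua for l in self.layers]),
            "mus": np.array([l.mus for l in self.layers]),
            "g": np.array([l.g for l in self.layers]),
        }


def dermal_sublayer_thicknesses(age: float) -> dict[str, float]:
    """Thickness (mm) of the four dermal sublayers at a given age.

    Total dermal thickness follows the linear thinning model
    ``0.75 mm + (61 - age) * 0.0044 mm`` and is partitioned into the
    papillary dermis (8.2%), upper blood net (4.37%), reticular dermis
    (81.97%) and deep blood net (5.46%).
    """
    c = load_constants()["dermis"]
    lo, hi = c["total_thickness_model"]["age_range_years"]
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside supported range [{lo}, {hi}] years")
    m = c["total_thickness_model"]
    total = m["anchor_thickness_mm"] + (m["anchor_age_years"] - age) * m["thinning_mm_per_year"]
    return {name: frac * total for name, frac in c["sublayer_fractions"].items()}


def melanosome_mua(wavelength: float) -> float:
    """Absorption coefficient (cm^-1) of pure melanosome interior."""
    m = load_constants()["epidermis"]["melanosome_mua"]
    return m["amplitude"] * float(wavelength) ** -m["exponent"]


def _baseline_mua(wavelength: float) -> float:
    # melanin-free epidermal baseline, back-solved from the VFM = 0.03 cell
    cells = load_constants()["epidermis"]["mua_vfm_cells"]
    key = str(int(wavelength))
    if key not in cells:
        raise ValueError(
            f"wavelength {wavelength} nm is not tabulated (tabulated: 515, 660, 880); "
            "pass extrapolate=True to epidermal_mua to interpolate the baseline"
        )
    v0 = cells["vfm"][0]
    return (cells[key][0] - v0 * melanosome_mua(wavelength)) / (1.0 - v0)


def epidermal_mua(wavelength: float, vfm: float, *, extrapolate: bool = False) -> float:
    """Epidermal absorption coefficient (cm^-1) for a melanosome fraction.

    Linear mixture ``vfm * mua_mel + (1 - vfm) * mua_base`` with the
    baseline calibrated per wavelength to the tabulated VFM = 0.03 cell.
    With ``extrapolate`` the baseline is interpolated (log-linearly) between
    the tabulated wavelengths.
    """
    if not 0.0 <= vfm <= 1.0:
        raise ValueError("vfm must lie in [0, 1]")
    cells = load_constants()["epidermis"]["mua_vfm_cells"]
    key = str(int(wavelength))
    if key in cells and float(int(wavelength)) == float(wavelength):
        base = _baseline_mua(wavelength)
    elif extrapolate:
        lams = np.array([515.0, 660.0, 880.0])
        bases = np.log([_baseline_mua(l) for l in lams])
        base = float(np.exp(np.interp(np.log(wavelength), np.log(lams), bases)))
    else:
        raise ValueError(
            f"wavelength {wavelength} nm is not tabulated; pass extrapolate=True"
        )
    return vfm * melanosome_mua(wavelength) + (1.0 - vfm) * base


def pulse_blood_factor(age: float) -> float:
    """Systolic blood-volume multiplier (>= 1) for the dermal sublayers.

    Tabulated at ages 23, 34.4, 44.8 and 55 (1.124 down to 1.073, the
    decline reflecting stiffening vessels); linearly interpolated between
    anchors and clamped (with a warning) outside them.
    """
    c = load_constants()["pulse_blood_factors"]
    ages, factors = np.asarray(c["ages"]), np.asarray(c["factors"])
    if age < ages[0] or age > ages[-1]:
        warnings.warn(
            f"age {age} outside tabulated pulse-factor span [{ages[0]}, {ages[-1]}]; "
            "clamping to the nearest anchor",
            stacklevel=2,
        )
    return float(np.interp(age, ages, factors))


def _mus_defaults() -> dict:
    return load_constants()["defaults"]


def build_tissue_model(
    age: float,
    vfm: float,
    wavelength: float,
    state: State = "rest",
    *,
    g: float | None = None,
    n_tissue: float | None = None,
    n_ambient: float | None = None,
    extrapolate: bool = False,
) -> TissueModel:
    """Assemble the six-layer model for one parameter combination.

    ``state="pulse"`` raises only the four dermal sublayers' absorption.
    The tabulated pulsed coefficients are anchored at age 23 (surge factor
    1.124); for other ages the blood-borne increment is rescaled by
    ``(pulse_blood_factor(age) - 1) / (1.124 - 1)``.
    """
    if state not in ("rest", "pulse"):
        raise ValueError("state must be 'rest' or 'pulse'")
    c = load_constants()
    key = str(int(wavelength))
    if key not in c["dermis"]["mus"]:
        raise ValueError(
            f"wavelength {wavelength} nm is not tabulated (515/660/880 only)"
        )
    d = c["defaults"]
    g = d["anisotropy_g"] if g is None else g
    n_tissue = d["refractive_index_tissue"] if n_tissue is None else n_tissue
    n_ambient = d["refractive_index_ambient"] if n_ambient is None else n_ambient

    sub = dermal_sublayer_thicknesses(age)
    anchor = c["pulse_blood_factors"]["factors"][0]  # 1.124 at the age-23 anchor
    scale = (pulse_blood_factor(age) - 1.0) / (anchor - 1.0)

    layers: list[LayerSpec] = []
    depth = 0.0

    def add(name: str, thickness: float, mua: float, mus: float) -> None:
        nonlocal depth
        layers.append(
            LayerSpec(name, thickness, depth, mua, mus, g=g, n=n_tissue)
        )
        depth += thickness

    epi = c["epidermis"]
    add("epidermis", epi["thickness_mm"], epidermal_mua(wavelength, vfm, extrapolate=extrapolate), epi["mus"][key])
    derm = c["dermis"]
    for name in SUBLAYER_NAMES:
        mua_rest = derm["mua_rest"][name][key]
        if state == "pulse":
            delta = derm["mua_pulsed"][name][key] - mua_rest
            mua = mua_rest + delta * scale
        else:
            mua = mua_rest
        add(name, sub[name], mua, derm["mus"][key])
    sc = c["subcutis"]
    add("subcutis", sc["thickness_mm"], sc["mua"][key], sc["mus"][key])

    return TissueModel(tuple(layers), age, vfm, wavelength, state, n_ambient=n_ambient)
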