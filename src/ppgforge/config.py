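"""Run configuration and parameter-grid expansion.

A :class:`RunConfig` captures every knob of the pipeline — the factorial
(age, VFM, wavelength) grid, Monte Carlo settings, waveform synthesis,
device chain and feature extraction — plus the master seed, so a single
config + seed reproduces a run end to end.  The default values are the
study grid: 4 ages x 4 melanosome fractions x 3 wavelengths = 48
combinations, each simulated in rest and pulse states (96 runs).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig", "expand_grid", "load_config", "save_config"]


@dataclass
class RunConfig:
    ages: list[float] = field(default_factory=lambda: [23.0, 34.4, 44.8, 55.0])
    vfms: list[float] = field(default_factory=lambda: [0.03, 0.10, 0.20, 0.30])
    wavelengths: list[float] = field(default_factory=lambda: [515.0, 660.0, 880.0])
    # Monte Carlo
    mc_photons: int = 1_000_000
    mc_target_cv: float = 0.10
    master_seed: int = 0
    detector: str = "default"  # "default" (verbatim radii) or "alternative"
    # waveform
    hr: float = 75.0
    fs: float = 120.0
    duration: float = 30.0
    noise: bool = True
    # device
    filter_id: int = 4
    adc_bits: int = 10
    reference_current: float = 32e-6
    led_power: float = 0.05
    # features
    p_grid: list[int] = field(default_factory=lambda: [10, 25, 33, 50, 66, 75])
    out_dir: str = "ppgforge_out"

    def __post_init__(self) -> None:
        for name in ("ages", "vfms", "wavelengths"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")
        if self.master_seed is None:
            raise ValueError("a master seed is required (no silent nondeterminism)")

    def config_hash(self) -> str:
        """Stable short hash of the full configuration, for run logs."""
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def expand_grid(config: RunConfig) -> tuple[list[tuple[float, float, float]], int]:
    """Full factorial (age, vfm, wavelength) combinations and the MC run count.

    Each combination needs one rest and one pulse simulation, so the run
    count is twice the number of combinations (96 for the default grid).
    """
    combos = [
        (a, v, w)
        for a in config.ages
        for v in config.vfms
        for w in config.wavelengths
    ]
    if not combos:
        raise ValueError("empty parameter grid")
    return combos, 2 * len(combos)


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def save_config(config: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
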