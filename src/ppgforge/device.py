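"""Device-side signal chain: filters, ADC quantization, rescaling.

Three filter chains bracket realistic wearable processing, plus a no-op
control:

1. 0.1–7 Hz 4th-order Butterworth bandpass;
2. 0.1–7 Hz 4th-order inverse Chebyshev (type II) bandpass followed by a
   10-sample moving average;
3. 7 Hz 4th-order inverse Chebyshev lowpass followed by a 10-sample moving
   average;
4. none (control: no noise, no filter).

All filtering is causal (forward-only), matching on-device processing; the
moving average is a trailing window.  The type II stopband attenuation is
not device-specified and defaults to 40 dB.

The ADC maps a detected-fraction signal to integer codes:

    photocurrent  i = 10 * value * LED_power * photodiode_area
    code            = floor(i * 2^bits / reference_current), saturated
    reconstruction  = code * reference_current / 2^bits

with the study defaults of a 32 uA reference current and 50 mW LED power.
The default photodiode area is the annular detector area.  Finally, all
records from one parameter combination are jointly rescaled to the range
0.5–2.7 expected by the downstream feature/regression stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

from .transport import DetectorSpec
from .waveform import PPGRecord

__all__ = [
    "FilterSpec",
    "ADCSpec",
    "FILTER_PRESETS",
    "apply_filter",
    "adc_convert",
    "resolution_sweep",
    "rescale_group",
]

RESCALE_RANGE = (0.5, 2.7)


@dataclass(frozen=True)
class FilterSpec:
    """One of the device filter chains."""

    id: str = "none"  # butter_bp | cheby2_bp_ma | cheby2_lp_ma | none
    order: int = 4
    band: tuple[float, ...] = (0.1, 7.0)  # Hz; (low, high) or (cutoff,)
    ma_window: int = 10  # samples, trailing
    stopband_db: float = 40.0

    def __post_init__(self) -> None:
        if self.id not in ("butter_bp", "cheby2_bp_ma", "cheby2_lp_ma", "none"):
            raise ValueError(f"unknown filter id {self.id!r}")
        if len(self.band) == 2 and not self.band[0] < self.band[1]:
            raise ValueError("bandpass requires low < high")
        if self.ma_window < 1:
            raise ValueError("moving-average window must be >= 1")


#: the study's numbered filters (4 = control)
FILTER_PRESETS: dict[int, FilterSpec] = {
    1: FilterSpec("butter_bp", band=(0.1, 7.0)),
    2: FilterSpec("cheby2_bp_ma", band=(0.1, 7.0)),
    3: FilterSpec("cheby2_lp_ma", band=(7.0,)),
    4: FilterSpec("none"),
}


@dataclass(frozen=True)
class ADCSpec:
    """Analog-to-digital conversion settings."""

    resolution: int = 10  # bits
    reference_current: float = 32e-6  # amperes
    led_power: float = 0.05  # watts
    photodiode_area: float | None = None  # cm^2; default: annular detector area

    def __post_init__(self) -> None:
        if not 1 <= self.resolution <= 32:
            raise ValueError("resolution must be 1..32 bits")
        if self.reference_current <= 0 or self.led_power <= 0:
            raise ValueError("reference current and LED power must be positive")
        if self.photodiode_area is not None and self.photodiode_area <= 0:
            raise ValueError("photodiode area must be positive")

    @property
    def area_cm2(self) -> float:
        if self.photodiode_area is not None:
            return self.photodiode_area
        return DetectorSpec().area_cm2


def _sos(spec: FilterSpec, fs: float) -> np.ndarray:
    nyq = fs / 2
    if any(f >= nyq for f in spec.band):
        raise ValueError(f"filter band edge {max(spec.band)} Hz >= Nyquist {nyq} Hz")
    if spec.id == "butter_bp":
        return sps.butter(spec.order, spec.band, btype="bandpass", fs=fs, output="sos")
    if spec.id == "cheby2_bp_ma":
        return sps.cheby2(spec.order, spec.stopband_db, spec.band, btype="bandpass", fs=fs, output="sos")
    if spec.id == "cheby2_lp_ma":
        return sps.cheby2(spec.order, spec.stopband_db, spec.band[0], btype="lowpass", fs=fs, output="sos")
    raise AssertionError(spec.id)


def apply_filter(record: PPGRecord, spec: FilterSpec) -> PPGRecord:
    """Apply one device filter chain, causally.

    The IIR stage runs first; for the ``*_ma`` chains a trailing
    ``ma_window``-sample moving average follows.  ``id="none"`` is the
    identity (the control condition).
    """
    if spec.id == "none":
        return record.copy_with(record.samples, filter="none")
    y = sps.sosfilt(_sos(spec, record.fs), record.samples)
    if spec.id.endswith("_ma"):
        kernel = np.ones(spec.ma_window) / spec.ma_window
        y = sps.lfilter(kernel, [1.0], y)
    return record.copy_with(y, filter=spec.id)


def adc_convert(record: PPGRecord, spec: ADCSpec) -> PPGRecord:
    """Quantize a detected-fraction record through the simulated ADC.

    Returns a record whose samples are the reconstructed amplitudes
    (code * reference / 2^bits, ampere units); the integer codes and a
    saturation flag are stored in the metadata.
    """
    area = spec.area_cm2
    current = 10.0 * record.samples * spec.led_power * area
    full_scale = 2**spec.resolution
    codes = np.floor(current * full_scale / spec.reference_current)
    saturated = bool((current > spec.reference_current).any() or (codes < 0).any())
    codes = np.clip(codes, 0, full_scale - 1).astype(np.int64)
    recon = codes * (spec.reference_current / full_scale)
    return record.copy_with(
        recon,
        adc={
            "resolution": spec.resolution,
            "reference_current": spec.reference_current,
            "led_power": spec.led_power,
            "photodiode_area": area,
            "saturated": saturated,
        },
        adc_codes=codes,
    )


def resolution_sweep(
    record: PPGRecord,
    bits_range: Iterable[int],
    reference_bits: int = 25,
    *,
    adc: ADCSpec | None = None,
    filter_spec: FilterSpec | None = None,
    order: str = "filter_then_adc",
) -> dict[int, float]:
    """Median percent difference of each ADC resolution against a 25-bit reference.

    For each bits value the same processing (optionally a filter) is applied
    to both the test and the reference conversion and the median of
    ``|x_b - x_ref| / |x_ref| * 100`` over samples is reported — the
    suggested methodology for choosing a sufficient ADC resolution.
    ``order`` selects filter-then-ADC (as described for the study's traces)
    or ADC-then-filter.
    """
    if order not in ("filter_then_adc", "adc_then_filter"):
        raise ValueError("order must be 'filter_then_adc' or 'adc_then_filter'")
    base = adc or ADCSpec()

    def process(bits: int) -> np.ndarray:
        spec = ADCSpec(bits, base.reference_current, base.led_power, base.photodiode_area)
        r = record
        if order == "filter_then_adc":
            if filter_spec is not None:
                r = apply_filter(r, filter_spec)
            return adc_convert(r, spec).samples
        r = adc_convert(r, spec)
        if filter_spec is not None:
            r = apply_filter(r, filter_spec)
        return r.samples

    ref = process(reference_bits)
    nz = ref != 0
    if not nz.any():
        raise ValueError("reference conversion is identically zero")
    out = {}
    for bits in bits_range:
        x = process(int(bits))
        out[int(bits)] = float(np.median(np.abs(x[nz] - ref[nz]) / np.abs(ref[nz])) * 100.0)
    return out


def rescale_group(records: Sequence[PPGRecord]) -> list[PPGRecord]:
    """Affinely rescale all records of one parameter combination to [0.5, 2.7].

    The joint minimum maps to 0.5 and the joint maximum to 2.7; rank order
    of samples is preserved.
    """
    if not records:
        raise ValueError("empty record group")
    lo = min(r.samples.min() for r in records)
    hi = max(r.samples.max() for r in records)
    if hi == lo:
        raise ValueError("constant record group cannot be rescaled")
    a, b = RESCALE_RANGE
    scale = (b - a) / (hi - lo)
    return [
        r.copy_with(a + (r.samples - lo) * scale, rescaled=list(RESCALE_RANGE))
        for r in records
    ]
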