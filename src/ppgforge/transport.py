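"""Monte Carlo photon transport for the layered fingertip model.

The geometry is a stack of laterally infinite slabs illuminated by a square
LED-type emitter (top-hat near field, Lambertian far field, half angle
clamped to pi/2) centred on the origin of the top surface; detection is an
annular photodiode on the same surface.  Two estimators are available:

* :func:`simulate` — the reference sampler (dimensionless steps converted
  by the local attenuation, absorption weighting, Henyey-Greenstein phase
  function, Fresnel top boundary, Russian roulette);
* :func:`run_pulse_pair` — a paired rest/pulse run on *shared* scattering
  paths.  Rest and pulse tissue differ only in dermal absorption, so the
  trajectory ensemble (a function of scattering only) is common to both
  and each state is scored with its own track-length attenuation.  The
  pulsatile AC, the difference of two nearly equal detected fractions, then
  converges orders of magnitude faster than with independent runs.

AC is stored as ``rest - pulse`` (a positive amplitude: the pulse state
absorbs more and therefore detects less); DC is the rest detected fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .tissue import TissueModel, build_tissue_model

__all__ = [
    "SourceSpec",
    "DetectorSpec",
    "MCResult",
    "PulsePair",
    "AmplitudeGrid",
    "simulate",
    "run_pulse_pair",
    "converge",
    "compute_grid",
    "normalize_grid",
    "expand_seeds",
]


@dataclass(frozen=True)
class SourceSpec:
    """Square LED-type emitter on the tissue surface (lengths in mm)."""

    side: float = 1.0
    half_angle: float = 2.4  # radians, clamped to pi/2 at use
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("source side length must be positive")
        if self.half_angle <= 0:
            raise ValueError("source half angle must be positive")

    @property
    def clamped_half_angle(self) -> float:
        if self.half_angle > math.pi / 2:
            warnings.warn(
                f"source half angle {self.half_angle} rad exceeds pi/2; clamping",
                stacklevel=2,
            )
            return math.pi / 2
        return self.half_angle


@dataclass(frozen=True)
class DetectorSpec:
    """Annular photodiode (lengths in mm).

    The default radii are the tabulated 0.0071/0.0091 mm values taken
    verbatim; they are far smaller than the 1.0 mm source they nominally
    surround, so :meth:`alternative` provides the physically consistent
    annulus just outside the source footprint (0.71–0.91 mm).
    """

    inner_radius: float = 0.0071
    outer_radius: float = 0.0091
    center: tuple[float, float] = (0.0, 0.0)
    surface: Literal["top", "bottom"] = "top"

    def __post_init__(self) -> None:
        if not 0 <= self.inner_radius <= self.outer_radius:
            raise ValueError("need 0 <= inner_radius <= outer_radius")

    @classmethod
    def alternative(cls) -> "DetectorSpec":
        """Annulus just outside the footprint of the 1.0 mm square source."""
        return cls(inner_radius=0.71, outer_radius=0.91)

    @property
    def area_cm2(self) -> float:
        """Annulus area in cm^2 (used as the default photodiode area)."""
        return math.pi * (self.outer_radius**2 - self.inner_radius**2) / 100.0


@dataclass(frozen=True)
class MCResult:
    """Weight-fraction tally of one simulation."""

    detected_fraction: float
    absorbed_fraction: float
    escaped_fraction: float
    n_photons: int
    seed: int

    def __post_init__(self) -> None:
        total = self.detected_fraction + self.absorbed_fraction + self.escaped_fraction
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"weight not conserved: tallies sum to {total}")


@dataclass(frozen=True)
class PulsePair:
    """Paired rest/pulse detection result for one grid point."""

    rest: MCResult
    pulse: MCResult
    ac: float
    dc: float
    cv_ac: float
    converged: bool = True

    def __post_init__(self) -> None:
        if self.cv_ac < 0:
            raise ValueError("cv_ac must be non-negative")


@dataclass
class AmplitudeGrid:
    """AC/DC amplitudes over the (age, VFM, wavelength) factorial grid."""

    table: pd.DataFrame  # columns: age, vfm, wavelength, ac, dc, cv_ac, n_photons, converged

    def __post_init__(self) -> None:
        required = {"age", "vfm", "wavelength", "ac", "dc"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"grid table missing columns {sorted(missing)}")


def expand_seeds(master_seed: int, n: int) -> np.ndarray:
    """Expand one master seed into ``n`` independent 32-bit substream seeds."""
    return np.random.SeedSequence(master_seed).generate_state(n)


def _clamped_sin2(source: SourceSpec) -> float:
    return math.sin(source.clamped_half_angle) ** 2


def simulate(
    model: TissueModel,
    source: SourceSpec | None = None,
    detector: DetectorSpec | None = None,
    n_photons: int = 100_000,
    seed: int = 0,
    *,
    w_min: float = _kernels.WEIGHT_MIN,
    p_survive: float = _kernels.P_SURVIVE,
) -> MCResult:
    """Run the reference absorption-weighting sampler for one tissue model.

    ``detected_fraction`` is the summed surviving photon weight exiting the
    detection surface inside the detector annulus, per launched photon.
    Deterministic for a fixed seed.
    """
    source = source or SourceSpec()
    detector = detector or DetectorSpec()
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if n_photons > 2**63 - 1:
        raise OverflowError("photon count overflows a 64-bit counter")
    arrs = model.layer_arrays()
    z_bounds = np.concatenate(([0.0], np.cumsum(arrs["thickness_cm"])))
    det, absd, esc = _kernels.mcml_kernel(
        int(seed) & 0xFFFFFFFF,
        int(n_photons),
        z_bounds,
        arrs["mua"],
        arrs["mus"],
        arrs["g"],
        model.layers[0].n / model.n_ambient,
        source.side / 10.0,
        _clamped_sin2(source),
        _kernels.DET_BOTTOM if detector.surface == "bottom" else _kernels.DET_TOP,
        detector.inner_radius / 10.0,
        detector.outer_radius / 10.0,
        detector.center[0] / 10.0,
        detector.center[1] / 10.0,
        w_min,
        p_survive,
    )
    return MCResult(det, absd, esc, n_photons, int(seed))


def _paired_run(
    rest: TissueModel,
    pulse: TissueModel,
    source: SourceSpec,
    detector: DetectorSpec,
    n_photons: int,
    seed: int,
    w_min: float,
    p_survive: float,
) -> tuple[MCResult, MCResult]:
    """One shared-path rest/pulse run (common random numbers)."""
    if detector.surface != "top":
        raise ValueError("paired runs detect on the top surface")
    a_rest = rest.layer_arrays()
    a_pulse = pulse.layer_arrays()
    if not (
        np.array_equal(a_rest["mus"], a_pulse["mus"])
        and np.array_equal(a_rest["g"], a_pulse["g"])
        and np.allclose(a_rest["thickness_cm"], a_pulse["thickness_cm"])
    ):
        raise ValueError("rest and pulse models must share geometry and scattering")
    z_bounds = np.concatenate(([0.0], np.cumsum(a_rest["thickness_cm"])))
    mua_sets = np.vstack([a_rest["mua"], a_pulse["mua"]])  # row 0 = smaller mua
    det, absd, esc = _kernels.paths_kernel(
        int(seed) & 0xFFFFFFFF,
        int(n_photons),
        z_bounds,
        mua_sets,
        a_rest["mus"],
        a_rest["g"],
        rest.layers[0].n / rest.n_ambient,
        source.side / 10.0,
        _clamped_sin2(source),
        detector.inner_radius / 10.0,
        detector.outer_radius / 10.0,
        detector.center[0] / 10.0,
        detector.center[1] / 10.0,
        w_min,
        p_survive,
    )
    res = [
        MCResult(det[k], absd[k], esc[k], n_photons, int(seed)) for k in (0, 1)
    ]
    return res[0], res[1]


def run_multi(
    models: Sequence[TissueModel],
    source: SourceSpec | None = None,
    detector: DetectorSpec | None = None,
    n_photons: int = 100_000,
    seed: int = 0,
    *,
    w_min: float = _kernels.WEIGHT_MIN,
    p_survive: float = _kernels.P_SURVIVE,
) -> list[MCResult]:
    """Score several absorption variants of one geometry on shared paths.

    All models must share thicknesses, scattering and anisotropy (e.g. a
    VFM ladder, or rest/pulse states); the first model should have the
    smallest absorption in every layer, since its weight drives the shared
    Russian roulette.  Differences between the returned detected fractions
    are per-photon paired — strictly monotone in any per-layer ``mua``
    ordering of the inputs.
    """
    if not models:
        raise ValueError("need at least one model")
    source = source or SourceSpec()
    detector = detector or DetectorSpec()
    if detector.surface != "top":
        raise ValueError("shared-path runs detect on the top surface")
    ref = models[0].layer_arrays()
    mua_rows = [ref["mua"]]
    for m in models[1:]:
        a = m.layer_arrays()
        if not (
            np.array_equal(ref["mus"], a["mus"])
            and np.array_equal(ref["g"], a["g"])
            and np.allclose(ref["thickness_cm"], a["thickness_cm"])
        ):
            raise ValueError("all models must share geometry and scattering")
        mua_rows.append(a["mua"])
    mua_sets = np.vstack(mua_rows)
    if np.any(mua_sets < mua_sets[0]):
        warnings.warn(
            "first model does not have the minimal absorption; roulette "
            "efficiency (not correctness) suffers",
            stacklevel=2,
        )
    z_bounds = np.concatenate(([0.0], np.cumsum(ref["thickness_cm"])))
    det, absd, esc = _kernels.paths_kernel(
        int(seed) & 0xFFFFFFFF,
        int(n_photons),
        z_bounds,
        mua_sets,
        ref["mus"],
        ref["g"],
        models[0].layers[0].n / models[0].n_ambient,
        source.side / 10.0,
        _clamped_sin2(source),
        detector.inner_radius / 10.0,
        detector.outer_radius / 10.0,
        detector.center[0] / 10.0,
        detector.center[1] / 10.0,
        w_min,
        p_survive,
    )
    return [
        MCResult(det[k], absd[k], esc[k], n_photons, int(seed))
        for k in range(len(models))
    ]


def run_pulse_pair(
    age: float,
    vfm: float,
    wavelength: float,
    n_photons: int = 100_000,
    seeds: Sequence[int] | None = None,
    *,
    master_seed: int | None = None,
    source: SourceSpec | None = None,
    detector: DetectorSpec | None = None,
    w_min: float = _kernels.WEIGHT_MIN,
    p_survive: float = _kernels.P_SURVIVE,
) -> PulsePair:
    """Triplicate paired rest/pulse simulation at one grid point.

    ``ac = rest - pulse`` detected fraction (averaged over the triplicate);
    ``dc`` is the rest detected fraction; ``cv_ac`` is sd/mean of the three
    AC values.  A non-positive mean AC flags the pair as unconverged rather
    than raising.
    """
    if seeds is None:
        if master_seed is None:
            master_seed = 0
        seeds = expand_seeds(master_seed, 3)
    if len(seeds) != 3:
        raise ValueError("run_pulse_pair expects exactly three triplicate seeds")
    source = source or SourceSpec()
    detector = detector or DetectorSpec()
    rest_model = build_tissue_model(age, vfm, wavelength, "rest")
    pulse_model = build_tissue_model(age, vfm, wavelength, "pulse")

    rest_runs, pulse_runs, acs = [], [], []
    for s in seeds:
        r, p = _paired_run(
            rest_model, pulse_model, source, detector, n_photons, s, w_min, p_survive
        )
        rest_runs.append(r)
        pulse_runs.append(p)
        acs.append(r.detected_fraction - p.detected_fraction)
    acs = np.asarray(acs)

    def _pool(runs: list[MCResult]) -> MCResult:
        return MCResult(
            float(np.mean([r.detected_fraction for r in runs])),
            float(np.mean([r.absorbed_fraction for r in runs])),
            float(np.mean([r.escaped_fraction for r in runs])),
            n_photons * len(runs),
            int(seeds[0]),
        )

    rest = _pool(rest_runs)
    pulse = _pool(pulse_runs)
    mean_ac = float(acs.mean())
    if mean_ac > 0:
        cv = float(acs.std(ddof=1) / mean_ac)
        converged = True
    else:
        cv = float("inf")
        converged = False
    return PulsePair(rest, pulse, max(mean_ac, 0.0), rest.detected_fraction, max(cv, 0.0), converged)


def converge(
    age: float,
    vfm: float,
    wavelength: float,
    target_cv: float = 0.10,
    start_n: int = 100_000,
    growth_factor: float = 4.0,
    *,
    max_photons: int = 100_000_000,
    master_seed: int = 0,
    source: SourceSpec | None = None,
    detector: DetectorSpec | None = None,
) -> tuple[PulsePair, int]:
    """Grow the photon count until the triplicate AC coefficient of variation
    drops below ``target_cv`` (the 10% convergence rule).

    Returns ``(pair, n_photons_used)``.  If the photon budget cap is reached
    first, the best (lowest-CV) attempt is returned with ``converged=False``.
    """
    if start_n < 1_000:
        raise ValueError("start_n must be at least 1e3")
    if growth_factor <= 1:
        raise ValueError("growth_factor must exceed 1")
    n = int(start_n)
    best: PulsePair | None = None
    best_n = n
    attempt = 0
    while True:
        seeds = expand_seeds(master_seed, 3 * (attempt + 1))[-3:]
        pair = run_pulse_pair(
            age, vfm, wavelength, n, seeds, source=source, detector=detector
        )
        if pair.cv_ac < target_cv:
            return pair, n
        if best is None or pair.cv_ac < best.cv_ac:
            best, best_n = pair, n
        nxt = int(n * growth_factor)
        if nxt > max_photons:
            return replace(best, converged=False), best_n
        n = nxt
        attempt += 1


def compute_grid(
    ages: Iterable[float],
    vfms: Iterable[float],
    wavelengths: Iterable[float],
    n_photons: int = 1_000_000,
    master_seed: int = 0,
    *,
    source: SourceSpec | None = None,
    detector: DetectorSpec | None = None,
    target_cv: float | None = None,
) -> AmplitudeGrid:
    """Run the full factorial grid at a fixed photon count (or, with
    ``target_cv``, with the convergence rule) and collect AC/DC amplitudes."""
    rows = []
    combos = [(a, v, w) for a in ages for v in vfms for w in wavelengths]
    sub_seeds = expand_seeds(master_seed, len(combos))
    for (age, vfm, wl), sd in zip(combos, sub_seeds):
        if target_cv is None:
            pair = run_pulse_pair(
                age, vfm, wl, n_photons, master_seed=int(sd),
                source=source, detector=detector,
            )
            n_used = n_photons
        else:
            pair, n_used = converge(
                age, vfm, wl, target_cv, start_n=n_photons,
                master_seed=int(sd), source=source, detector=detector,
            )
        rows.append(
            dict(
                age=age, vfm=vfm, wavelength=wl, ac=pair.ac, dc=pair.dc,
                cv_ac=pair.cv_ac, n_photons=n_used, converged=pair.converged,
            )
        )
    return AmplitudeGrid(pd.DataFrame(rows))


def normalize_grid(grid: AmplitudeGrid) -> AmplitudeGrid:
    """Scale AC and DC maps so each has maximum exactly 1.

    Adds ``normalized_ac``/``normalized_dc`` columns and records the argmax
    combinations in ``table.attrs``.  Raises on an all-zero grid; invariant
    under uniform rescaling of the raw amplitudes.
    """
    df = grid.table.copy()
    if len(df) == 0:
        raise ValueError("empty amplitude grid")
    out_attrs = {}
    for col in ("ac", "dc"):
        m = df[col].max()
        if m <= 0:
            raise ValueError(f"all-zero {col.upper()} grid cannot be normalized")
        df[f"normalized_{col}"] = df[col] / m
        imax = df[col].idxmax()
        out_attrs[f"argmax_{col}"] = tuple(
            df.loc[imax, ["age", "vfm", "wavelength"]]
        )
    df.attrs.update(out_attrs)
    return AmplitudeGrid(df)
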