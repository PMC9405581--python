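# Methods

This note records the scientific and numerical choices behind `ppgforge`,
in the spirit of a model-description appendix: what is modelled, which
constants drive it, where the design was genuinely open, and what a green
test does and does not establish.

## 1. Tissue model

Six plane-parallel layers of the volar fingertip (epidermis, papillary
dermis, upper blood net, reticular dermis, deep blood net, subcutis), each
homogeneous, laterally infinite.

**Geometry.** Epidermis 0.55 mm, subcutis 2.00 mm, both age-independent.
Total dermal thickness follows a linear thinning law anchored at 0.75 mm
for a 61-year-old with a slope of 0.0044 mm per year, partitioned into the
four sublayers by fixed volume fractions (8.2%, 4.37%, 81.97%, 5.46%).
The slope is the literature's per-year fit expressed in mm; quoted once as
"0.00044 mm", which is a unit slip — only 0.00044 cm/yr reproduces every
tabulated thickness. Supported age range 18–80 y (hard error outside).
One tabulated cell (upper blood net, age 55) is printed as 0.033 mm where
the model gives 0.0339 mm; the source truncated that cell while rounding
its neighbour, so exact 3-decimal agreement there is unattainable and the
tests hold that single cell to one unit in the last printed digit.

**Optics.** Scattering coefficients, dermal and subcutis absorption are
tabulated at 515/660/880 nm and used verbatim. Epidermal absorption is a
linear melanosome mixture, `µa(λ, VFM) = VFM · µa_mel(λ) + (1 − VFM) ·
µa_base(λ)` with `µa_mel = 6.6·10¹⁰ λ⁻³·³³ cm⁻¹` (λ in nm). The baseline
is *back-solved from the tabulated VFM = 0.03 cell* rather than taken from
a literature formula, so the table remains authoritative; the mixture then
reproduces all twelve tabulated cells within 0.8%. Anisotropy g = 0.9 and
refractive index 1.4 (ambient 1.0) are standard skin values — the source
does not print them — and are exposed as arguments.

**Pulse state.** A systolic beat raises only the four dermal sublayers'
absorption. The tabulated pulsed coefficients correspond to the youngest
(23 y) subject, whose blood-volume surge is 1.124×; the surge factor is
tabulated down to 1.073× at 55 y and linearly interpolated (clamped with a
warning outside 23–55 y). For other ages the blood-borne increment scales
as `(factor(age) − 1) / 0.124`, preserving the printed values at the
anchor. The precision of the printed pulsed values matters: at 660/880 nm
the increments survive with one significant digit (e.g. 0.5250 − 0.5249 =
0.0001 cm⁻¹), which propagates into any cross-wavelength AC comparison
(§6).

## 2. Photon transport

Two estimators over the same geometry (z = 0 at the illuminated surface,
lengths internally in cm):

* **Reference sampler** (`simulate`): dimensionless step −ln ξ converted by
  the local µt, absorption weighting µa/µt per collision,
  Henyey–Greenstein phase function, unpolarized Fresnel reflection at the
  top 1.4/1.0 interface, absorbing bottom boundary, Russian roulette below
  weight 10⁻⁴ with survival 0.1. Detection is the surviving weight exiting
  within the annular detector.
* **Shared-path paired estimator** (`run_pulse_pair`, `run_multi`):
  trajectories sampled from (µs, g) only — identical for any set of
  absorption vectors over the same geometry — with each absorption vector
  scored by the track-length factor exp(−Σ µa·ℓ). Rest/pulse (and whole
  VFM ladders) ride the same paths, making AC = rest − pulse a per-photon
  paired difference: at 2·10⁵ photons the triplicate CV of AC is already
  ~1.5%, versus the enormous photon counts independent runs would need.
  Roulette is driven by the first (smallest-absorption) channel and applied
  jointly, which keeps every channel unbiased.

Weight bookkeeping is exact rather than in-expectation: roulette kills
deposit the dead weight in the absorbed bin, survivals deposit the negative
amplification `w − w/p`, so detected + absorbed + escaped = 1 to float
round-off on every run (tested at 10⁻⁹).

**AC sign.** The verbal definition "pulse minus rest" yields a negative
number (the pulse state absorbs more and detects less); AC is stored as
rest − pulse so that it is the positive amplitude used everywhere
downstream.

**Source and detector.** The emitter is a 1.0 mm square with a Lambertian
angular distribution clamped to a half angle of π/2 — the quoted 2.4 rad
exceeds a hemisphere and is treated as "fully Lambertian", with a warning.
The quoted detector radii (0.0071/0.0091 mm) are kept as the default but
conflict with an annulus "surrounding" a 1 mm emitter; they appear to be a
100× slip for 0.71/0.91 mm, which is exactly the annulus just outside the
source footprint. `DetectorSpec.alternative()` provides that physically
consistent geometry and is used for the trend tests, where the tiny default
would detect almost nothing at desk-scale photon counts.

**Seeds.** One master seed expands to independent 32-bit substreams
(`numpy.random.SeedSequence`); triplicates use consecutive substreams. The
jitted kernels seed numba's Mersenne-Twister, which reproduces NumPy's
legacy `RandomState` stream bit for bit — the test suite exploits this by
replaying a kernel run against an independently coded pure-Python photon
loop on the same stream.

**Convergence rule.** Each grid point is run in triplicate with an
increasing photon count until CV(AC) < 10%, growth factor 4 from a
configurable start; hitting the photon budget returns the best attempt
flagged unconverged. The study-scale counts (5·10⁸–10¹¹ photons/GPU) are
out of desk scope; tests run 10⁵–10⁶ photons with the paired estimator,
which is statistically adequate for every trend they assert.

## 3. Waveform generator

The pulse is `y(t) = Σ aᵢ exp(−((t − bᵢ)/cᵢ)²)` — the spreadsheet-solver
parameterisation with no 2c² factor and no normalisation. This convention
matters: the shipped age templates (23/34.4/44.8/55 y, native period
0.8 s) are only meaningful under it. Fitting replaces the original
generalized-reduced-gradient spreadsheet solver with multi-start bounded
least squares (scipy trf) on relative residuals, scored by median relative
error (robust to near-zero tails); round-trip refits of shipped templates
recover parameters to ≪1% with median error ≪0.1%.

Records are tiled by concatenation — any step at the beat junction is
accepted, as in the source's repetition scheme — after time-axis scaling of
the template to the beat period. The phase is computed by sample-index
modulo, not time modulo, so that a beat spanning a whole number of samples
tiles *exactly* periodically (float time-modulo jitters at the wrap and
produced 4·10⁻² amplitude artifacts at beat 12+). The finished record is
affinely scaled to span AC above a DC floor; noise (default 20/40/60 Hz at
0.38/0.59/0.59 of AC) is added after scaling, with the 60 Hz tone phased
π/2 because it sits exactly at the 120 Hz Nyquist frequency.

## 4. Device simulator

Filters: 0.1–7 Hz 4th-order Butterworth bandpass; 0.1–7 Hz 4th-order
inverse Chebyshev bandpass + 10-sample trailing moving average; 7 Hz
inverse Chebyshev lowpass + the same moving average; and a no-op control.
One caption prints the band as "0.1–0.7 Hz"; 0.1–7 Hz is adopted since a
0.7 Hz cutoff would delete the 1.25 Hz cardiac fundamental that the
downstream features demonstrably retain. The type II stopband attenuation
is not printed; 40 dB, configurable. All filtering is causal
(forward-only) — device-realistic, and consistent with the ringing visible
in the source's low-resolution traces.

ADC: photocurrent `i = 10 · value · P_LED · A_PD` (the dimensional
looseness of the printed relation is implemented literally),
`code = ⌊i · 2^bits / I_ref⌋` saturated to [0, 2^bits − 1]. Defaults
I_ref = 32 µA, P_LED = 50 mW, A_PD = the annular detector area. The
resolution sweep applies identical processing at each bit depth and at the
25-bit reference and reports the median percent sample difference
(filter-then-ADC by default; the other order is exposed).

Group rescaling maps each parameter combination's records jointly onto
[0.5, 2.7], the range of the training data the regression stage expects.

## 5. Feature extraction

Peak detection re-implements the adaptive rolling-mean approach of the
heartPy library (window 0.75 s; regional maxima above the baseline;
refractory de-duplication at half the expected beat; rejection of beats
closer than half the median inter-beat interval) so the package carries no
external peak-detection dependency. Onsets are the preceding local
minimum. The dicrotic notch follows the stated second-derivative rule: the
smoothed (Savitzky–Golay, window 11, order 3), min-max-scaled second
derivative is scanned between peak and next onset; its deepest interior
local minimum is the "b" wave and the first local maximum after it the "c"
wave, taken as the notch. Requiring an *interior* minimum matters: the
sample at the peak itself sits on the rising flank of the b-wave and would
otherwise masquerade as it, pinning the notch 30 ms after the peak instead
of mid-beat.

Sub-sample precision: the systolic peak (time and value) is refined by a
three-point parabolic fit, and threshold crossings are linearly
interpolated. At 120 Hz the raw grid is 8.3 ms — a third of the systolic
width at the 75% threshold — and the parabolic refinement is what brings
the width features within their acceptance tolerances; onsets are left at
the sampled minimum because a tiled beat's foot is a genuine corner.

Width conventions: pulse amplitude is peak − onset value;
`x{p}SysWidth` = rising p% crossing → peak, `x{p}DiaWidth` = peak →
falling p% crossing, `x{p}WidthTime` their sum and `x{p}DivWidthTime` the
diastolic/systolic ratio. This convention makes the reported
width/ratio pairs mutually consistent (0.67 s at 10% splitting ≈
0.12/0.55 s at ratio 4.68). The p-grid {10, 25, 33, 50, 66, 75} is
configurable; only 10 and 75 are externally evidenced, the rest populate
the registry (29 named features per record with the default grid;
notch-dependent entries are flagged missing rather than failing when no
notch exists). Per-window values are means across accepted beats; window
acceptance is >90% of expected peaks found and <10% rejected.

The reported feature values this package is tested against appear to be
means over further factor levels (their printed sd annotations suggest so),
which the acceptance tolerances (±0.04 s on widths, ±15% on ratios)
absorb; the control pipeline lands at 0.188/0.250 s (75% widths),
0.694 s (10% width, age 23) and 5.33/3.33 (10% ratios) against printed
0.16/0.23, 0.67 and 4.68/3.26.

## 6. What the synthetic world does not reproduce

* **Wavelength-trend magnitudes.** The reported normalized-AC changes
  (−59% from 515→660 nm, +107% from 660→880 nm) reproduce in sign and
  ordering but not magnitude (−93%/+56% at the consistent annulus;
  −80…−93% over every collection geometry scanned to 10 mm radius). The
  binding constraint is the four-decimal precision of the tabulated pulsed
  absorption: at 660/880 nm the pulsatile increment retains one significant
  digit, and AC at those wavelengths is directly proportional to it. No
  photon count can recover information the table does not carry; the
  corresponding acceptance check is left failing by design, with the
  sign/ordering half asserted.
* **Training data.** The clinical database behind the original regression
  models is out of scope. `generate_synthetic_training` plants a known
  linear-plus-noise dependence (documented in `DataFrame.attrs`), which
  makes the preprocessing rules, split evaluation and sensitivity metric
  testable — parameter recovery, residual-sd recovery, pass-through
  identities — but means the published clinical error statistics are
  *not* reproduced and no clinical validity is claimed.
* **Physiology not modelled.** No beat-to-beat variability, arrhythmia,
  motion artifact, epidermal thinning with age, or voxel-level anatomy;
  the slabs are laterally infinite, so source–detector separation effects
  beyond the annulus radii are geometric only.

A green test therefore establishes: internal consistency with the tabulated
constants, correctness of the estimators against closed forms and
independent oracles, and the qualitative factor trends — not agreement with
any clinical dataset.

## 7. Numerical details worth knowing

* Roulette threshold 10⁻⁴, survival 0.1; both overridable per call.
* The degenerate flight (non-interacting layer, exactly horizontal
  direction) is terminated as absorbed rather than looping.
* `fit_template` requires a strictly positive template (relative
  residuals); constant templates are rejected.
* Feature extraction needs ≥2 beats; empty fiducial sets are returned, not
  raised, for degenerate signals.
* Records round-trip through CSV at 17 significant digits with
  `float_precision="round_trip"` parsing — bitwise equality is tested.
* Preprocessing order is fixed: range filter → 3-sd outlier removal →
  min-max rescale; a second application is a no-op on the tested worlds,
  though pathological distributions could lose further rows on re-running
  (the sd shrinks after removal).
* Suite-scale photon counts: the wavelength-trend check runs 10⁶
  photons/wavelength (measured ~45 µs per photon path on one CPU), and the
  reduced-grid trend check 2·10⁵ per (age, λ) with VFM/state as shared-path
  channels; both are far inside the statistical resolution their
  assertions need.
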