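# Methods

This note documents the models and procedures `arraycal` implements, the
defaults and why they were chosen, and what the synthetic studies do and do
not demonstrate.

## Coordinate and geometry conventions

Positions are CAX-centered, in cm, in the detector plane at 100 cm
source-to-detector distance. +x is lateral, +y longitudinal (toward the
gantry). Reconstruction-grid indices (X, Y) are signed integers with 0 on
the CAX; one grid unit is the array shifting distance, which must be an
integer multiple of the detector spacing. Shifting the array by s cm moves
a detector from x to beam coordinate x + s, so the one-step-left wide-field
measurement reads `MLAT-1(X,Y) = R(X-1,Y)·S(X,Y)`.

The MapCHECK2 layout is built from its published pitch: 65 rows at 0.5 cm
longitudinal interval (y = −16..16), 1 cm lateral detector spacing within a
row, odd rows staggered 0.5 cm, and four 7×7 cm² corner triangles cut from
the 26 cm (lateral) × 32 cm (longitudinal) active area. These constraints
alone yield 1527 detectors — the actual diode count of the device — of
which the 779 on the integer-cm lattice form the reconstruction grid. The
orientation (32 cm longitudinal) follows from the longitudinal error-lock
anchors at ±14 cm and the 16-step longitudinal chains, which both require a
16 cm longitudinal half-extent. Masked detectors are carried as NaN
throughout, never zero: a zero would corrupt ratio products, a NaN
truncates the affected chain and is reported.

Which of the two interleaved detector families contains the exact array
center is configurable (`origin_index`); the default places it on the
integer-lattice family, which is what makes a 1 cm reconstruction grid
possible.

## Ratio-chain reconstruction

Each 1D profile value is a telescoping product of shifted/unshifted reading
ratios, in which the per-detector sensitivities cancel identically — the
reconstruction is exactly invariant to the true sensitivity map in
noiseless data, which the tests assert at machine precision. Products are
computed as exponentials of sums of log-ratios, treating the two chain
directions symmetrically over up to 16 factors. Chains start at index 0 and
extend outward; a missing detector truncates the chain beyond it (no
gap-jumping — every intermediate reading is required), and a non-positive
reading inside a chain is an error naming the offending index. Grid indices
are exact integers: shifts must be declared in integer steps, and no
tolerance-based matching of shift distances is done. The 2D profile is the
per-row lateral profile reweighed by the central longitudinal profile,
`RNOR(X,Y) = RXNOR(X,Y)·RYNOR(0,Y)`; if the central column is unusable at
some row this is an error rather than a silent substitution of a neighbour
column. Longitudinal chains are built for every column (not just the
central one); the extra columns feed the longitudinal error-lock and
diagnostics.

## Error model and locking

Per-step multiplicative errors accumulate along chains as

    RNOR'(X) = RNOR(X)·(1+E1−E2)^|X|   (X < 0)
    RNOR'(X) = RNOR(X)/(1+E1+E2)^X     (X > 0)

E1 (output variation) alone tilts the profile — one side up, the other
down; E2 (positioning) alone moves both sides the same way, flattening or
sharpening. E2 is a single average factor although the underlying error
scales with the local profile gradient; the residual row-to-row spread of
the per-row estimates is retained in the diagnostics as a measure of that
simplification. The sign pairing (1+E1−E2 on the negative side, 1+E1+E2 on
the positive side) is the unique assignment consistent with the stated
directional behaviour of the two components and with the worked 16-step
arithmetic (0.036%/0.054% per step ↔ 1.45%/0.3% edge deviations).

Locking: three narrow-strip exposures shift the array so the strip center
lands on positions A < 0 < C (defaults: ±11 steps lateral with a 4×37 cm²
strip, ±14 steps longitudinal with 37×4 cm²). The probed detectors all
receive the strip-center fluence, so their reading ratios are pure
sensitivity ratios; dividing the wide-field ratios by them gives the true
normalized profile at the anchors. With u = (RNOR'(A)/RNOR(A))^(1/(−A)) − 1
and v = (RNOR(C)/RNOR'(C))^(1/C) − 1, the closed form is e1 = (u+v)/2,
e2 = (v−u)/2. Estimates are solved per row and aggregated by unweighted
mean over the rows whose chains reach both anchors (rows whose anchors fall
in the masked corners are skipped and listed); correction applies the
aggregate estimate to every row and is the exact algebraic inverse of the
forward model. Per-row estimates remain available in the diagnostics for
the alternative row-wise correction mode of analysis.

## Noniterative reference

The narrow-field-scan method reconstructs each point from its own pair of
measurements: scanning the strip across the array gives the relative
sensitivity of every probed column (row) directly, and the wide-field
reading divided by it gives the profile with no ratio chaining, hence no
error propagation — a local output drift perturbs exactly one scan
position, which the tests assert. It serves as the independent cross-check
of the iterative method (they agree to < 1e-10 on clean sessions) at the
cost of 59 irradiations instead of 9 at 1 cm resolution. The default scan
step equals the grid step (1 cm) so the reference natively covers the
reconstruction grid; the labor-saving 2 cm protocol is available via
`scan_step=2` and yields a coarser grid that is interpolated like any
other.

## Simulator

Forward model per detector:
`reading = MU · output_scale · noise · R(x+shift+pos_err, y+…) · S(x,y)`.
MU is a pure scale (default 200) and cancels in all ratios.

* **Beam profile.** The default bowl is a smoothed cone,
  `R = 1 + s·(sqrt(r² + w²) − w)` with w = 1.5 cm and s fixed so that
  R = 1.08 at 15 cm off-axis, exactly. The quasi-linear rise (relative
  gradient ≈ 0.0059/cm away from the apex) reproduces the two quantitative
  signatures large-field array measurements show: a 1 mm displacement
  perturbs a reading by ≈ 0.053% essentially anywhere off-center, and a
  5 mm displacement appears as a ≈ 0.29% per-step error in the chains. An
  even-polynomial bowl (a2·r² + a4·r⁴) whose gradient grows linearly from
  zero is available via parameters but fits the constant-per-step error
  model visibly worse; it is not the default because measured flattened
  beams do not behave that way. A Gaussian FFF peak, a flat beam, and a
  custom callable are also available; the methods are shape-independent by
  construction.
* **Aperture.** Error-function field edges with a configurable 80–20
  penumbra width, default 0.5 cm. Wide-field irradiations warn if any
  detector sits within two penumbra widths of the field edge. The
  `narrow_flat` switch replaces the in-field shape of narrow strips with a
  constant, to stress-test the equal-fluence assumption separately from
  aperture effects (under the shifting convention used here the assumption
  is exact even for curved profiles, because every probed detector sits at
  the strip center).
* **Sensitivities.** 1 + spread·z with z standard normal truncated at ±5σ
  (relative response spread; default studies use 2%, in the range of diode
  arrays). Zero spread gives exact unity.
* **Noise.** Independent multiplicative Gaussian per detector, truncated at
  ±5σ; diode repeatability is relative, so noise is specified as a relative
  SD (0.1% in the default studies). All randomness derives from a single
  session seed via per-measurement substreams: sessions are
  bit-reproducible and different measurements are independent.
* **Positioning error.** Applied in continuous cm in the profile argument,
  not in grid steps, so sub-step errors (5 mm against a 1 cm step) are
  representable.

## Robustness study

`run_robustness_study` calibrates the same simulated MapCHECK2 three ways
(locked, unlocked, reference) under two conditions: normal (0.1% noise
only) and with a 5 mm systematic displacement added to the two shifted
wide-field irradiations (the locking strips and the reference scans stay
aligned, mirroring the published experimental design where the error was
introduced into the iterative procedure under test). Deviations are
per-detector absolute percent differences over the detectors all methods
calibrate, reported against ground truth and against the reference.

Typical outcome (seed 1): unlocked degrades from ≈0.3% to ≈2.6% mean
(≈6% at edges) while locked stays at ≈0.4%, within 0.3 points of the
reference — an improvement of ≈6×. Two residuals set the locked floor:
the single-factor E2 approximation leaves ≈0.2% of gradient-dependent
structure (measured by the noiseless study), and 0.1% reading noise random-
walks to ≈0.35% mean through the chains. Because the floor is mostly noise,
the locked/unlocked ratio is seed-dependent (roughly 3–8 over seeds, ≥5 for
about 80% of them); the dedicated test fixes the study seed.

What the study does *not* show: real beams have horns near the field edge,
detector response drifts with temperature and accumulated dose, output
variation is correlated in time rather than white, and positioning errors
in practice combine translation with small rotations. None of these are
modelled; the study demonstrates the propagation/locking mechanics, not a
clinical commissioning result.

## Numerical and interface choices

* Bilinear interpolation to detector positions (monotone, cannot overshoot
  on bowl profiles); bicubic behind a flag. Values at grid nodes are taken
  from the grid directly, so node detectors are exact even next to masked
  corners. Detectors outside the grid hull or adjacent to an undefined node
  are excluded and reported, never extrapolated.
* The normalization detector is the geometry origin; if it is masked or
  unusable, calibration aborts.
* Deviation statistics use the reference method's value as denominator;
  histograms default to 0.1-percentage-point bins.
* e1/e2 are stored as fractions and reported additionally in percent.
* Measurement files, sensitivity maps (TSV), profiles and session
  manifests are plain text, write floats via `repr` (shortest round-trip),
  and round-trip bit-exactly; outputs embed the session seed and a config
  hash.

## Known limitations

* The error-lock corrects a constant per-step factor per axis; errors whose
  per-step size varies strongly across the array (sharp local gradients,
  field horns) are only corrected on average.
* A drift in one locking exposure biases the corresponding anchor by the
  same factor (documented bias mode, tested); the triad cannot distinguish
  it from a genuine sensitivity difference.
* The equal-fluence narrow-field argument assumes pure translations; array
  rotation during a shift is not modelled.
* Greer-style scans cover |x| ≤ 12 cm laterally by default, so the extreme
  lateral grid columns (±13) are reference-free; comparisons use the common
  support.
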