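# Methods

## Tilt model

A 3-axis accelerometer at quasi-static rest measures the gravity vector
in the device frame, so inclination follows from the direction cosines of
the measured acceleration **a** = (ax, ay, az), in G.  Two formula
families are implemented.

The *triple-axis* forms give an X–Y plane angle θ = tan⁻¹(ax/ay) and the
angle from gravity φ = cos⁻¹(az/‖a‖) ∈ [0°, 180°].  The θ form is exposed
exactly as written (its denominator is the single Y component); the
conventional triple-axis inclination divides by √(ay² + az²) instead, and
it is that conventional family — *independent inclination sensing* —
that the pipeline actually uses:

    θ = tan⁻¹( ax / √(ay² + az²) )
    ψ = tan⁻¹( ay / √(ax² + az²) )
    φ = tan⁻¹( √(ax² + ay²) / az )

Useful identities: sin θ = ax/‖a‖ and sin ψ = ay/‖a‖, so the angles are
scale-invariant in ‖a‖; and for az > 0 the two φ forms coincide.  All
angles are reported in degrees.

**Quadrant resolution.**  The plain arctangent confines θ, ψ to
(−90°, 90°] and cannot distinguish an orientation from its mirror through
the horizontal plane.  Each angle is therefore extended to (−180°, 180°]
with two-argument arctangent semantics: the numerator keeps its own sign
and the quadrature-sum denominator takes the sign of az, giving
θ = atan2(ax, sign(az)·√(ay² + az²)) and likewise for ψ, while
φ = atan2(√(ax² + ay²), az) ∈ [0°, 180°] (an inverted device reads
φ = 180°).  az = 0 is treated as the upper hemisphere so that near-flat
orientations resolve continuously.  The resolution is a function of the
raw sample only, hence idempotent.

**Degenerate inputs.**  Zero denominators return the signed ±90° limit —
the formulas' continuous limits at the gimbal boundaries — rather than
raising.  An exactly zero acceleration vector raises
`UndefinedOrientationError`: free fall has no orientation reference.
Angles at −180° exactly (an artifact of signed zeros in atan2) are folded
onto +180°.

**Rates.**  Acceleration is sampled at 50 Hz on a ±8 G range; tilt is
computed at 25 Hz by keeping every second sample.  No anti-alias filter
is applied before decimation — postural sway lives well below the 12.5 Hz
Nyquist limit of the decimated stream, and the feature stage applies no
spectral analysis that aliasing could corrupt.  Quadrant resolution runs
after decimation, on each retained sample.  Timestamps must be regular to
within 1% of the nominal step (configurable) or the series is rejected.

## Sway features

Per device axis: AMP(w) = max − min of the samples in each
non-overlapping 1 s window w aligned to trial start (trailing partial
window dropped); RMS over consecutive non-overlapping groups of three AMP
values, i.e. one RMS value per 3 s.  A T-second trial yields ⌊T⌋ AMP and
⌊T/3⌋ RMS values per axis; trials under 3 s are rejected.  Because AMP is
a within-window range, any constant offset — gravity on the axis pointing
down — cancels; this is the pipeline's only (implicit) gravity removal,
and no detrending or band-pass filtering is applied.  Both AMP and RMS
are positively homogeneous: scaling the dynamic part of the signal by k
scales every feature by k, which is what makes amplitude calibration in
the simulator exact in the noiseless case.

**Sway score.**  The scalar score per anatomical direction is the trial
mean of that direction's RMS series, in G, and the overall score is the
arithmetic mean over AP/ML/V.  The mean-of-RMS statistic is the simplest
scalar consistent with a 3 s RMS update cadence, and it produces scores
on the 0.1–0.5 G scale observed in the study groups.  Tilt-angle AMP
series (degrees) are computed identically and reported, but scores are
built from accelerations only.

**Axis mapping.**  Device axes map to anatomical directions through a
bijective `AxisMap`; the default Z→AP, X→ML, Y→V corresponds to a patch
worn flat on the chest with Z pointing outward.  The mapping is
configurable because mounting conventions vary and the choice only
relabels, never changes, the per-axis features.

## Diagnostic evaluation

**Labeling.**  Fallers are labeled by one of three criteria: BBS < 40
(strict inequality by default; an inclusive ≤ 40 variant is available
since clinical descriptions phrase the high-risk band as "40 or less"),
TUG > 14 s, or a positive 3-month fall history.

**ROC.**  The decision rule is score ≥ threshold ⇒ faller (the MCI group
sways more, so higher sway indicates risk).  Thresholds sweep the
distinct score values in descending order behind an ∞ sentinel; the curve
is traced by cumulative counts, so tied scores collapse onto single
vertices and the trapezoidal area equals the Mann–Whitney pair-counting
probability with ties counted one half.  This identity, plus invariance
under strictly increasing score transforms and the label-complement
symmetry AUC → 1 − AUC, is enforced by the test suite against brute-force
enumeration and scikit-learn as independent oracles.

**Uncertainty.**  SE(AUC) uses the Hanley–McNeil nonparametric formula
with Q₁ = A/(2−A), Q₂ = 2A²/(1+A), and the 95% interval A ± 1.96·SE is
clipped to [0, 1] — the standard normal-approximation summary for small
diagnostic studies, consistent with published intervals that cap at 0.99.

**Operating point.**  Youden's J = max(sens + spec − 1) selects the
cut-off; ties break toward higher sensitivity (a fall screen prefers
missing fewer fallers), then toward the lower threshold.  Sensitivity,
specificity and accuracy are TP/(TP+FN), TN/(TN+FP) and (TP+TN)/N; a
zero denominator yields NaN with a `None` grade rather than an exception.
Grades partition [0, 1] contiguously: excellent [0.81, 1], good
[0.61, 0.81), moderate [0.41, 0.61), poor [0, 0.41).

**Group comparison.**  Summary-statistic comparisons use Welch's
unequal-variance t-test (two-sided): the groups compared — young healthy
adults vs older adults with MCI — have clearly unequal spreads, so the
pooled-variance form would be miscalibrated.

## Synthetic cohorts

The generators encode the study conditions: two groups of n = 20, with
group sway-score moments (G) of 0.16 ± 0.20 (healthy) and 0.41 ± 0.12
(MCI) in the BBS context, 0.36 ± 0.08 and 0.47 ± 0.12 in the TUG
context, and clinical moments BBS 54.61 ± 1.33 vs 39 ± 5.88,
TUG 9.42 ± 0.25 s vs 14.11 ± 1.37 s.

*Score level.*  Sway scores are plain Gaussian draws — only means and SDs
are published, and truncating at zero would bias exactly the moments
being matched.  BBS draws are rounded to integers and clipped to [0, 56];
TUG draws are clipped positive.  Under these moments the closed-form
binormal separation Φ(Δμ/√(σ₀² + σ₁²)) is ≈ 0.86 (BBS context) and
≈ 0.78 (TUG context), which is what the large-n empirical AUC converges
to and what the acceptance script reports.

*Signal level.*  A trial is gravity (unit vector, 1 G) plus per-axis
oscillation plus white noise.  The oscillation is a sum of three
random-phase sinusoids with frequencies uniform in 0.1–2 Hz — the typical
postural-sway band — normalized so the `amplitude` parameter bounds the
peak excursion in G.  Defaults: 30 s at 50 Hz, noise off (tests and
examples enable 0.01–0.02 G noise where realism matters).  Specs whose
worst-case excursion could leave ±8 G are rejected up front.

*Calibration.*  `calibrate_amplitude` inverts the feature pipeline: it
finds the amplitude whose pipeline score equals a target, exactly by
linearity when noiseless, otherwise by Brent root-finding on a frozen
signal realization (same seed at every trial amplitude), to within 2%.
Per-subject targets drawn from the group score distributions (negative
draws clipped to the noise floor, since windowed scores are non-negative)
then yield raw-signal cohorts whose end-to-end AUC reproduces the
score-level binormal value; the acceptance suite verifies this within
3 Monte-Carlo standard errors on a 50-per-group cohort of 12 s trials —
sizes chosen to exercise the full chain at desk scale.

*Seeding.*  A single cohort seed fans out into per-subject substreams via
`numpy.random.SeedSequence.spawn`, so subject `MCI-001` is bit-identical
whether generated in a cohort of 4 or 40.

**What the simulator does not emulate.**  Real BBS/TUG trials contain
task phases (sit-to-stand, turning, gait) with nonstationary,
non-sinusoidal accelerations, sensor bias drift, and within-subject
correlation between sway and clinical scores beyond group membership.
Passing tests therefore demonstrate that the computational chain is
correct and well-calibrated under the stated statistical model — not that
the published per-cohort point estimates (which derive from 40
unavailable participants) are recovered.  Correspondingly, the acceptance
checks compare simulated AUCs against published confidence bounds, not
point values.

## Numerical choices

- Angles in degrees throughout; −180° folded to +180°.
- arctan ratios computed via atan2 on (num·sign(den), |den|) to avoid
  overflow at subnormal denominators.
- ROC assembled by a stable descending sort with cumulative counts,
  O(n log n), exact for ties.
- Report JSON is serialized with sorted keys and the ∞ threshold sentinel
  mapped to `null`, so reruns are byte-identical and the file is strict
  JSON.
- Youden tie-breaks are deterministic (higher sensitivity, then lower
  threshold).

## Known limitations

- The printed triple-axis θ = tan⁻¹(ax/ay) is exposed for parity but not
  used; its denominator differs from the conventional form and it is
  undefined for ax = ay = 0.
- Published per-cohort SEs and some accuracy values are internally
  inconsistent with their own CIs/metrics and are not reproduction
  targets; see the grading and CI conventions above for what is computed.
- No gyroscope/magnetometer fusion and no heading estimation: tilt comes
  from acceleration alone and is only valid quasi-statically.
- The ROC analysis treats subjects as independent; repeated trials per
  subject would require clustered variants out of scope here.
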