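# Methods

This note documents the models, numerical procedures and design choices
behind `lgabs`, in the spirit of a package's methods appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Device model

The simulated device is a bilaterally symmetric lumbar exoskeleton that
produces a per-side hip torque τ_E = τ_P + τ_A. All torques are per-side
N·m; total device torque is twice the per-side value. Angles are degrees
of lumbar flexion from the global vertical (0 upright), speeds deg/s.

**Passive law.** τ_P(θ_C) is defined by a keypoint table: five
characteristic angles, five torque ratios (fractions of the maximum
torque, non-decreasing, ending at 1), and a maximum torque per assistance
percentage. Sections between keypoints are interpolated with PCHIP
(shape-preserving cubic) splines; unconstrained cubics can overshoot and
break the device's observed property of providing progressively greater
force with flexion, so monotone keypoints must give a monotone curve.
Below the first characteristic angle the torque is 0 when the first ratio
is 0 (the default tables anchor the curve at zero), otherwise it holds the
first keypoint's value; beyond the last angle it is clamped at the last
keypoint's value. A single curve serves flexing and extending motion:
hysteresis is treated as negligible, consistent with a device whose
controller compensates the loss.

**Active law.** τ_A(θ̇_C) is a three-piece hinge per percentage: 0 below
the threshold speed `vel_lim`, affine through `(vel_lim, 0)` and
`(vel_max, tau_a_max)` between, constant `tau_a_max` above. The stored
slope/intercept always satisfy `intercept = -slope * vel_lim`. The law as
written uses strict inequalities, leaving the breakpoints formally
unassigned; both one-sided limits coincide there, so the implementation
closes them by continuity — an unobservable choice. The torque engages
only on frames where the trunk ascends within a cycle whose peak flexion
exceeded the activation angle ψ_A.

**Percentage scaling.** Devices are characterized at a few percentages
(100/70/40 by default, the levels a characterization campaign would pick).
The remaining multiples of ten are filled by even spacing: differences
between adjacent anchors are distributed uniformly over the intermediate
steps, below the lowest anchor values fall evenly to 0 at 0%, and above
the highest anchor the value is held (there is no basis for extrapolating
beyond the strongest calibrated level). Velocity thresholds scale the same
way; every generated row's slope and intercept are re-derived from its own
breakpoints so the hinge invariants hold by construction. Percentages are
restricted to multiples of ten, as device UIs enforce; arbitrary
percentages are rejected rather than interpolated.

## Kinematics

Captures are uniformly sampled flexion-angle series (60 Hz by default,
matching common IMU rigs). Velocity is estimated by a centred moving
average (default 0.25 s) followed by a central finite difference;
the reflection padding keeps linear trends exact through the smoother.
Frames are labeled descend / ascend / hold with a symmetric threshold
(default 2 deg/s): with flexion increasing downward, *ascending* means
dθ_C/dt < 0, and the active law consumes the rectified ascent speed
max(0, -dθ_C/dt). Cycles span the flexion minima between successive
flexion peaks (peak detection requires a prominence of 20% of the motion
range); leading/trailing partial cycles are kept but flagged. The
activation mask re-evaluates per frame — an ascent interrupted mid-way
re-engages within the same cycle — because that is the observable
contract; whether real firmware latches instead is not knowable from
outside and is deliberately not emulated.

## Statics

Mechanics are sagittal-plane and scalar: the device is bilaterally
symmetric and its validation channel (chest force) is one-dimensional.
Per side, the chest pad and leg pad act at lever arms `d_tt` and `d_mt`
from the trochanter, so F_C = τ_E/d_tt and F_Lg = τ_E/d_mt; the pelvis
force F_R is computed as the residual that closes the device free body's
horizontal force balance (it is otherwise unquantified), and the device
weight splits between shoulders and pelvis with a configurable fraction
(default 0.5, an explicit assumption). Transferring a pad force to a
skeletal reference point adds the couple `offset x force`, which in the
sagittal plane is the scalar product of offset and force. Forces are
internal in N; chest forces are reported in kgf (divided by g = 9.80665)
because that is the load-cell unit.

## Calibration

Calibration reduces repeated captures per percentage to one averaged
chest-force curve (force vs flexion angle for passive, force vs ascent
speed for active) and extracts the keypoint anchors from it.

**Resampling and averaging.** Each trace is resampled onto a common grid
(default 200 points spanning the intersection of the traces' ranges) by
local polynomial least squares — a LOESS-style estimator whose window
(default half-width: 1% of the span) widens until it holds enough points
with sufficiently distinct abscissas for a well-posed fit. This estimator
was chosen over global interpolation for two reasons: it reproduces any
locally polynomial curve exactly, and it confines the influence of a kink
in the underlying law to the kink's own neighbourhood. The local degree
matches the curve family's section order: cubic for passive curves, linear
for the piecewise-linear active curves (where a local cubic can
extrapolate wildly across sampling gaps). Averaging across traces is
pointwise, with the pointwise standard deviation kept as dispersion.
Optional cleaning (median filter, range clipping) is available but off by
default; the generators' artifacts are handled structurally instead.

**Passive anchors.** The averaged force is converted to per-side torque
via τ = F·g·d_tt/2. Because the curve family is a spline *per section*,
its derivative may jump exactly at the characteristic angles, so the
torque at each angle is estimated from section-wise cubic fits that
exclude a guard band (default 2.5% of the span) around the bounding
angles; interior angles average their two adjacent sections' estimates,
and the clamped tail beyond the last angle contributes its region mean
(the constant's extrapolation-free estimate). The maximum torque is read
at the last characteristic angle — not the curve's global maximum, whose
location would be noise-dependent — and ratios are clipped to [0, 1] and
made non-decreasing, absorbing noise-level violations of the family's
invariants.

**Active anchors.** The hinge is fitted by an exhaustive search over cut
index pairs partitioning the grid into zero / linear / plateau regions,
with the closed-form least-squares line and plateau level computed per
partition from prefix sums — deterministic, and exact when the data are
exactly piecewise linear. Grid points within a guard band (default 5% of
the speed span) of the first-pass breakpoints mix two regimes and are
excluded before a single refit. If the fitted saturation speed lands at
the end of the data range, no plateau is observable and calibration fails
with a diagnostic rather than returning an extrapolated row. Passive and
active modes are calibrated separately, from separate capture sets;
hybrid captures are reserved for validation.

## Synthetic data

The generator emulates a characterization campaign from a known
ground-truth device: slow single flexion–extension cycles for the passive
mode (12 s period, 90° peak — slow enough that the active law stays
silent), five brisk ascents for the active mode (3 s period, 70° peak,
fast enough to sweep through the hinge's saturation), and free mixed
movement with optional half-ascents for hybrids; the default campaign is
3 captures × 3 percentages per mode plus 2 hybrids, i.e. 20 recordings.
Motion is raised-cosine with a configurable peak hold; angle noise is
white Gaussian added before smoothing. The load-cell channel is the
forward model's chest force plus white noise (default σ = 0.25 kgf, a
realistic cell-noise scale), plus two structural artifacts: a taring
offset fixed at the deepest-flexion frame, and descent contamination
proportional to descent speed (amplitude quoted at a 30 deg/s reference),
the simplest mechanism consistent with cells that keep registering the
wearer's lowering effort. All generators are bit-reproducible under fixed
seeds.

What the generator does **not** emulate: IMU drift, soft-tissue and
garment compliance, intersegmental coordination, asymmetric loading, or
any load distribution across pad surfaces. Passing round-trip tests
therefore demonstrates the pipeline's correctness and noise behaviour on
data with this structure — not that a physical device obeys the model.

## Risk scoring

The lumbar demand surrogate is the static gravitational moment
(m_trunk·g·c + m_hand·g·l)·sin θ_C. The per-posture scores map angle,
|angular acceleration|, force, torque and grip through configurable
monotone piecewise-linear score maps; the per-posture risks (weighted
score sums, unit weights by default) are averaged over frames and scaled
by a repetitions-per-minute rate, which is exposed rather than assumed
because how capture duration converts to a workday rate is
method-specific. Color bands follow the convention green < 25 ≤ yellow
< 40 ≤ red. The exoskeleton-aware recomputation subtracts the total
device torque from the demand, clamped at zero (over-assistance models a
fully unloaded joint, never a reversed one), and only the force and
torque scores see the change — the fixed-factor contract the tests check
bit-exactly. The score maps' shapes are package defaults with a
documented contract (non-negative, non-decreasing), not a reimplementation
of any proprietary method's calibrated internals; every property the
package guarantees (assistance monotonicity, fixed factors, bands) holds
for any configuration satisfying that contract.

## Validation

Per capture, the headline force metric is the mean *absolute* per-frame
difference between simulated and measured chest force, in kgf — absolute,
because signed means cancel and understate error; the convention is
recorded in the report. Active captures are compared under the
ascending-only filter ("active mod"): frames not labeled ascend are
zeroed in both series, removing the wearer's lowering effort that the
cells record but the device does not produce. Risk comparison runs the
identical pipeline on two torque sources: the model's τ_E, and the torque
implied by the measured chest force through the chest lever arm (negative
readings clamp to zero assistance). Reports serialize to JSON and a plain
text table; colors are labels, never terminal styling.

## Problem sizes and tolerances

Default problem sizes — 60 Hz captures of 13–16 s, 200-point curve grids,
20-seed noise studies, 1000-configuration equilibrium sweeps — keep the
full test suite and the acceptance script in the seconds-to-a-minute
range on a laptop-class machine while leaving every estimator
well-conditioned. Noise-free round trips are asserted at 1e-6 (relative
for anchors, kgf for per-frame force); the machinery achieves machine
precision there because every estimation step (local polynomial
resampling, section fits, cut-pair least squares) is exact on data the
model family actually generates. Equilibrium residuals are asserted at
1e-9. Noisy recovery is asserted as a rate (tau_a_max within 5% of truth
in ≥ 18 of 20 seeded runs) and a concentration check (pooled mean
absolute deviation within 3 standard errors of σ·√(2/π), the half-normal
mean).

## Known limitations

- The per-frame activation rule is one reading of an indirectly observed
  controller; real firmware may latch or hysterese.
- F_Lg uses a constant lever arm; thigh-angle dependence is not modeled.
- The risk surrogate is static and sagittal; inertial lumbar loading is
  outside its demand term (it enters only through the acceleration score).
- Calibration assumes the passive and active laws are separable; hybrid
  captures are never used for fitting, so uncertainty can accumulate in
  hybrid simulation.
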