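# Methods

This note documents the models behind `handrim`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical choices that matter when reading results.

## Protocol and friction model

The study conditions the package defaults to are a practice protocol of
9 sessions × 3 blocks × 4 min at a commanded wheel speed of 2.78 m/s
(10 km/h) on a roller ergometer that brakes the wheelchair with rolling
friction only. With friction coefficient μ and lumped system mass m, the
braking force is F = μ·m·g and the external power to hold speed v is
P = μ·m·g·v. Defaults μ = 0.011 and m = 69.3 kg give P ≈ 20.8 W at the
commanded speed, the protocol's nominal 21 W load. Mass is a single
configurable lump: the nominal load is reproduced with participant mass
alone, so no separate wheelchair mass is modelled. Gravity is fixed at
9.81 m/s². A coast-down trace decelerates at μ·g; `coast_down_mu` fits
v(t) by least squares and returns |slope|/g, which inverts the simulation
exactly in the noise-free case.

## Synthetic ergometer signals

Each side exerts half-sine torque pulses in time: smooth, single-peaked —
the typical shape of handrim torque profiles — and analytically convenient
(time-mean = 2/π × peak over the contact). Pulse duration is the true
contact angle converted to time at the commanded speed
(t_push = θ·r_wheel / v); pulses repeat at the configured push frequency;
the per-block push count is ⌊f·T⌋ by construction. When no peak torque is
prescribed, pulses are sized so the cycle-mean push force balances
friction, i.e. peak force = (π/2)·(μ·m·g/2)·(T_cycle/t_push) per side.

Wheel speed integrates m·dv/dt = F_total − μ·m·g. Because the force
profile is prescribed (independent of v), the solution is an exact
cumulative trapezoid sum on the sampling grid (second-order accurate;
cross-checked in the tests against an adaptive ODE solver). The default
initial speed is chosen so that the mean over complete cycles equals the
commanded speed — a uniform shift of the solution that still satisfies the
dynamics; starting exactly at a push onset would otherwise bias the
periodic orbit's mean ≈ 1% high. Non-physical configurations (pulses too
weak to sustain friction, so the speed collapses to zero mid-block) raise
a configuration error naming the offending parameter.

Gaussian noise (default SD 1 N) is added to the *recorded* force only; the
dynamics integrate the noise-free force, and both sides share the velocity
trace (symmetric rider). An optional asymmetry factor rescales left/right
amplitudes at constant total impulse. Ground truth (push onsets/offsets,
true contact angles and torque amplitudes) is returned alongside and
written to a `truth.json` sidecar on disk, for oracle tests.

## Push detection and per-push variables

The raw force is filtered with a 15 Hz 4th-order zero-phase Butterworth
filter; "4th-order zero-phase" is read as a 4th-order design applied
forward–backward (the conventional reading; magnitude response is
effectively 8th order, phase is zero — peak lag under one sample).

Segmentation operates on wheel torque τ = F·r_wheel (wheel radius
0.355 m): candidate intervals are runs of τ above half the onset
threshold containing at least one sample above it, where the onset
threshold is max(1.0 N·m, 10% of the block's median segment peak); gaps
under 0.05 s merge; intervals shorter than 0.05 s are dropped. Because a
fixed threshold clips ~5% of a half-sine (≈ 3° of contact angle at these
settings), interval edges then walk outward toward the torque zero
crossing. The walk requires torque to keep falling and to stay above twice
a robust noise estimate (1.4826 × MAD of the inter-push gap samples):
without the falling/noise-floor conditions, the zero-phase filter's
smeared pulse tails plus noise let edges run far into the gap (errors up
to ~40° were observed). On clean signals the refinement recovers true
edges exactly; at the default noise the per-push worst error is ≈ 14°
with a mean bias ≈ −1.5°, negligible after session averaging. Whether the
original instrumentation thresholds on force, torque or power is not
documented; all constants are configurable (`DetectionSettings`).

Per push, work is the trapezoidal integral of F·v, contact angle the
integral of wheel angular velocity (measured speed, not hand kinematics),
and mean torque/power are trapezoidal *time averages* — sample means would
undercount a 0.2 s half-sine by ~5% through the endpoint zeros. Cycle time
is onset-to-next-onset and is undefined for the final push in a window
(excluded from means). Session aggregation uses pushes fully inside the
last 60 s of each block (steady state assumed), per side, then
side-averages, then block-averages; a block window with no detected pushes
contributes missing values, never zeros, and is recorded.

## Spirometry and efficiency

Breaths arrive as a Poisson process with a 4 s mean inter-breath interval
(≈ 15 breaths/min). Breath VO₂ is set so that energy expenditure averages
max(PO/GME_true × 100, 100 W): the 100 W resting floor keeps simulated
efficiency finite and below 100% at vanishing loads, and is irrelevant at
protocol loads (420 W at 21 W and 5%). VCO₂ = RER_true × VO₂; both
channels carry independent multiplicative noise (default SD 5%). Heart
rate is affine in power (80 bpm + 2.5 bpm/W + noise), a crude but
sufficient stand-in since HR is a pass-through outcome.

Energy expenditure is recovered from measured breaths through the Garby–
Åstrup oxygen energetic equivalent e = 4.940·RER + 16.040 kJ/L O₂
(EE = VO₂[L/s]·e·1000). Which equivalent the original CPET firmware used
is unknowable; the constants are exposed in `EnergeticsSettings`, and the
athlete-reference efficiency figure is computed from printed EE and PO, so
it is formula-independent. Efficiency is GME = PO/EE × 100. The RER screen
(discard GME when mean RER > 1.0, boundary inclusive) applies once per
session, to the session-mean RER, not per block. Discarded efficiency is
null and reduces the n of downstream t-tests.

## Hand paths and pattern classification

The marker generator plays the push phase on the rim circle (arc centred
on top-dead centre spanning the true contact angle) and the recovery as
the reverse arc with a radial offset profile: +A·sin(πs) for SLOP (over
the rim), −A·sin(πs) for SC (under), A·sin(2πs) for DLOP (over then
under), and a within-band wiggle for ARC, with loop amplitude A = 30% of
rim radius — well clear of the 5% classification band. Marker noise
defaults to 1 mm.

The classifier scores recovery samples against the rim circle: vertical
deviation from the upper rim arc when |x| < rim radius and y > 0, radial
deviation otherwise (matching the sagittal visual judgment). An excursion
requires ≥ 5 consecutive samples beyond the ±5% band. Per recovery,
(above ∧ below) → DLOP, above → SLOP, below → SC, neither → ARC; the
trajectory label is the majority over recoveries in the window (ties →
most recent). Recovery phases are the complement of push intervals; for
marker-only input, rim proximity (within the band) defines contact — and a
path that never leaves the band is labelled ARC directly, since that is
the pattern's definition. How raters in practice separate push from
recovery visually is not documented; the proximity convention is this
package's choice.

Session labels follow block majority with last-block tie-break, applied
per rater, then majority across raters (same tie rule, documented — the
cross-rater tie case is not specified anywhere and essentially never
arises with three raters and four categories). Fleiss' κ uses the
statsmodels implementation behind the module surface; a single-category
table makes expected agreement 1 and κ undefined — reported as degenerate,
not raised. Interpretation bands follow Landis–Koch.

## Statistics

The learning model is outcome ~ session + speed + (1 + session | subject),
fitted by maximum likelihood (not REML — the likelihood-ratio test
compares fixed-effect structures), with the practice effect tested by LRT
(χ², 1 df) against the model without the session term. Convergence and
boundary (singular) fits are flagged honestly in the result. Calibration:
at 200 null simulations (15 subjects × 9 sessions, random intercept SD 1,
random slope SD 0.05, residual SD 1, speeds on the study schedule) the
rejection rate at α = 0.05 is ≈ 0.06. A perfectly affine outcome (zero
residual) makes the variance components unidentifiable; that case
short-circuits to the exact least-squares solution, flagged `degenerate`.

The expert comparison is a one-sample t-test of final-session values
against the athlete reference. P-values are one-sided in the direction of
the observed difference — the convention under which t = 0 gives p = 0.5,
matching the reference statistics table; a `sided="two"` switch is
provided. (Some printed rows of that table, e.g. mean torque t = 3.22 with
p = 0.03, are not consistent with either convention at face value; the
package reports the exact p for the chosen convention.) Zero SD with a
nonzero difference yields an infinite t, reported as such. No
multiple-testing correction is applied (α = 0.05 per test, as in the
protocol).

## Study generator and what passing tests mean

`simulate_study` strings the generators into a full practice study. The
per-session group trajectories (speed, cycle time, contact angle,
efficiency, RPE) default to the bundled reference session means
(`handrim.reference`), with persistent per-subject offsets drawn at 0.8 ×
the printed between-subject SDs — shrunk so joint draws stay physically
consistent (push shorter than cycle; additional clamps guard the tails).
Body mass varies between subjects (SD 9.87 kg × 0.8) so the external-power
spread matches the cohort. The RER trajectory falls 0.97 → 0.87 with
subject SD 0.03, reproducing occasional early-session RER > 1.0 discards.
Pre/post techniques follow the observed transition counts (3 ARC→DLOP,
2 DLOP→DLOP, 2 SC→SC, 6 SLOP→DLOP, 2 SLOP→SLOP). All randomness derives
from one integer seed; identical seeds give bitwise-identical outputs.

The generator emulates steady cyclic propulsion with stationary per-block
parameters. It does **not** emulate: within-block fatigue or drift,
braking/negative-power phases, push-to-push variability in amplitude or
timing, 3-D force direction (so no fraction of effective force),
glove–rim coupling, VO₂ on-kinetics at block starts, or air drag (lab
setting). Passing round-trip tests therefore shows the *analysis chain* is
correct under realistic signal and noise scales — not that the pipeline
handles every artefact of field recordings.

## Problem sizes and numerical choices

Unit tests use 30–120 s blocks; the end-to-end checks run one full
15 × 9 × 3-block study at 100 Hz and 200 null-model simulations, sizes
chosen to exercise the complete protocol while keeping a test cycle in the
low minutes. Filtering requires > 45 samples (padding of the 4th-order
sosfiltfilt); cutoffs at or above Nyquist and non-uniform time bases
(spread > 1 μs) are rejected. CSV gaps larger than 5 nominal steps in
uniformly sampled streams are warned about and never interpolated — the
record is rejected as non-uniform. Breath files are event-based, so block
pauses there are not treated as gaps. Optimizer: MixedLM lbfgs/bfgs,
maxiter 200; LRT χ² is clipped at 0.

## Known limitations

- The automated pattern rule operationalizes a human visual judgment; on
  real marker data, band width and run length (`ClassifierSettings`) may
  need tuning, and hybrid paths near the band will be sensitive to ε.
- Push detection assumes force referred to the wheel and a non-negative
  velocity; backward rolling and active braking are out of scope.
- The one-sample comparison treats the single athlete session as a fixed
  reference value, ignoring his measurement variability.
- Mixed-model small-sample inference relies on the asymptotic χ²; with 15
  subjects the test runs slightly liberal (≈ 0.06 at α = 0.05).
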