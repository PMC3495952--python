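# Methods

## Model and coordinate conventions

The walker is a planar point mass `m` at the hip, carried by rigid
massless legs of length `L` (hip to ankle) with rigid massless feet of
length `l` (ankle to toe). Each step re-anchors the coordinate frame
at the leading heel/ankle contact B; `+x` is the direction of travel,
`+y` up. The hip angle `θ` of the leading leg is measured from the
vertical, positive while the mass is behind the contact, so a step runs
`θ: +α → −α` with `θ̇ < 0`. The mass sits at `C = (−L sin θ, L cos θ)`
and the trailing toe at `A = (−a, 0)`, `a = 2L sin α − l`.

The trailing-ankle angle `ψ` is the interior angle of triangle ADC at
the ankle D, positive toward plantar flexion; at double-stance onset
(flat trailing foot) `ψ₀ = π/2 − α`. Of the two circle-intersection
solutions for D we take the branch continuous with the flat-foot
configuration (heel rising, ankle at non-negative height) — the
physical heel-lift push-off. Angles are radians, units SI throughout.

The swing leg is massless, so its dynamics are irrelevant and scuffing
is ignored; the inter-leg angle is reset to `2α` at no energetic cost
before each heel strike. These idealisations make the model
energetically a powered rimless wheel: fixed energy in per step (spring
work `W = ½k(μ − ψ₀)²`), speed-squared energy out per collision.

## Numerical integration and events

The hybrid system is integrated by an adaptive Dormand–Prince 5(4)
Runge–Kutta stepper specialised to the two-dimensional state
`(θ, θ̇)` and compiled with numba (the entrainment scans run hundreds
of 300-stride walks). Defaults:

* per-step error-norm tolerance `tol = 1e-11` (configurable through
  `NumericsConfig`); halving it changes the simulated step period by
  less than `1e-8` s;
* state events — toe-off (`ψ = μ`, equivalently `θ = θ_f`), heel
  strike (`θ = −α`), fall-back (`θ̇ = 0`) and the extension cap — are
  localised by bisection on the cubic Hermite interpolant of the
  accepted step, to machine precision in the event function;
* pulse on/off instants are *time* events: the step size is capped so
  the integrator lands on them exactly;
* ground-reaction-force monitors (`F_B` in double stance, `f` in
  single stance) record minima at every accepted point; by default they
  flag rather than halt (`strict_grf=True` converts a negative minimum
  into a FLY_OFF termination). Along the default period-one gait both
  stay positive everywhere, with `min F_B ≈ 149.3` N at double-stance
  onset.

Degenerate starts (`θ̇₀ ≥ 0` at `θ = α`) terminate FALL_BACK
immediately. There is no randomness anywhere in the simulator;
identical configurations produce identical outputs.

Energy audits close to ~`2e-8` J per step (double-stance work balance,
single-stance conservation) and the collision kinetic-energy ratio is
`cos² 2α` to machine precision, since the collision map is algebraic.

## Calibration

`k = 87.3 N·m/rad` makes the spring torque at double-stance onset,
`k(μ − ψ₀)`, equal the peak plantar-flexion torque of normal human
gait, taken as 17% of body weight × leg length (`0.17 mgL ≈ 133.4`
N·m). The just-vault-over stiffness evaluates to `k_C ≈ 67.5` N·m/rad
(closed form, cross-checked against a bisection on simulated step
completion to 0.1%), and the shipped `k` also stays below the fly-off
level, so the period-one gait exists and is unique: step period
`τ₀ ≈ 0.9666` s, average speed `2L sin α / τ₀ ≈ 1.035` m/s. Step
period and speed are defined per *step*; the stride period is `2τ₀` by
symmetry.

## Perturbation experiments

The standard pulse train has amplitude `A = 0.1·k(μ − ψ₀) ≈ 13.35`
N·m, width `Δ = 0.1` s, period `τ_p`, initial offset `δ`, and belongs
to one designated leg (matching a one-ankle experimental protocol). It
contributes to the dynamics only while that leg is the trailing leg in
double stance; swing-phase portions are nullified, so pulse work per
stride is non-negative and bounded by `A·(π − ψ₀)`.

**Entrainment criterion** (the convergence plots motivate it; nothing
sharper is needed): 300 strides per run; entrained iff every one of the
last 30 stride periods is within 1 ms of `τ_p` *and* the locked phase
varies by at most 0.01 over that window. The locked phase is
`Φ = (pulse onset − toe-off)/stride period`, wrapped to `[−0.5, 0.5)`.

**Basin membership** requires entrainment for *all* tested offsets
(default: 8 equispaced `δ`), reflecting the observation that the locked
phase is a global attractor. The default scan covers `2τ₀ ± 0.1` s at
2 ms resolution. Under the default settings the basin measures 3.9% of
`2τ₀`, lies entirely at `τ_p ≤ 2τ₀`, and entrainment fails from 80 ms
of detuning; the locked phase sits just before toe-off
(`Φ ≈ −0.03`).

### Toe-off gating for pulses that outlast double stance

What happens when a pulse is still active at `ψ = μ` is the one point
where the physical idealisation underdetermines the algorithm. Both
readings are implemented and selectable per `PulseTrain`:

* `TRUNCATE_AT_MU` (default): double stance always ends at `ψ = μ`;
  the remaining pulse is nullified.
* `EXTEND_WHILE_POSITIVE`: since a massless trailing foot pushes as
  long as the total ankle torque is positive, double stance continues
  on the pulse torque alone until pulse-off or a linkage cap
  `ψ = π − ε_cap` (default `ε_cap = 0.01` rad), whichever comes first;
  reaching the cap forces toe-off and the walk continues (it is not
  treated as a terminating singularity).

Truncation is the default because it is the policy that produces the
clean period-one entrainment phenomenology: basin ≈ 3.9–4.1% of `2τ₀`
(2 ms grid; 3.93% with 8 offsets, 4.14% with 4), failure threshold at
80 ms, offset-independent locking at the end of double stance. Under
extension, a pulse straddling toe-off drives the linkage toward its
singularity, where `ψ′(θ)` blows up and the pulse dumps ~7 J in a few
milliseconds; at moderate detuning the walk then settles into
alternating period-two states (one stride pulsed, one not) and the
all-offsets basin fragments to ≈ 1.7%. The extension policy remains
available for sensitivity studies, and `basin_scan` accepts either.

### Speed-vs-phase probes

Three measures of "average speed vs pulse onset phase" are provided,
because the quantity is probe-dependent:

* `step` — one pulse fired from the limit cycle; speed = step length /
  duration of the step containing the pulse's effective portion. This
  is the literal per-step reading; its range across phases is 5.7% of
  the unperturbed speed (the bound from finite pulse work is < 9%).
* `stride` — same probe, speed over the two-step stride, capturing the
  energy the pulse carries through the next collision.
* `sustained` — one pulse per stride anchored at a fixed phase of each
  stride; the converged stride period is reported as a speed. Each
  point of this curve is an actually achievable locked state, so it is
  the right curve for converting speed spans into *entrainable stride
  periods* (`period = stride length / speed`).

The sustained curve's maximum reproduces the scanned basin width
(main-branch estimate 4.1%), and its early-double-stance negative-slope
branch — pulses applied where the linkage gearing `|ψ′|` is still
small — spans only 0.126% of `2τ₀`, a secondary basin more than thirty
times narrower than the main one and irrelevant in practice.

## Problem sizes

The shipped experiments use: 300 strides per entrainment run, 2 ms ×
8-offset grids for the basin scan, 201-point phase grids for the
speed-vs-phase curves, and 40 strides to converge each sustained probe.
These sizes leave all reported quantities converged at the third
significant figure; the acceptance script completes in well under a
minute on one CPU.

## Known limitations

* Multi-period (period-2+) gait branches are not searched for; the
  analysis targets the period-one gait and its basin. (The period-two
  states observed under the extension gating are reported as
  non-entrainment, not characterised further.)
* The feet are point contacts at toe and heel; there is no rollover,
  compliance, friction cone or slipping.
* Only plantar-flexion (accelerating) pulses are modelled; the model
  cannot entrain to periods above `2τ₀`, whereas human subjects also
  entrain, narrowly, to slower perturbations — a genuine limitation of
  the one-degree-of-freedom idealisation.
* The synthetic experiments probe exactly the deterministic model: no
  sensorimotor noise, no step-to-step morphological variability. Tests
  passing here validate the mechanics and the numerics, not any claim
  about variability observed in real gait data.
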