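# anklewalker

A simulator and analysis toolkit for a *state-determined* model of
bipedal walking: a point mass on rigid massless legs whose only
actuation is a pre-loaded torsional spring at the trailing ankle,
released at every heel strike. Despite having a single degree of
freedom and no oscillator or planner anywhere, the model walks with an
asymptotically stable periodic gait, entrains to periodic mechanical
perturbations over a narrow basin of periods, and phase-locks the
perturbation to the end of double stance — the salient limit-cycle
behaviours observed in human treadmill experiments. It is aimed at
researchers in computational biomechanics and motor control who need a
transparent, fully reproducible hybrid-dynamics testbed for
entrainment and gait-stability questions.

## The model

One step has two continuous phases joined by an impact:

* **Double stance** — from heel strike (hip angle `θ = +α`) until the
  ankle spring releases. The model is an actuated four-bar linkage
  (ground, trailing foot `l`, trailing leg `L`, leading leg `L`); the
  trailing-ankle torque is `T = k(μ − ψ)` for ankle angle `ψ ≤ μ`, zero
  afterwards. In generalized-force form

      m L² θ̈ = m g L sin θ + T(ψ) ψ′(θ),

  with `ψ(θ)` from the linkage: `ψ = arccos[(l² + L² − AC²)/(2lL)]`,
  `AC² = a² + L² − 2aL sin θ`, toe offset `a = 2L sin α − l`.
* **Single stance** — an inverted pendulum, `θ̈ = (g/L) sin θ`, until
  the next heel strike at `θ = −α`.
* **Heel strike** — an inelastic collision that scales the angular
  velocity by `cos 2α` (kinetic energy by `cos² 2α`) and swaps legs.

Sampling at heel strikes collapses the dynamics to a one-dimensional
step-to-step (Poincaré) map with the closed form

    f(x) = −cos 2α · √(x² + c),    c = k(μ − ψ₀)² / (m L²),

because the spring injects the fixed work `W = ½k(μ − ψ₀)²` per step
while the collision removes energy in proportion to speed squared. The
fixed point is the period-one gait; the Floquet multiplier is exactly
`cos² 2α` (0.25 for `α = π/6`), so collisional dissipation is itself
the stabilising mechanism. A period-one gait exists iff `k` exceeds the
just-vault-over stiffness `k_C = 2mgL(1 − cos α) sin² 2α /(μ − ψ₀)²`
and stays below the fly-off level at which the leading heel unloads.

Entrainment experiments superimpose a square torque pulse train
(amplitude 10% of peak ankle torque, width 0.1 s, period `τ_p`) on one
ankle; pulses are nullified whenever that leg is in swing, so they can
only add energy, which is why the basin of entrainment lies entirely at
`τ_p ≤ 2τ₀` (the unperturbed stride period).

Default parameters (adult-human morphology): `m = 80` kg, `L = 1` m,
`l = 0.2` m, `g = 9.81` m/s², `α = π/6`, `μ = 2.576` rad, and
`k = 87.3` N·m/rad, calibrated so the peak ankle torque matches 17% of
body weight × leg length.

## A worked example

```bash
python examples/01_period_one_gait.py
```

prints

```
fixed point: theta_dot* = -0.92205 rad/s, v_C = 1.84409 m/s
step period tau_0      = 0.966615 s
double-stance duration = 0.346433 s
average forward speed  = 1.034538 m/s
min leading-heel GRF   = 149.31 N (> 0: no fly-off)
ankle spring work      = 102.02 J per step
energy residuals: double stance +2.45e-08 J, single stance +6.08e-09 J, collision KE-ratio error +0.00e+00
post-step velocity returns to the fixed point: -0.922046600 vs -0.922046600
```

The walker settles into a 0.967 s step at 1.03 m/s — slow human
walking — with every ground reaction force positive (the gait is
physically realisable) and the spring work per step exactly balancing
the collision loss, to the integrator's event-localisation floor.

The other examples cover stability (`02`, Floquet multiplier 0.25000
numeric vs 0.25 analytic and fourfold-per-step error decay),
entrainment with phase locking at the end of double stance (`03`), and
the basin scan plus speed-vs-phase curve (`04`). The same experiments
are available from the thin CLI:

```bash
walker stepmap
walker entrain --tp 1.8841 --delta 0.3 --strides 300 --out strides.csv
walker scan --tp-step 0.002 --deltas 8 --out basin.csv
walker vphase --grid 201 --measure sustained --out vphi.csv
```

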