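"""Simulate the unperturbed period-one gait and audit its energetics.

The walker starts at the analytic fixed point of the step-to-step map
(post-collision angular velocity theta_dot* ~ -0.922 rad/s) and takes
one full step: spring-powered double stance, pendular single stance,
inelastic heel strike.  Printed: the step period (~0.967 s), average
forward speed (~1.03 m/s, slow human walking), the minimum leading-heel
ground reaction force (~149 N, at double-stance onset -- positive, so
the foot never lifts), and the per-phase energy residuals (~1e-8 J, the
integrator's event-localisation floor).
"""

from anklewalker import (
    HybridState,
    WalkerParams,
    energy_audit,
    fixed_point,
    simulate_step,
)

params = WalkerParams()
thd_star, v_C = fixed_point(params)
print(f"fixed point: theta_dot* = {thd_star:.5f} rad/s, v_C = {v_C:.5f} m/s")

result, trajectory, nxt = simulate_step(
    HybridState(theta=params.alpha, theta_dot=thd_star), None, params
)
print(f"step period tau_0      = {result.duration:.6f} s")
print(f"double-stance duration = {result.double_stance_duration:.6f} s")
print(f"average forward speed  = {params.step_length / result.duration:.6f} m/s")
print(f"min leading-heel GRF   = {result.min_grf_leading:.2f} N (> 0: no fly-off)")
print(f"ankle spring work      = {result.ankle_work:.2f} J per step")

audit = energy_audit(trajectory, params, result)
print(
    f"energy residuals: double stance {audit.double_stance_residual:+.2e} J, "
    f"single stance {audit.single_stance_residual:+.2e} J, "
    f"collision KE-ratio error {audit.collision_ke_ratio_error:+.2e}"
)
print(
    "post-step velocity returns to the fixed point: "
    f"{nxt.theta_dot:.9f} vs {thd_star:.9f}"
)
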