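# Standard entrainment protocol: pulse train ~50 ms faster than the
# natural stride period (2*tau_0 ~ 1.9332 s).  Run with:
#   walker entrain --config examples/configs/entrainment_minus50ms.yaml --tp 1.8841 --delta 0.3
model: {}          # standard parameter set
numerics:
  tol: 1.0e-11
pulse:
  amplitude_fraction: 0.1   # of peak ankle torque -> 13.35 N*m
  width: 0.1                # s
  period: 1.8841            # s
  offset: 0.3               # s
  perturbed_leg: LEG_A
  gating_policy: truncate
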