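# A stiffer ankle spring: faster gait, stronger push-off.  Still below
# the fly-off limit.  Run with:
#   walker stepmap --config examples/configs/stiff_spring.yaml
model:
  k: 110.0
numerics:
  tol: 1.0e-11
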