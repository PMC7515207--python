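# Activator-repressor clock: small activator (oscillatory) baseline.
name: fig7b
model:
  kind: clock
  params: {ra_rel: 1.0e-3, xa_star: 1.0, xr_star: 1.0}
run: ode
t_end: 400.0
clock_mode: qssa
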