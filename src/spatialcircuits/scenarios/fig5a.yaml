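# Transcription vs gene location: pole-localized gene, PDE vs reduced ODE.
name: fig5a
model:
  kind: txtl
  params: {x_star: 1.0, rs_rel: 0.3, rm_rel: 0.88, rR_rel: 0.44, epsilon: 1.0e-3}
run: both
grid: 200
t_end: 8.0
theta: auto
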