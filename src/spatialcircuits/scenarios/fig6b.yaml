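# Repression by a large dimerizing repressor of a pole-localized gene.
name: fig6b
model:
  kind: repressor
  params: {x_star: 1.0, r_rel: 1.0}
run: ode
t_end: 20.0
theta: auto
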