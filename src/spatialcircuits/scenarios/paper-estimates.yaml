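# Worked-example radii from the literature: RNAP 6.5 nm (r/r*=0.3),
# mRNA 20 nm (0.88), ribosome 10 nm (0.44); gene at the cell pole.
name: paper-estimates
model:
  kind: txtl
  params: {x_star: 1.0, rs_rel: 0.3, rm_rel: 0.88, rR_rel: 0.44}
run: ode
t_end: 8.0
theta: auto
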