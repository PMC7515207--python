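# Translation vs mRNA/ribosome radii: tiny RNAP so the gene location is immaterial.
name: fig5b
model:
  kind: txtl
  params: {x_star: 0.5, rs_rel: 1.0e-3, rm_rel: 0.88, rR_rel: 0.44, epsilon: 1.0e-3}
run: ode
t_end: 8.0
theta: auto
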