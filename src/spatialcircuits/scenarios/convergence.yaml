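# Case I binding pair for the epsilon-convergence study (PDE vs reduced ODE).
name: convergence
model:
  kind: circuit
  name: case1-binding
  epsilon: 1.0e-2
  density: {kind: logistic}
  species:
    - {name: E, r_rel: 0.88}
    - {name: S, r_rel: 0.44}
  reactions:
    - {enzyme: E, substrate: S, a: 1.0, d: 5.0, kappa: 1.0}
  productions:
    E: {alpha_bar: 1.0}
    S: {alpha_bar: 1.0}
run: both
grid: 200
t_end: 5.0
theta: auto
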