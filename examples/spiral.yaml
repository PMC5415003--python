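# Minimal spiral-wave simulation as a declarative device ring:
# cross-field initial conditions, diffusion substep, Barkley kinetics.
# Run with:  cardiogrid run examples/spiral.yaml
macros:
  u: 0
  v: 1
  i: 2
state:
  xmax: 42
  ymax: 42
  vmax: 3
  hx: 0.4
globals:
  ht: 0.02
devices:
  - device: k_func
    nowhere: true
    pgm: "begin = eq(t,0); out = eq(mod(t,100),0); end = ge(t,400)"
  - device: k_func
    when: begin
    name: IC
    pgm: "u[u] = gt(y,21); u[v] = 0.4*lt(x,21)"
  - device: stop
    when: end
  - device: diffstep
    v0: "[u]"
    v1: "[i]"
    ht: 0.02
    hx: 0.4
    D: 1.0
  - device: euler
    v0: "[u]"
    v1: "[v]"
    ht: 0.02
    ode: fhnbkl
    par: {a: 0.8, b: 0.01, eps: 0.02}
  - device: singz
    when: out
    v0: "[u]"
    v1: "[v]"
    c0: 0.5
    c1: 0.25
    prefix: tip
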