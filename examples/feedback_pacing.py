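"""Feedback-controlled stimulation assembled entirely from devices.

A FitzHugh-Nagumo pulse travels along a 1D cable.  A registration
electrode (reduce device) monitors the voltage in a small window; a
Poincare detector latches the front-arrival time Tfront; a feedback
k_func opens a stimulus window Del after the front, lasting Dur; the
stimulus k_func adds the force to the diffusion-current layer.  This is
the standard low-voltage defibrillation protocol skeleton.
"""

from cardiogrid.engine import (Diff, EulerDevice, KFunc, KPoincare, KPrint,
                               Reduce, StateGrid, Stop, run_ring)

ht, Del, Dur, Amp = 0.02, 5.0, 0.5, 2.0
state = StateGrid.from_box(80, 3, 1, vmax=3, h=0.5)
state.globals.update({"ht": ht, "Del": Del, "Dur": Dur, "Amp": Amp,
                      "Tstart": 0.1, "Tfront": -1000.0,
                      "signal": -2.0, "front": 0.0})
monitor = KPrint(expressions=["T", "force", "signal"])
ring = [
    KFunc(nowhere=True, pgm=f"T = t*{ht}; begin = eq(t,0); end = ge(T,40)"),
    KFunc(when="begin", pgm="u0 = ifle0(x-6, 1.7, -1.04); "
                            "u1 = ifle0(x-6, 0.7, -0.66)"),
    Reduce("max", v0=0, result="signal", x0=55, x1=59, y0=1, y1=1),
    KPoincare(pgm="front = signal; Tfront = T"),
    KFunc(nowhere=True, name="feedback",
          pgm="force = ht*Amp*ge(T,Tstart)*ge(T,Tfront+Del)"
              "*le(T,Tfront+Del+Dur)"),
    Diff(v0=0, v1=2, D=1.0, hx=0.5),
    KFunc(when="force", name="stim", pgm="u2 = u2 + force"),
    EulerDevice(v0=0, v1=1, ht=ht, ode="fhncub",
                par={"eps": 0.3, "bet": 0.71, "gam": 0.5, "Iu": "@2"}),
    monitor,
    Stop(when="end"),
]
run_ring(ring, state)

rows = [line.split() for line in monitor.lines]
t_on = [float(r[0]) for r in rows if float(r[1]) > 0.0]
print(f"front reached the electrode at T = {state.globals['Tfront']:.2f}")
print(f"stimulus window: T = {t_on[0]:.2f} .. {t_on[-1]:.2f} "
      f"(delay {t_on[0]-state.globals['Tfront']:.2f}, "
      f"duration {t_on[-1]-t_on[0]:.2f})")
# The stimulus switches on one delay (Del) after the registered front
# and stays on for Dur, to one time step.
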