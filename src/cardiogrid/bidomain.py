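"""Bidomain operator splitting.

The bidomain model couples a parabolic equation for the transmembrane
voltage V with an elliptic equation for the intracellular potential
Phi_i:

    chi (Cm dV/dt + I_ion) = div(sigma_i grad Phi_i) - chi I_ext,
    div((sigma_i + sigma_e) grad Phi_i) = div(sigma_e grad V).

One time step splits into four substeps, each one device:

    diff(1):   S1 = div(D_e grad V)
    elliptic:  div((D_e + D_i) grad Phi_i) = S1
    diff(2):   S2 = div(D_i grad Phi_i)
    euler:     dV/dt = kinetics(V) + S2

When the extracellular tensor is proportional to the intracellular one
(D_e = nu D_i), Phi_i is proportional to V and the scheme reduces to a
monodomain model with D_eff = nu/(1+nu) D_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diffusion import apply_diffusion, build_tensor, build_weights
from .elliptic import EllipticProblem, EllipticSolver
from .engine import Diff, EllipticDevice, EulerDevice
from .geometry import GeometryGrid

__all__ = [
    "BidomainConfig",
    "BidomainStepper",
    "bidomain_devices",
    "bidomain_substep_sequence",
    "planewave_exact",
]


@dataclass
class BidomainConfig:
    """Tensors, layer allocation and controls for the splitting scheme.

    Membrane capacitance and surface-to-volume scale factors default to
    1 and are folded into the diffusivities.  Layers: V (voltage),
    phi (intracellular potential), s (scratch, recycled between the
    elliptic right-hand side S1 and the parabolic source S2).
    """

    Di_par: float = 2.0
    Di_trans: float = 0.2
    De_par: float = 8.0
    De_trans: float = 2.0
    v_layer: int = 0
    phi_layer: int = 1
    s_layer: int = 2
    ht: float = 0.01
    hx: float | None = None
    ode: str = "zfk"
    par: dict = field(default_factory=lambda: {"alpha": 0.13})
    elliptic: dict = field(default_factory=dict)   # tolerance, pin, ...

    def __post_init__(self):
        if min(self.Di_par, self.Di_trans, self.De_par, self.De_trans) <= 0:
            raise ValueError("all four diffusivities must be positive")
        if len({self.v_layer, self.phi_layer, self.s_layer}) != 3:
            raise ValueError("V, phi and scratch layers must be distinct")


def bidomain_devices(cfg: BidomainConfig, **restriction) -> list:
    """The four-substep device sequence, in execution order."""
    ell = dict(cfg.elliptic)
    ell.setdefault("tolerance", 1e-8)
    return [
        Diff(v0=cfg.v_layer, v1=cfg.s_layer, Dpar=cfg.De_par,
             Dtrans=cfg.De_trans, hx=cfg.hx, name="diff_e", **restriction),
        EllipticDevice(v0=cfg.s_layer, v1=cfg.phi_layer, Dpar=cfg.De_par + cfg.Di_par,
                       Dtrans=cfg.De_trans + cfg.Di_trans, hx=cfg.hx,
                       name="elliptic", **ell, **restriction),
        Diff(v0=cfg.phi_layer, v1=cfg.s_layer, Dpar=cfg.Di_par,
             Dtrans=cfg.Di_trans, hx=cfg.hx, name="diff_i", **restriction),
        EulerDevice(v0=cfg.v_layer, v1=cfg.v_layer, ht=cfg.ht, ode=cfg.ode,
                    par={**cfg.par, "Iu": f"@{cfg.s_layer}"},
                    name="euler", **restriction),
    ]


def bidomain_substep_sequence(state, cfg: BidomainConfig, **restriction):
    """Execute the four substeps once on a state grid (one turn)."""
    devices = bidomain_devices(cfg, **restriction)
    for d in devices:
        d.setup(state)
    for d in devices:
        d.run(state)
    return state


class BidomainStepper:
    """Stand-alone stepper over plain arrays (no device ring overhead).

    Precomputes the three stencils (extracellular, intracellular,
    summed) and the multigrid hierarchy once; :meth:`step` advances V
    and Phi_i by one splitting step, warm-starting the elliptic solve
    from the previous potential.  ``free_mask`` restricts updates to a
    subgrid with Dirichlet data outside (the verification problem);
    without it the no-flux + pin configuration is used.
    """

    def __init__(self, geom: GeometryGrid, Di=(2.0, 0.2), De=(8.0, 2.0),
                 kinetics=None, free_mask: np.ndarray | None = None,
                 pin=None, upin: float = 0.0, tolerance: float = 1e-8,
                 vcycles: int = 50, upper_level: int = 10):
        self.geom = geom
        self.We = build_weights(geom, build_tensor(geom, *De))
        self.Wi = build_weights(geom, build_tensor(geom, *Di))
        Dsum = (De[0] + Di[0], De[1] + Di[1])
        Wsum = build_weights(geom, build_tensor(geom, *Dsum))
        self.kinetics = kinetics or (lambda V: V * (V - 0.13) * (1.0 - V))
        self.free_mask = free_mask
        problem = EllipticProblem(
            geom, Wsum, rhs=np.zeros(geom.shape), pin=pin, upin=upin,
            free_mask=free_mask, tolerance=tolerance, vcycles=vcycles,
            upper_level=upper_level, coarse_diffusivities=Dsum,
        )
        self.solver = EllipticSolver(problem)
        if free_mask is not None:
            self._upd = free_mask & geom.tissue_mask
        else:
            self._upd = geom.tissue_mask
        self.last_info = None

    def step(self, V: np.ndarray, phi: np.ndarray, k: float):
        """One splitting step; V and phi are updated in place."""
        S1 = apply_diffusion(V, self.We)
        phi_new, info = self.solver.solve(S1, u0=phi)
        self.last_info = info
        phi[...] = phi_new
        S2 = apply_diffusion(phi, self.Wi)
        m = self._upd
        V[m] += k * (self.kinetics(V[m]) + S2[m])
        return V, phi


def planewave_exact(X, Y, t, theta: float = 0.0, s: float = -5.0,
                    alpha: float = 0.13, Di=(2.0, 0.2), De=(8.0, 2.0)):
    """Exact plane-wave solution of the one-component bidomain system.

    For kinetics f(V) = V(V-alpha)(1-V) the system has travelling-front
    solutions

        V* = [1 + exp(xi / sqrt(2 D*))]^{-1},   Phi_i* = K V*,
        xi = x cos(theta) + y sin(theta) - s - c t,

    with directional diffusivities D*_i = Di_par cos^2 + Di_trans sin^2
    (same for e), harmonic combination D* = D*_i D*_e / (D*_i + D*_e),
    potential ratio K = D*_e / (D*_i + D*_e) and front speed
    c = sqrt(2 D*) (1/2 - alpha).

    Returns (V*, Phi_i*, info) where info holds c, K, D*.
    """
    ct, st = np.cos(theta), np.sin(theta)
    Dsi = Di[0] * ct**2 + Di[1] * st**2
    Dse = De[0] * ct**2 + De[1] * st**2
    Dstar = Dsi * Dse / (Dsi + Dse)
    K = Dse / (Dsi + Dse)
    c = np.sqrt(2.0 * Dstar) * (0.5 - alpha)
    xi = X * ct + Y * st - s - c * t
    V = 1.0 / (1.0 + np.exp(xi / np.sqrt(2.0 * Dstar)))
    return V, K * V, {"c": float(c), "K": float(K), "Dstar": float(Dstar)}
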