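"""Excitation-kinetics model library.

Models come in two formats, mirroring the two classes of kinetics
solvers:

``rhs``
    A plain right-hand-side function ``rhs(state, params) -> dstate/dt``
    for generic explicit solvers (forward Euler, RK4).  ``state`` has the
    model variables on its last axis and may be vectorized over grid
    nodes; parameters are named scalars, any of which the engine may bind
    to a grid layer (per-node arrays that broadcast against the node
    axes).  Models that are not naturally ODE systems may instead supply
    a ``direct_step(state, params, k)`` that performs the time step
    itself.

``ionic``
    A structured description for exponential (Rush-Larsen family)
    solvers: the state vector is partitioned into "other" (non-gate)
    variables, gating variables with voltage-dependent transition rates
    alpha(V), beta(V), and Markov-chain blocks whose rate matrix is
    decomposed into univariate parts (tabulatable) plus an optional small
    multivariate remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "RHSModel",
    "Gate",
    "MarkovPart",
    "MarkovChain",
    "IonicModelSpec",
    "fhncub_rhs",
    "barkley_rhs",
    "zfk_rhs",
    "hodgkin_huxley_ionic",
    "toy_markov_channel",
    "get_rhs_model",
    "get_ionic_model",
    "RHS_REGISTRY",
    "IONIC_REGISTRY",
]


# ---------------------------------------------------------------------
# rhs format
# ---------------------------------------------------------------------

@dataclass
class RHSModel:
    """Plain right-hand-side kinetics model."""

    name: str
    n_var: int
    defaults: dict
    rhs: Callable
    direct_step: Callable | None = None

    def __call__(self, state, params=None):
        p = dict(self.defaults)
        if params:
            p.update(params)
        return self.rhs(state, p)


def _p(params, key):
    return params[key]


def fhncub_rhs(state, params):
    """Cubic FitzHugh-Nagumo kinetics.

    du/dt = (1/eps) (u - u^3/3 - v) + Iu
    dv/dt = eps (u + bet - gam*v) + Iv
    """
    eps = np.asarray(params["eps"])
    if np.any(eps <= 0):
        raise ValueError("fhncub: eps must be positive")
    u = state[..., 0]
    v = state[..., 1]
    du = (u - u**3 / 3.0 - v) / eps + params["Iu"]
    dv = eps * (u + params["bet"] - params["gam"] * v) + params["Iv"]
    return np.stack(np.broadcast_arrays(du, dv), axis=-1)


def barkley_rhs(state, params):
    """Barkley's fast-slow caricature of excitable kinetics.

    du/dt = (1/eps) u (1 - u) (u - (v + b)/a)
    dv/dt = u - v
    """
    a, b, eps = params["a"], params["b"], params["eps"]
    if np.any(np.asarray(eps) <= 0) or np.any(np.asarray(a) == 0):
        raise ValueError("fhnbkl: need eps > 0 and a != 0")
    u = state[..., 0]
    v = state[..., 1]
    du = u * (1.0 - u) * (u - (v + b) / a) / eps
    dv = u - v
    return np.stack(np.broadcast_arrays(du, dv), axis=-1)


def zfk_rhs(state, params):
    """Zeldovich-Frank-Kamenetsky (Nagumo / Schloegl) single-variable kinetics.

    dV/dt = V (V - alpha) (1 - V) + Iu
    """
    V = state[..., 0]
    dV = V * (V - params["alpha"]) * (1.0 - V) + params["Iu"]
    return np.broadcast_arrays(dV)[0][..., None]


RHS_REGISTRY: dict[str, RHSModel] = {}


def _register_rhs(model: RHSModel) -> RHSModel:
    RHS_REGISTRY[model.name] = model
    return model


_register_rhs(RHSModel(
    "fhncub", 2,
    {"eps": 0.3, "bet": 0.71, "gam": 0.5, "Iu": 0.0, "Iv": 0.0},
    fhncub_rhs,
))
_register_rhs(RHSModel(
    "fhnbkl", 2,
    {"a": 0.8, "b": 0.01, "eps": 0.02},
    barkley_rhs,
))
_register_rhs(RHSModel(
    "zfk", 1,
    {"alpha": 0.13, "Iu": 0.0},
    zfk_rhs,
))


def get_rhs_model(name: str) -> RHSModel:
    try:
        return RHS_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown rhs model {name!r}; known: {sorted(RHS_REGISTRY)}"
        ) from None


# ---------------------------------------------------------------------
# ionic format
# ---------------------------------------------------------------------

@dataclass
class Gate:
    """A gating variable dy/dt = alpha(V)(1-y) - beta(V) y."""

    index: int
    alpha: Callable
    beta: Callable
    univariate: bool = True


@dataclass
class MarkovPart:
    """One univariate term of a Markov-chain rate-matrix decomposition.

    ``matrix(v)`` returns the (n, n) rate matrix contribution for a
    scalar value ``v`` of the control variable at state index
    ``control_index``.  Columns must sum to zero (probability
    conservation).
    """

    matrix: Callable
    control_index: int = 0
    univariate: bool = True


@dataclass
class MarkovChain:
    """A block of state variables evolving as du/dt = M u.

    ``M`` is the sum of the declared univariate ``parts`` plus an
    optional multivariate ``remainder(state) -> matrix`` which the solver
    advances by forward Euler.
    """

    indices: Sequence[int]
    parts: list[MarkovPart]
    remainder: Callable | None = None

    @property
    def n_states(self) -> int:
        return len(self.indices)


@dataclass
class IonicModelSpec:
    """State partition for exponential solvers.

    The first ``n_other`` variables are the non-gate ("other") block,
    with the transmembrane voltage V first; ``other_rhs(state, params)``
    returns their time derivatives.  Gate and Markov-chain indices must
    be disjoint from the other block and together cover the state.
    """

    name: str
    n_var: int
    n_other: int
    other_rhs: Callable
    gates: list[Gate] = field(default_factory=list)
    markov_chains: list[MarkovChain] = field(default_factory=list)
    defaults: dict = field(default_factory=dict)
    v_range: tuple[float, float] = (-100.0, 60.0)
    initial_state: np.ndarray | None = None

    def __post_init__(self):
        covered = set(range(self.n_other))
        for g in self.gates:
            if g.index in covered:
                raise ValueError(f"{self.name}: index {g.index} covered twice")
            covered.add(g.index)
        for c in self.markov_chains:
            for i in c.indices:
                if i in covered:
                    raise ValueError(f"{self.name}: index {i} covered twice")
                covered.add(i)
        if covered != set(range(self.n_var)):
            raise ValueError(
                f"{self.name}: other/gate/Markov partition does not cover "
                f"the state vector (covered {sorted(covered)}, n_var {self.n_var})"
            )


# -- Hodgkin-Huxley ----------------------------------------------------

def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with the removable singularity at x = 0 filled
    by its series limit y."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-7
    safe = np.where(small, 1.0, x)
    out = safe / (1.0 - np.exp(-safe / y))
    # limit x->0: y * (1 + x/(2y) + ...)
    return np.where(small, y * (1.0 + x / (2.0 * y)), out)


def hh_alpha_m(V):
    return 0.1 * _vtrap(V + 40.0, 10.0)


def hh_beta_m(V):
    return 4.0 * np.exp(-(V + 65.0) / 18.0)


def hh_alpha_h(V):
    return 0.07 * np.exp(-(V + 65.0) / 20.0)


def hh_beta_h(V):
    return 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))


def hh_alpha_n(V):
    return 0.01 * _vtrap(V + 55.0, 10.0)


def hh_beta_n(V):
    return 0.125 * np.exp(-(V + 65.0) / 80.0)


_HH_CONST = dict(
    gNa=120.0, ENa=50.0, gK=36.0, EK=-77.0, gL=0.3, EL=-54.387, Cm=1.0,
)


def _hh_other_rhs(state, params):
    V = state[..., 0]
    m = state[..., 1]
    h = state[..., 2]
    n = state[..., 3]
    c = _HH_CONST
    INa = c["gNa"] * m**3 * h * (V - c["ENa"])
    IK = c["gK"] * n**4 * (V - c["EK"])
    IL = c["gL"] * (V - c["EL"])
    dV = (-(INa + IK + IL) + params.get("Iu", 0.0)) / c["Cm"]
    return np.asarray(dV)[..., None]


def hodgkin_huxley_ionic() -> IonicModelSpec:
    """Hodgkin-Huxley squid-axon model in ionic format.

    Four state variables: V (mV, resting approximately -65 mV) and the
    gates m, h, n.  All transition rates are univariate in V, so the
    Rush-Larsen solver tabulates them; the removable singularities of
    alpha_m and alpha_n are filled by their series limits.
    """
    rest = np.array([-65.0, 0.0529, 0.5961, 0.3177])
    return IonicModelSpec(
        name="hh",
        n_var=4,
        n_other=1,
        other_rhs=_hh_other_rhs,
        gates=[
            Gate(1, hh_alpha_m, hh_beta_m),
            Gate(2, hh_alpha_h, hh_beta_h),
            Gate(3, hh_alpha_n, hh_beta_n),
        ],
        defaults={"Iu": 0.0},
        v_range=(-100.0, 60.0),
        initial_state=rest,
    )


# -- toy Markov chains -------------------------------------------------

def _check_rate_matrix(M, what, tol=1e-12):
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{what}: rate matrix must be square")
    colsums = np.abs(M.sum(axis=0))
    if np.any(colsums > tol):
        raise ValueError(
            f"{what}: rate-matrix columns must sum to zero "
            f"(max |sum| = {colsums.max():.3g})"
        )
    off = M - np.diag(np.diag(M))
    if np.any(off < -tol):
        raise ValueError(f"{what}: negative off-diagonal transition rate")
    return M


def toy_markov_channel(
    n_states: int = 2,
    rate_spec: dict | None = None,
    clamp_V: float | None = None,
) -> IonicModelSpec:
    """Synthetic Markov-chain channel for exercising matrix exponential
    stepping: M(V) = M0 + sigma(V) * M1, both parts univariate in V.

    ``rate_spec`` may provide arrays ``M0``, ``M1`` (zero column sums,
    non-negative off-diagonals) and a scalar function ``sigma``; the
    default is a nearest-neighbour chain with V-dependent forward rates.
    State layout: V ("other", with zero drift — clamp it externally or
    leave constant) followed by the ``n_states`` chain probabilities.
    """
    if n_states < 2:
        raise ValueError("need at least 2 channel states")
    spec = rate_spec or {}
    if "M0" in spec:
        M0 = _check_rate_matrix(spec["M0"], "M0")
        if M0.shape[0] != n_states:
            raise ValueError("M0 has wrong size")
    else:
        # symmetric nearest-neighbour hopping at unit rate
        M0 = np.zeros((n_states, n_states))
        for i in range(n_states - 1):
            M0[i + 1, i] += 1.0
            M0[i, i] -= 1.0
            M0[i, i + 1] += 1.0
            M0[i + 1, i + 1] -= 1.0
        _check_rate_matrix(M0, "M0")
    if "M1" in spec:
        M1 = _check_rate_matrix(spec["M1"], "M1")
    else:
        # V-modulated forward rates
        M1 = np.zeros((n_states, n_states))
        for i in range(n_states - 1):
            M1[i + 1, i] += 1.0
            M1[i, i] -= 1.0
        _check_rate_matrix(M1, "M1")
    sigma = spec.get("sigma", lambda v: 1.0 / (1.0 + np.exp(-v)))

    def zero_rhs(state, params):
        return np.zeros_like(np.asarray(state[..., 0]))[..., None]

    parts = [
        MarkovPart(lambda v, _M=M0: _M, control_index=0),
        MarkovPart(lambda v, _M=M1, _s=sigma: _s(v) * _M, control_index=0),
    ]
    init = np.zeros(1 + n_states)
    init[0] = clamp_V if clamp_V is not None else 0.0
    init[1] = 1.0
    return IonicModelSpec(
        name=f"toy_markov_{n_states}",
        n_var=1 + n_states,
        n_other=1,
        other_rhs=zero_rhs,
        markov_chains=[
            MarkovChain(indices=list(range(1, 1 + n_states)), parts=parts)
        ],
        v_range=(-10.0, 10.0),
        initial_state=init,
    )


IONIC_REGISTRY: dict[str, Callable[[], IonicModelSpec]] = {
    "hh": hodgkin_huxley_ionic,
    "toy_markov": toy_markov_channel,
}


def get_ionic_model(name: str, **kwargs) -> IonicModelSpec:
    try:
        return IONIC_REGISTRY[name](**kwargs)
    except KeyError:
        raise KeyError(
            f"unknown ionic model {name!r}; known: {sorted(IONIC_REGISTRY)}"
        ) from None
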