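"""Time stepping of cell kinetics.

Explicit schemes (forward Euler, classical RK4) apply to any ``rhs``
model.  Exponential schemes of the Rush-Larsen family apply to ``ionic``
models: gating variables are advanced by the closed-form solution of
their linear relaxation with rates frozen at the current voltage, and
Markov-chain blocks by the matrix exponential of the frozen rate matrix
(Lie splitting over the declared univariate parts, forward Euler on any
multivariate remainder).  Univariate coefficient families are tabulated
on a fine grid of the control variable at start-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .cell_models import IonicModelSpec, MarkovPart, RHSModel

__all__ = [
    "NumericError",
    "RateTable",
    "euler_step",
    "rk4_step",
    "rush_larsen_gate_step",
    "matrix_rush_larsen_step",
    "rl_step_matrix",
    "tabulate",
    "tabulate_ionic",
    "ionic_step",
    "SOLVER_REGISTRY",
]


class NumericError(ArithmeticError):
    """Non-finite values produced during time stepping."""


def _check_finite(deriv, model_name):
    if not np.all(np.isfinite(deriv)):
        bad = np.nonzero(~np.isfinite(np.atleast_2d(deriv)).all(axis=0))[0]
        raise NumericError(
            f"{model_name}: non-finite derivative in variable index "
            f"{bad.tolist()}"
        )


# ---------------------------------------------------------------------
# Explicit schemes
# ---------------------------------------------------------------------

def euler_step(state, model: RHSModel, params=None, k: float = 0.01):
    """One forward Euler step ``state + k * rhs(state)``.

    Models with a ``direct_step`` (kinetics not representable as plain
    ODEs) delegate the whole step to the model.
    """
    if k <= 0:
        raise ValueError("time step k must be positive")
    p = dict(model.defaults)
    if params:
        p.update(params)
    if model.direct_step is not None:
        return model.direct_step(np.asarray(state, dtype=float), p, k)
    deriv = model.rhs(np.asarray(state, dtype=float), p)
    _check_finite(deriv, model.name)
    return state + k * deriv


def rk4_step(state, model: RHSModel, params=None, k: float = 0.01):
    """One classical four-stage Runge-Kutta step (local error O(k^5))."""
    if k <= 0:
        raise ValueError("time step k must be positive")
    p = dict(model.defaults)
    if params:
        p.update(params)
    y = np.asarray(state, dtype=float)
    f = model.rhs
    k1 = f(y, p)
    k2 = f(y + 0.5 * k * k1, p)
    k3 = f(y + 0.5 * k * k2, p)
    k4 = f(y + k * k3, p)
    incr = (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
    _check_finite(incr, model.name)
    return y + k * incr


# ---------------------------------------------------------------------
# Rush-Larsen family
# ---------------------------------------------------------------------

_zero_rate_warned = False


def rush_larsen_gate_step(y, alpha, beta, k):
    """Exponential step for a gate dy/dt = alpha (1-y) - beta y.

    y' = y_inf + (y - y_inf) exp(-(alpha+beta) k),  y_inf = alpha/(alpha+beta).

    Exact when the rates are constant over the step; unconditionally
    stable and maps [0, 1] into itself for any k > 0.  Where
    alpha + beta == 0 the gate has no dynamics and is returned unchanged.
    """
    if k <= 0:
        raise ValueError("time step k must be positive")
    y = np.asarray(y, dtype=float)
    a = np.asarray(alpha, dtype=float)
    b = np.asarray(beta, dtype=float)
    tot = a + b
    degenerate = tot == 0.0
    if np.any(degenerate):
        global _zero_rate_warned
        if not _zero_rate_warned:
            warnings.warn(
                "rush_larsen_gate_step: alpha + beta == 0 at some nodes; "
                "gate left unchanged there", stacklevel=2,
            )
            _zero_rate_warned = True
    safe = np.where(degenerate, 1.0, tot)
    yinf = np.where(degenerate, y, a / safe)
    return np.where(degenerate, y, yinf + (y - yinf) * np.exp(-tot * k))


def rl_step_matrix(M, k: float):
    """Matrix-exponential step matrix T = exp(k M) by diagonalization.

    Falls back to scaling-and-squaring (``scipy.linalg.expm``) with a
    warning if the eigenbasis is defective or the reconstructed real
    matrix has imaginary residue above 1e-10.
    """
    M = np.asarray(M, dtype=float)
    try:
        lam, S = np.linalg.eig(M)
        Sinv = np.linalg.inv(S)
        # defective matrices pass eig() silently with a near-singular
        # eigenbasis; verify the decomposition actually reconstructs M
        scale = max(1.0, float(np.max(np.abs(M))))
        recon_err = np.max(np.abs((S * lam) @ Sinv - M))
        if recon_err > 1e-8 * scale:
            raise np.linalg.LinAlgError("defective or ill-conditioned eigenbasis")
        T = S @ np.diag(np.exp(lam * k)) @ Sinv
        resid = np.max(np.abs(T.imag)) if np.iscomplexobj(T) else 0.0
        if not np.all(np.isfinite(T.real)) or resid > 1e-10:
            raise np.linalg.LinAlgError("ill-conditioned eigenbasis")
        return np.ascontiguousarray(T.real)
    except np.linalg.LinAlgError:
        warnings.warn(
            "matrix Rush-Larsen: diagonalization failed; falling back to "
            "scaling-and-squaring matrix exponential", stacklevel=2,
        )
        return scipy.linalg.expm(k * M)


def matrix_rush_larsen_step(u, M, k: float):
    """Advance a Markov-chain probability vector: u' = exp(k M) u."""
    if k <= 0:
        raise ValueError("time step k must be positive")
    return rl_step_matrix(M, k) @ np.asarray(u, dtype=float)


# ---------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------

@dataclass
class RateTable:
    """Precomputed values of a univariate function family on a uniform
    grid of the control variable.

    Lookup returns the entry of the *nearest* grid node (no
    interpolation; exact ties go to the lower index).  Queries outside
    [vmin, vmax] clamp to the end entries and are counted.
    """

    vmin: float
    vmax: float
    values: np.ndarray          # shape (n, ...) — entry per grid node
    n_clamped: int = 0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dv(self) -> float:
        return (self.vmax - self.vmin) / (self.n - 1)

    def index(self, v):
        """Nearest-node index array for query values ``v``."""
        v = np.asarray(v, dtype=float)
        raw = (v - self.vmin) / self.dv
        idx = np.ceil(raw - 0.5).astype(np.intp)   # half-way ties -> lower
        clamped = int(np.count_nonzero((idx < 0) | (idx > self.n - 1)))
        if clamped:
            self.n_clamped += clamped
        return np.clip(idx, 0, self.n - 1)

    def lookup(self, v):
        return self.values[self.index(v)]


def tabulate(fn_family, vmin: float, vmax: float, n: int = 20000) -> RateTable:
    """Tabulate a univariate function (scalar -> array) on n grid nodes."""
    if n < 2:
        raise ValueError("tabulation needs at least 2 grid nodes")
    if not vmax > vmin:
        raise ValueError("need vmax > vmin")
    grid = np.linspace(vmin, vmax, n)
    first = np.asarray(fn_family(grid[0]), dtype=float)
    values = np.empty((n,) + first.shape)
    values[0] = first
    for i in range(1, n):
        values[i] = fn_family(grid[i])
    return RateTable(vmin, vmax, values)


@dataclass
class IonicTables:
    """Start-up tabulation for an ionic model at a fixed time step."""

    k: float
    gate_tables: dict = field(default_factory=dict)   # gate index -> RateTable of (E, yinf)
    markov_tables: dict = field(default_factory=dict)  # (chain, part) -> RateTable of T

    @property
    def clamp_report(self) -> int:
        tables = list(self.gate_tables.values()) + list(self.markov_tables.values())
        return sum(t.n_clamped for t in tables)


def tabulate_ionic(spec: IonicModelSpec, k: float, n: int = 20000) -> IonicTables:
    """Precompute gate step coefficients and Markov step matrices.

    For each univariate gate the pair (exp factor, equilibrium value) is
    tabulated over the model's declared control range; for each
    univariate Markov part the full step matrix exp(k M_i(v)).
    """
    vmin, vmax = spec.v_range
    tabs = IonicTables(k=k)
    for g in spec.gates:
        if not g.univariate:
            continue

        def gate_coeffs(v, _g=g):
            a = float(np.asarray(_g.alpha(v)))
            b = float(np.asarray(_g.beta(v)))
            tot = a + b
            if tot == 0.0:
                return np.array([1.0, 0.0])
            return np.array([np.exp(-tot * k), a / tot])

        tabs.gate_tables[g.index] = tabulate(gate_coeffs, vmin, vmax, n)
    for ci, chain in enumerate(spec.markov_chains):
        for pi, part in enumerate(chain.parts):
            if not part.univariate:
                continue
            tabs.markov_tables[(ci, pi)] = tabulate(
                lambda v, _p=part: rl_step_matrix(_p.matrix(v), k),
                vmin, vmax, n,
            )
    return tabs


# ---------------------------------------------------------------------
# Full ionic step
# ---------------------------------------------------------------------

def _markov_part_step(u, part: MarkovPart, control, k, table: RateTable | None):
    """Apply one univariate Lie-splitting substep to chain vectors.

    ``u`` has shape (..., n_states); ``control`` broadcasts over the
    leading axes.
    """
    if table is not None:
        T = table.lookup(control)                      # (..., n, n)
        return np.einsum("...ij,...j->...i", T, u)
    # diagonalization on the fly, node by node
    c = np.broadcast_to(np.asarray(control, dtype=float), u.shape[:-1])
    flat_u = u.reshape(-1, u.shape[-1])
    flat_c = c.reshape(-1)
    out = np.empty_like(flat_u)
    cache: dict[float, np.ndarray] = {}
    for i, cv in enumerate(flat_c):
        T = cache.get(cv)
        if T is None:
            T = rl_step_matrix(part.matrix(cv), k)
            cache[cv] = T
        out[i] = T @ flat_u[i]
    return out.reshape(u.shape)


def ionic_step(state, spec: IonicModelSpec, k: float,
               tables: IonicTables | None = None, params=None):
    """One exponential (Rush-Larsen) step of an ionic model.

    Non-gate variables advance by forward Euler on ``other_rhs``; gates
    by the exponential gate step (tabulated when available); each Markov
    chain by sequential matrix Rush-Larsen over its declared parts, in
    declaration order, then forward Euler on the remainder.  All blocks
    read the incoming state (rates frozen at the step start).
    """
    if k <= 0:
        raise ValueError("time step k must be positive")
    if tables is not None and tables.k != k:
        raise ValueError("tables were built for a different time step")
    p = dict(spec.defaults)
    if params:
        p.update(params)
    state = np.asarray(state, dtype=float)
    out = state.copy()
    V = state[..., 0]

    deriv = spec.other_rhs(state, p)
    _check_finite(deriv, spec.name)
    out[..., :spec.n_other] = state[..., :spec.n_other] + k * deriv

    for g in spec.gates:
        table = tables.gate_tables.get(g.index) if tables else None
        y = state[..., g.index]
        if table is not None:
            coeff = table.lookup(V)                    # (..., 2): E, yinf
            E, yinf = coeff[..., 0], coeff[..., 1]
            out[..., g.index] = yinf + (y - yinf) * E
        else:
            out[..., g.index] = rush_larsen_gate_step(y, g.alpha(V), g.beta(V), k)

    for ci, chain in enumerate(spec.markov_chains):
        idx = np.asarray(chain.indices)
        u = state[..., idx]
        for pi, part in enumerate(chain.parts):
            table = tables.markov_tables.get((ci, pi)) if tables else None
            control = state[..., part.control_index]
            u = _markov_part_step(u, part, control, k, table)
        if chain.remainder is not None:
            R = chain.remainder(state)
            u = u + k * np.einsum("...ij,...j->...i", R, u)
        out[..., idx] = u
    return out


SOLVER_REGISTRY = {
    "euler": euler_step,
    "rk4": rk4_step,
    "rushlarsen": ionic_step,
}
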