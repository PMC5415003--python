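"""Multigrid solver for the bidomain elliptic equation.

Solves ``A phi = S`` where A is the 19-point diffusion stencil built by
:mod:`cardiogrid.diffusion` (shared code path) for the summed
intra + extracellular tensor.  With pure no-flux boundaries A is
singular (constants are in its kernel); the additive constant is fixed
by pinning the solution at a single tissue node,
``phi(pin) = upin``.  Alternatively a free-node mask restricts the
solve to a subgrid, with nodes outside it acting as Dirichlet data
(used by the plane-wave verification problem).

The solver runs Full Multigrid: nested iteration from the coarsest
level, then V-cycles on the finest grid with multicolour Gauss-Seidel
(or Jacobi) smoothing, vertex-centred transfers (trilinear
prolongation; injection for fields, full weighting for residuals) and
coarse operators rebuilt from the coarsened tissue indicator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .diffusion import StencilWeights, build_tensor, build_weights
from .geometry import GeometryGrid

__all__ = [
    "EllipticProblem",
    "EllipticSolver",
    "SolverError",
    "SolveInfo",
    "solve_elliptic",
    "smoother_sweep",
    "restrict",
    "prolong",
]


class SolverError(RuntimeError):
    """Divergence or invalid solver configuration."""


# ---------------------------------------------------------------------
# Vertex-centred grid transfers
# ---------------------------------------------------------------------

def _coarse_size(n: int) -> int:
    return (n + 1) // 2 if n >= 3 else n


def _prolong_axis(c: np.ndarray, nf: int, axis: int) -> np.ndarray:
    nc = c.shape[axis]
    if nc == nf:
        return c
    f_shape = list(c.shape)
    f_shape[axis] = nf
    f = np.zeros(f_shape)
    sl = [slice(None)] * c.ndim

    def put(fidx, arr):
        s = sl.copy()
        s[axis] = fidx
        f[tuple(s)] = arr

    def take(cidx):
        s = sl.copy()
        s[axis] = cidx
        return c[tuple(s)]

    put(slice(0, nf, 2), take(slice(0, (nf + 1) // 2)))
    n_mid = nf // 2                     # fine odd indices 1, 3, ..
    left = take(slice(0, n_mid))
    right_hi = min(n_mid + 1, nc)
    right = take(slice(1, right_hi))
    if right.shape[axis] < n_mid:       # last odd fine node has no right parent
        pad = take(slice(nc - 1, nc))
        right = np.concatenate([right, pad], axis=axis)
    put(slice(1, nf, 2), 0.5 * (left + right))
    return f


def prolong(coarse: np.ndarray, fine_shape: tuple[int, int, int]) -> np.ndarray:
    """Trilinear (vertex-centred) interpolation to the fine grid.

    Exact for constants, and for linear fields on a full box.
    """
    out = coarse
    for axis in range(3):
        out = _prolong_axis(out, fine_shape[axis], axis)
    return out


def _restrict_axis_fw(f: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Full weighting along one axis; returns (weighted sum, weight sum)."""
    nf = f.shape[axis]
    nc = _coarse_size(nf)
    if nc == nf:
        return f, np.ones_like(f)
    sl = [slice(None)] * f.ndim

    def take(idx):
        s = sl.copy()
        s[axis] = idx
        return f[tuple(s)]

    centre = take(slice(0, nf, 2))
    acc = 0.5 * centre
    wacc = np.full_like(centre, 0.5)
    left = take(slice(0, nf - 1, 2))    # fine index 2i-1 exists for i >= 1
    pad_shape = list(left.shape)
    # neighbours at 2i-1 (missing for i=0) and 2i+1 (may miss for last i)
    lm = take(slice(1, nf, 2))          # fine odd nodes
    n_odd = lm.shape[axis]
    zeros1 = np.zeros([s if a != axis else 1 for a, s in enumerate(pad_shape)])
    lpad = np.concatenate([zeros1, 0.25 * lm], axis=axis)[
        tuple(sl[:axis] + [slice(0, nc)] + sl[axis + 1:])
    ]
    wl = np.concatenate(
        [zeros1, 0.25 * np.ones_like(lm)], axis=axis
    )[tuple(sl[:axis] + [slice(0, nc)] + sl[axis + 1:])]
    rpad = np.concatenate([0.25 * lm, zeros1], axis=axis)[
        tuple(sl[:axis] + [slice(0, nc)] + sl[axis + 1:])
    ]
    wr = np.concatenate(
        [0.25 * np.ones_like(lm), zeros1], axis=axis
    )[tuple(sl[:axis] + [slice(0, nc)] + sl[axis + 1:])]
    return acc + lpad + rpad, wacc + wl + wr


def restrict(
    fine: np.ndarray,
    kind: str = "injection",
) -> np.ndarray:
    """Vertex-centred restriction to the coarse grid (every other node).

    ``injection`` takes the coincident fine value, so constants are
    reproduced and ``restrict(prolong(c))`` returns ``c`` at coarse
    nodes.  ``full_weighting`` averages with the [1/4, 1/2, 1/4] kernel
    per axis (weights renormalized at boundaries), used internally for
    residual transfer.
    """
    if kind == "injection":
        out = fine
        for axis in range(3):
            n = out.shape[axis]
            sl = [slice(None)] * 3
            sl[axis] = slice(0, n, 2) if n >= 3 else slice(None)
            out = out[tuple(sl)]
        return out.copy()
    if kind != "full_weighting":
        raise ValueError(f"unknown restriction kind {kind!r}")
    num, den = fine, np.ones_like(fine)
    for axis in range(3):
        num, dw = _restrict_axis_fw(num, axis)
        den, _ = _restrict_axis_fw(den, axis)
    return num / den


def _fw_raw(f: np.ndarray) -> np.ndarray:
    """Unnormalized full weighting (per axis 1/2 centre, 1/4 sides)."""
    num = f
    for axis in range(3):
        num, _ = _restrict_axis_fw(num, axis)
    return num


def _restrict_residual(r: np.ndarray, free: np.ndarray) -> np.ndarray:
    """Full-weighting residual transfer normalized over the free nodes.

    The residual is zero at void/fixed nodes; averaging those zeros in
    with full weight would underestimate the coarse residual along
    staircase and Dirichlet boundaries and stall the coarse correction,
    so the weights are renormalized by the free-node indicator.
    """
    num = _fw_raw(r)
    den = _fw_raw(free.astype(float))
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 1e-12)
    return out


# ---------------------------------------------------------------------
# Level construction
# ---------------------------------------------------------------------

@dataclass
class _Level:
    shape: tuple[int, int, int]
    weights: StencilWeights
    tissue: np.ndarray            # bool (nx, ny, nz)
    free: np.ndarray              # bool flat (N,)
    order: np.ndarray             # colour-grouped free flat indices
    nbr: np.ndarray               # (N, n_off-1) flat neighbour indices
    wgt: np.ndarray               # (N, n_off-1)
    diag: np.ndarray              # (N,)


def _flatten_stencil(weights: StencilWeights, free3: np.ndarray) -> _Level:
    shape = weights.weights.shape[:3]
    nx, ny, nz = shape
    N = nx * ny * nz
    n_off = weights.n_off
    I, J, K = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    own = ((I * ny + J) * nz + K).ravel()
    nbr = np.empty((N, n_off - 1), dtype=np.intp)
    wgt = np.empty((N, n_off - 1))
    for m in range(1, n_off):
        q = weights.offsets[m]
        Iq, Jq, Kq = I + q[0], J + q[1], K + q[2]
        valid = (
            (Iq >= 0) & (Iq < nx) & (Jq >= 0) & (Jq < ny)
            & (Kq >= 0) & (Kq < nz)
        )
        flat = np.where(
            valid, (np.clip(Iq, 0, nx - 1) * ny + np.clip(Jq, 0, ny - 1)) * nz
            + np.clip(Kq, 0, nz - 1), own.reshape(shape),
        )
        nbr[:, m - 1] = flat.ravel()
        wgt[:, m - 1] = weights.weights[..., m].ravel()
    diag = weights.weights[..., 0].ravel()

    free = free3.ravel().copy()
    isolated = free & (diag == 0.0)
    if np.any(isolated):
        warnings.warn(
            f"elliptic: {int(isolated.sum())} isolated tissue node(s) with "
            "zero centre weight held at their current value", stacklevel=2,
        )
        free = free & ~isolated

    colour = ((I % 2) * 4 + (J % 2) * 2 + (K % 2)).ravel()
    order_parts = [
        np.nonzero(free & (colour == c))[0] for c in range(8)
    ]
    order = np.concatenate(order_parts).astype(np.intp)
    return _Level(
        shape=shape, weights=weights, tissue=free3.copy(),
        free=free, order=order, nbr=nbr, wgt=wgt, diag=diag,
    )


def _coarsen_geometry(geom: GeometryGrid) -> GeometryGrid:
    """Coarse indicator: tissue if any fine node within one step of the
    coincident fine node is tissue; fibre sampled at the coincident node."""
    nx, ny, nz = geom.shape
    mask = geom.tissue_mask
    # max-pool over the 3^3 neighbourhood
    pad = np.zeros((nx + 2, ny + 2, nz + 2), dtype=bool)
    pad[1:-1, 1:-1, 1:-1] = mask
    pooled = np.zeros_like(mask)
    for dx in (0, 1, 2):
        for dy in (0, 1, 2):
            for dz in (0, 1, 2):
                pooled |= pad[dx:dx + nx, dy:dy + ny, dz:dz + nz]
    sl = tuple(
        slice(0, n, 2) if n >= 3 else slice(None) for n in (nx, ny, nz)
    )
    status = pooled[sl].astype(np.int32)
    fibre = geom.fibre[sl + (slice(None),)].copy()
    norms = np.linalg.norm(fibre, axis=-1)
    bad = norms < 1e-9
    fibre[bad] = (1.0, 0.0, 0.0)
    fibre /= np.linalg.norm(fibre, axis=-1)[..., None]
    cg = GeometryGrid(*status.shape, geom.h * 2, status, fibre)
    return cg


# ---------------------------------------------------------------------
# Problem / solver
# ---------------------------------------------------------------------

@dataclass
class SolveInfo:
    converged: bool
    cycles: int
    sweeps: int                  # raw sweep count over all levels
    residual: float
    fine_sweep_equivalents: float = 0.0   # sweeps weighted by level size


@dataclass
class EllipticProblem:
    """A pinned (or Dirichlet-restricted) elliptic problem A phi = S."""

    geom: GeometryGrid
    weights: StencilWeights
    rhs: np.ndarray
    pin: tuple[int, int, int] | None = None
    upin: float = 0.0
    free_mask: np.ndarray | None = None     # defaults to the tissue mask
    tolerance: float = 1e-8
    delta: float = 0.5
    upper_level: int = 3
    vcycles: int = 20
    preiter: int = 1
    postiter: int = 2
    maxiter: float = 1e6
    smoother: str = "gauss_seidel"
    # diffusivities used to rebuild the operator on coarse levels; falls
    # back to an isotropic unit tensor (coarse operators need only be
    # spectrally close for the correction to work)
    coarse_diffusivities: tuple[float, float] | None = None

    @classmethod
    def from_tensors(cls, geom, Dpar, Dtrans, rhs, **kw):
        tensor = build_tensor(geom, Dpar, Dtrans)
        kw.setdefault("coarse_diffusivities", (Dpar, Dtrans))
        return cls(geom, build_weights(geom, tensor), rhs, **kw)


class EllipticSolver:
    """Multigrid hierarchy for a fixed geometry/operator.

    Build once, then :meth:`solve` for each right-hand side (warm starts
    supported through the initial-guess argument).
    """

    def __init__(self, problem: EllipticProblem):
        self.p = problem
        self._sweeps = 0
        self._sweep_equiv = 0.0
        geom = problem.geom
        if problem.free_mask is not None:
            free3 = problem.free_mask & geom.tissue_mask
        else:
            free3 = geom.tissue_mask.copy()
        # With pure no-flux boundaries the operator is singular (constants
        # in the kernel).  The pin condition phi(pin) = upin is enforced as
        # a gauge: iterate on the singular system and shift the whole field
        # after each cycle so the pin value is exact.  Fixing the pin node
        # in the iteration instead would leave the constant error mode with
        # only a point-source residual, which multigrid cannot correct
        # efficiently.  When Dirichlet data fixes the constant (free_mask
        # given), the pin (if any) is imposed as a fixed node.
        self._gauge_pin = problem.pin is not None and problem.free_mask is None
        if problem.pin is not None:
            px, py, pz = problem.pin
            if not geom.tissue_mask[px, py, pz]:
                raise SolverError("pin location is not a tissue node")
            if not self._gauge_pin:
                free3[px, py, pz] = False
        elif problem.free_mask is None:
            warnings.warn(
                "elliptic: no pin and no Dirichlet restriction; the "
                "no-flux problem is singular up to a constant", stacklevel=2,
            )
        if not np.any(free3):
            raise SolverError("no free nodes to solve for")

        self.levels: list[_Level] = [_flatten_stencil(problem.weights, free3)]
        g, f3 = geom, free3
        Dp, Dt = problem.coarse_diffusivities or (1.0, 1.0)
        pin = problem.pin if not self._gauge_pin else None
        for _ in range(int(problem.upper_level)):
            if min(s for s in g.shape if s > 1) < 5:
                break
            cg = _coarsen_geometry(g)
            cf = restrict(f3.astype(float), "injection") >= 1.0
            cf &= cg.tissue_mask
            if pin is not None:
                cpin = tuple(min(c // 2, s - 1) for c, s in zip(pin, cg.shape))
                cf[cpin] = False
                pin = cpin
            if not np.any(cf):
                break
            cw = build_weights(cg, build_tensor(cg, Dp, Dt))
            self.levels.append(_flatten_stencil(cw, cf))
            g, f3 = cg, cf

    # -- level primitives ---------------------------------------------
    def _sweep(self, lvl: _Level, u: np.ndarray, rhs: np.ndarray, n: int = 1):
        fine_n = max(1, self.levels[0].order.size)
        self._sweep_equiv += n * lvl.order.size / fine_n
        for _ in range(n):
            if self.p.smoother == "jacobi":
                out = u.copy()
                _kernels.jacobi_sweep(
                    lvl.order, lvl.nbr, lvl.wgt, lvl.diag, u, rhs, out
                )
                u[:] = out
            else:
                _kernels.gs_sweep(lvl.order, lvl.nbr, lvl.wgt, lvl.diag, u, rhs)
        self._sweeps += n

    def _residual(self, lvl: _Level, u, rhs):
        r = np.zeros_like(u)
        maxr = _kernels.residual(lvl.order, lvl.nbr, lvl.wgt, lvl.diag, u, rhs, r)
        return r, maxr

    def _vcycle(self, li: int, u: np.ndarray, rhs: np.ndarray):
        lvl = self.levels[li]
        if li == len(self.levels) - 1:
            self._sweep(lvl, u, rhs, 40)
            return
        self._sweep(lvl, u, rhs, self.p.preiter)
        r, _ = self._residual(lvl, u, rhs)
        rc = _restrict_residual(
            r.reshape(lvl.shape), lvl.free.reshape(lvl.shape)
        )
        clvl = self.levels[li + 1]
        rc[~clvl.free.reshape(clvl.shape)] = 0.0
        ec = np.zeros(rc.size)
        self._vcycle(li + 1, ec, rc.ravel())
        e = prolong(ec.reshape(clvl.shape), lvl.shape).ravel()
        u[lvl.free] += e[lvl.free]
        self._sweep(lvl, u, rhs, self.p.postiter)

    # -- public solve --------------------------------------------------
    def solve(self, rhs: np.ndarray, u0: np.ndarray | None = None):
        """Solve A phi = rhs; returns (phi, SolveInfo).

        Values at non-free nodes of ``u0`` (Dirichlet data, pin) are
        kept; with no ``u0`` the fixed values default to zero / upin and
        the initial guess comes from FMG nested iteration.
        """
        p = self.p
        lvl0 = self.levels[0]
        rhs_flat = np.ascontiguousarray(rhs, dtype=float).ravel().copy()
        self._sweeps = 0
        self._sweep_equiv = 0.0
        if u0 is not None:
            u = np.asarray(u0, dtype=float).ravel().copy()
        else:
            # FMG nested iteration: restrict the right-hand side down the
            # hierarchy, then solve coarsest-first, prolonging each level's
            # smoothed solution as the next finer initial guess.  Fixed
            # (non-free) values default to upin / zero; callers with
            # Dirichlet shell data must pass it through u0 instead.
            base = p.upin if p.pin is not None else 0.0
            rhs_levels = [rhs_flat]
            rl = rhs_flat.reshape(lvl0.shape)
            for li in range(1, len(self.levels)):
                prev = self.levels[li - 1]
                rl = _restrict_residual(rl, prev.free.reshape(prev.shape))
                rhs_levels.append(rl.ravel().copy())
            u = None
            for li in range(len(self.levels) - 1, -1, -1):
                lvl = self.levels[li]
                if u is None:
                    u = np.full(lvl.free.size, base)
                else:
                    u = prolong(
                        u.reshape(self.levels[li + 1].shape), lvl.shape
                    ).ravel()
                u[~lvl.free] = base
                n = 40 if li == len(self.levels) - 1 else (
                    p.preiter + p.postiter + 1
                )
                self._sweep(lvl, u, rhs_levels[li], n)
        flat_pin = None
        if p.pin is not None:
            px, py, pz = p.pin
            flat_pin = (px * lvl0.shape[1] + py) * lvl0.shape[2] + pz
            if self._gauge_pin:
                u[lvl0.free] += p.upin - u[flat_pin]
            else:
                u[flat_pin] = p.upin

        _, res = self._residual(lvl0, u, rhs_flat)
        res_min = res
        cycles = 0
        converged = res <= p.tolerance
        while not converged:
            if cycles >= p.vcycles or self._sweeps >= p.maxiter:
                break
            self._vcycle(0, u, rhs_flat)
            cycles += 1
            if self._gauge_pin:
                u[lvl0.free] += p.upin - u[flat_pin]
            _, res = self._residual(lvl0, u, rhs_flat)
            if res < res_min:
                res_min = res
            elif res > 10.0 * res_min and res > p.tolerance:
                raise SolverError(
                    f"elliptic solver diverging: residual {res:.3e} grew "
                    f"10x above its minimum {res_min:.3e} after {cycles} cycles"
                )
            converged = res <= p.tolerance
        return u.reshape(lvl0.shape), SolveInfo(
            converged=converged, cycles=cycles, sweeps=self._sweeps,
            residual=float(res),
            fine_sweep_equivalents=self._sweep_equiv,
        )


def solve_elliptic(problem: EllipticProblem, u0: np.ndarray | None = None):
    """One-shot Full-Multigrid solve; see :class:`EllipticSolver`."""
    solver = EllipticSolver(problem)
    phi, info = solver.solve(problem.rhs, u0=u0)
    if not info.converged:
        warnings.warn(
            f"elliptic: maxiter/vcycles reached at residual "
            f"{info.residual:.3e} > tolerance {problem.tolerance:.3e}",
            stacklevel=2,
        )
    return phi, info


def smoother_sweep(
    phi: np.ndarray, problem: EllipticProblem, kind: str = "gauss_seidel"
) -> np.ndarray:
    """One full smoother sweep on the fine grid; pin re-imposed after."""
    if kind not in ("gauss_seidel", "jacobi"):
        raise ValueError(f"unknown smoother {kind!r}")
    import copy

    prob = copy.copy(problem)
    prob.smoother = kind
    solver = EllipticSolver(prob)
    lvl = solver.levels[0]
    u = np.asarray(phi, dtype=float).ravel().copy()
    rhs = np.asarray(problem.rhs, dtype=float).ravel()
    solver._sweep(lvl, u, rhs, 1)
    if problem.pin is not None:
        px, py, pz = problem.pin
        fp = (px * lvl.shape[1] + py) * lvl.shape[2] + pz
        if solver._gauge_pin:
            u[lvl.free] += problem.upin - u[fp]
        else:
            u[fp] = problem.upin
    return u.reshape(lvl.shape)
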