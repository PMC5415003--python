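"""Jitted inner loops for the elliptic solver.

The smoother and residual kernels operate on a flattened stencil
representation: per node, the flat indices of its stencil neighbours and
the matching weights (centre weight kept separately as the diagonal).
Only the node indices listed in ``order`` are touched, so Dirichlet /
void / pinned nodes are skipped by construction.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gs_sweep(order, nbr, wgt, diag, u, rhs):
    """One Gauss-Seidel sweep over the nodes in ``order`` (in order)."""
    for t in range(order.shape[0]):
        p = order[t]
        s = rhs[p]
        for m in range(nbr.shape[1]):
            s -= wgt[p, m] * u[nbr[p, m]]
        u[p] = s / diag[p]


@njit(cache=True)
def jacobi_sweep(order, nbr, wgt, diag, u, rhs, out):
    """One Jacobi sweep; ``out`` must enter as a copy of ``u``."""
    for t in range(order.shape[0]):
        p = order[t]
        s = rhs[p]
        for m in range(nbr.shape[1]):
            s -= wgt[p, m] * u[nbr[p, m]]
        out[p] = s / diag[p]


@njit(cache=True)
def residual(order, nbr, wgt, diag, u, rhs, r):
    """r = rhs - A u on the ordered nodes; returns max |r| there."""
    maxr = 0.0
    for t in range(order.shape[0]):
        p = order[t]
        s = rhs[p] - diag[p] * u[p]
        for m in range(nbr.shape[1]):
            s -= wgt[p, m] * u[nbr[p, m]]
        r[p] = s
        a = abs(s)
        if a > maxr:
            maxr = a
    return maxr
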