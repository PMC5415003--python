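"""Anisotropic diffusion operator on indicator-function geometries.

The operator L u = sum_jk d/dx_j ( D_jk d/dx_k u ) is discretized on the
regular grid by a 19-point stencil (6 face, 12 edge neighbours and the
centre; full-corner offsets carry zero weight).  The tissue indicator
psi multiplies every neighbour reference, which annihilates links to
void nodes; together with the centre weight being the negative sum of
the others this realizes the no-flux boundary condition on the staircase
boundary of the tissue domain without any explicit boundary treatment.

The diffusion tensor is transversely isotropic,
``D = Dtrans * I + (Dpar - Dtrans) f f^T`` with f the unit fibre
direction, i.e. eigenvalues {Dpar, Dtrans, Dtrans}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import GeometryGrid

__all__ = [
    "DiffusionTensorField",
    "StencilWeights",
    "build_tensor",
    "build_weights",
    "apply_diffusion",
    "diffstep",
]


@dataclass
class DiffusionTensorField:
    """Per-node symmetric diffusion tensor derived from the fibre field."""

    Dpar: float
    Dtrans: float
    tensor: np.ndarray          # (nx, ny, nz, 3, 3); zero at void nodes


def build_tensor(geom: GeometryGrid, Dpar: float, Dtrans: float) -> DiffusionTensorField:
    """Transversely isotropic tensor D = Dtrans*I + (Dpar-Dtrans) f f^T."""
    if not (Dtrans > 0):
        raise ValueError("Dtrans must be positive")
    if Dpar < Dtrans:
        warnings.warn(
            "Dpar < Dtrans: cross-fibre diffusivity exceeds along-fibre",
            stacklevel=2,
        )
    f = geom.fibre
    outer = np.einsum("...i,...j->...ij", f, f)
    tensor = Dtrans * np.eye(3) + (Dpar - Dtrans) * outer
    tensor = tensor * geom.tissue_mask[..., None, None]
    return DiffusionTensorField(Dpar, Dtrans, tensor)


# offsets: centre first, then faces, then edges (corner offsets have zero
# weight by construction and are omitted)
_FACES = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def _edge_offsets():
    out = []
    eye = np.eye(3, dtype=int)
    for j, k in ((0, 1), (0, 2), (1, 2)):
        for sj in (1, -1):
            for sk in (1, -1):
                out.append(tuple(sj * eye[j] + sk * eye[k]))
    return out


@dataclass
class StencilWeights:
    """Per-node weight set of the discrete diffusion operator.

    ``offsets[0]`` is the centre; weights are identically zero at void
    nodes, and at tissue nodes every row sums to zero (constants are in
    the kernel of the operator).
    """

    offsets: np.ndarray         # (n_off, 3) int, centre first
    weights: np.ndarray         # (nx, ny, nz, n_off)
    h: float

    @property
    def n_off(self) -> int:
        return self.offsets.shape[0]


def _shift(padded: np.ndarray, q, shape) -> np.ndarray:
    """View of the zero-padded array shifted by offset q."""
    nx, ny, nz = shape
    return padded[
        1 + q[0]: 1 + q[0] + nx,
        1 + q[1]: 1 + q[1] + ny,
        1 + q[2]: 1 + q[2] + nz,
    ]


def build_weights(
    geom: GeometryGrid, tensor: DiffusionTensorField, h: float | None = None
) -> StencilWeights:
    """Assemble the 19-point stencil weights.

    Face weights: psi_{p+q} D_jj^p / h^2 plus the tensor-gradient
    correction psi_{p+q} psi_{p-q} (4h^2)^{-1} (+/-) sum_j (D_jk^{p+q_j}
    - D_jk^{p-q_j}); edge weights: psi_{p+q} (+/-) D_jk^p / (2 h^2);
    centre: negative sum of all the others.  In the gradient correction
    any j-probe that lands on a void node drops that j-contribution.
    2D grids (nz = 1) restrict the offsets to the z = 0 plane.
    """
    if h is None:
        h = geom.h
    if h <= 0:
        raise ValueError("space step h must be positive")
    shape = geom.shape
    two_d = geom.nz == 1

    psi = geom.tissue_mask.astype(float)
    psi_pad = np.zeros((shape[0] + 2, shape[1] + 2, shape[2] + 2))
    psi_pad[1:-1, 1:-1, 1:-1] = psi
    D_pad = np.zeros((shape[0] + 2, shape[1] + 2, shape[2] + 2, 3, 3))
    D_pad[1:-1, 1:-1, 1:-1] = tensor.tensor

    offsets = [(0, 0, 0)]
    for q in _FACES + _edge_offsets():
        if two_d and q[2] != 0:
            continue
        offsets.append(q)
    offsets = np.array(offsets, dtype=np.intp)

    n_off = offsets.shape[0]
    W = np.zeros(shape + (n_off,))
    eye = np.eye(3, dtype=int)
    h2 = h * h

    for oi in range(1, n_off):
        q = offsets[oi]
        nz_axes = np.nonzero(q)[0]
        psi_q = _shift(psi_pad, q, shape)
        if len(nz_axes) == 1:                       # face +/- e_k
            k_ax = int(nz_axes[0])
            s = int(q[k_ax])
            w = psi_q * tensor.tensor[..., k_ax, k_ax] / h2
            # gradient correction, needs both +/- e_k neighbours in tissue
            psi_mq = _shift(psi_pad, -q, shape)
            corr = np.zeros(shape)
            for j_ax in range(3):
                if two_d and j_ax == 2:
                    continue
                ej = eye[j_ax]
                m_j = _shift(psi_pad, ej, shape) * _shift(psi_pad, -ej, shape)
                dD = (
                    _shift(D_pad[..., j_ax, k_ax], ej, shape)
                    - _shift(D_pad[..., j_ax, k_ax], -ej, shape)
                )
                corr += m_j * dD
            w = w + psi_q * psi_mq * s * corr / (4.0 * h2)
        else:                                       # edge +/- (e_j +/- e_k)
            j_ax, k_ax = (int(a) for a in nz_axes)
            sign = int(q[j_ax]) * int(q[k_ax])
            w = psi_q * sign * tensor.tensor[..., j_ax, k_ax] / (2.0 * h2)
        W[..., oi] = w * psi

    W[..., 0] = -W[..., 1:].sum(axis=-1)
    return StencilWeights(offsets=offsets, weights=W, h=h)


def apply_diffusion(u: np.ndarray, weights: StencilWeights) -> np.ndarray:
    """(L u)_p = sum_q W_q^p u_{p+q}; zero at void nodes.

    References to out-of-grid or void neighbours carry zero weight, so
    the values of ``u`` there never enter.
    """
    shape = weights.weights.shape[:3]
    if u.shape != shape:
        raise ValueError(f"field shape {u.shape} != grid shape {shape}")
    u_pad = np.zeros((shape[0] + 2, shape[1] + 2, shape[2] + 2))
    u_pad[1:-1, 1:-1, 1:-1] = u
    Lu = weights.weights[..., 0] * u
    for oi in range(1, weights.n_off):
        Lu += weights.weights[..., oi] * _shift(u_pad, weights.offsets[oi], shape)
    return Lu


def diffstep(u: np.ndarray, weights: StencilWeights, k: float) -> np.ndarray:
    """Forward Euler substep with the diffusion term: u + k L u."""
    if k < 0:
        raise ValueError("time step k must be non-negative")
    return u + k * apply_diffusion(u, weights)
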