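"""Regular-grid tissue geometries.

A geometry is a regular cuboidal grid of nodes, each carrying an integer
*status* (0 = void, nonzero = tissue) and a fibre-direction unit vector.
Irregular anatomies are represented by inscribing them into the smallest
enclosing cuboid; the status array is the grid indicator function of the
tissue domain, and no-flux boundary conditions emerge from it in the
diffusion stencil rather than from any explicit boundary description.

Geometries are stored on disk in the ``.bbg`` ASCII format: one node per
line, ``x, y, z, status, fibre_x, fibre_y, fibre_z``, with only tissue
points required to be listed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryGrid",
    "Subdomain",
    "SubdomainPlan",
    "GeometryError",
    "read_bbg",
    "write_bbg",
    "make_disk",
    "make_ball",
    "make_box",
    "make_thickness_step",
    "partition_plan",
]

_FIBRE_TOL = 1e-9


class GeometryError(ValueError):
    """Malformed geometry file or invalid geometry."""


@dataclass
class GeometryGrid:
    """Regular 3D grid with tissue indicator and per-node fibre vectors.

    Attributes
    ----------
    nx, ny, nz : int
        Node counts per axis.  2D problems use ``nz = 1``.
    h : float
        Space step; the physical coordinate of node ``(i, j, k)`` is
        ``(i*h, j*h, k*h)`` (0-based integer indexing).
    status : ndarray of int, shape (nx, ny, nz)
        Tissue indicator; 0 is void, any nonzero value is tissue (the
        value itself is preserved for future use as a tissue-type label).
    fibre : ndarray of float, shape (nx, ny, nz, 3)
        Fibre direction; unit length at tissue nodes, meaningless at void
        nodes.
    """

    nx: int
    ny: int
    nz: int
    h: float
    status: np.ndarray
    fibre: np.ndarray

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int32).reshape(
            self.nx, self.ny, self.nz
        )
        self.fibre = np.asarray(self.fibre, dtype=np.float64).reshape(
            self.nx, self.ny, self.nz, 3
        )

    # -- derived views ------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def tissue_mask(self) -> np.ndarray:
        """Boolean indicator (the grid function psi)."""
        return self.status != 0

    @property
    def n_tissue(self) -> int:
        return int(np.count_nonzero(self.status))

    def validate(self, anisotropy: bool = True) -> None:
        """Check invariants; raise :class:`GeometryError` on violation."""
        if self.h <= 0:
            raise GeometryError("space step h must be positive")
        if self.n_tissue == 0:
            raise GeometryError("geometry contains no tissue points")
        if anisotropy:
            norms = np.linalg.norm(self.fibre[self.tissue_mask], axis=-1)
            if np.any(np.abs(norms - 1.0) > _FIBRE_TOL):
                raise GeometryError(
                    "fibre vectors at tissue points are not unit length"
                )

    def normalize_fibres(self, anisotropy: bool = True) -> None:
        """Renormalize fibre vectors at tissue nodes to unit length."""
        mask = self.tissue_mask
        vec = self.fibre[mask]
        norms = np.linalg.norm(vec, axis=-1)
        if np.any(norms < _FIBRE_TOL):
            if anisotropy:
                raise GeometryError(
                    "tissue point with zero-length fibre vector "
                    "(anisotropy requested)"
                )
            vec[norms < _FIBRE_TOL] = (1.0, 0.0, 0.0)
            norms = np.linalg.norm(vec, axis=-1)
        self.fibre[mask] = vec / norms[:, None]


# ---------------------------------------------------------------------
# .bbg input / output
# ---------------------------------------------------------------------

def read_bbg(
    path,
    h: float = 1.0,
    shape: tuple[int, int, int] | None = None,
    anisotropy: bool = True,
) -> GeometryGrid:
    """Read a ``.bbg`` geometry file.

    Each non-blank, non-comment line must contain 4 or 7 comma-separated
    numeric fields: ``x, y, z, status[, fx, fy, fz]``.  Nodes absent from
    the file get status 0 (void); fibre vectors of void lines are
    ignored; fibre vectors at tissue points are renormalized to unit
    length.  4-field lines default the fibre to (1, 0, 0) (isotropic
    runs).

    Parameters
    ----------
    shape
        Grid dimensions ``(nx, ny, nz)``; if omitted they are inferred
        as max coordinate + 1 per axis.
    """
    coords: list[tuple[int, int, int]] = []
    statuses: list[int] = []
    fibres: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = [f.strip() for f in line.split(",")]
            if len(fields) not in (4, 7):
                raise GeometryError(
                    f"{path}:{lineno}: expected 4 or 7 comma-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                x, y, z = (int(float(fields[i])) for i in range(3))
                st = int(float(fields[3]))
                if len(fields) == 7:
                    fx, fy, fz = (float(fields[i]) for i in range(4, 7))
                else:
                    fx, fy, fz = 1.0, 0.0, 0.0
            except ValueError as exc:
                raise GeometryError(
                    f"{path}:{lineno}: non-numeric field ({exc})"
                ) from None
            if x < 0 or y < 0 or z < 0:
                raise GeometryError(
                    f"{path}:{lineno}: negative node coordinates"
                )
            coords.append((x, y, z))
            statuses.append(st)
            fibres.append((fx, fy, fz))

    if shape is None:
        if not coords:
            raise GeometryError(f"{path}: no tissue points in file")
        arr = np.array(coords)
        shape = tuple(int(m) + 1 for m in arr.max(axis=0))
    nx, ny, nz = shape

    status = np.zeros((nx, ny, nz), dtype=np.int32)
    fibre = np.zeros((nx, ny, nz, 3))
    fibre[..., 0] = 1.0
    seen: set[tuple[int, int, int]] = set()
    dupes = 0
    for (x, y, z), st, f in zip(coords, statuses, fibres):
        if x >= nx or y >= ny or z >= nz:
            raise GeometryError(
                f"{path}: node ({x},{y},{z}) outside declared grid {shape}"
            )
        if (x, y, z) in seen:
            dupes += 1
        seen.add((x, y, z))
        status[x, y, z] = st          # last occurrence wins
        if st != 0:
            fibre[x, y, z] = f
    if dupes:
        warnings.warn(
            f"{path}: {dupes} duplicate node coordinate(s); last wins",
            stacklevel=2,
        )

    geom = GeometryGrid(nx, ny, nz, h, status, fibre)
    if geom.n_tissue == 0:
        raise GeometryError(f"{path}: no tissue points in file")
    geom.normalize_fibres(anisotropy=anisotropy)
    geom.validate(anisotropy=anisotropy)
    return geom


def write_bbg(geom: GeometryGrid, path) -> None:
    """Write a geometry to ``.bbg``; only tissue points are emitted."""
    geom.validate(anisotropy=False)
    xs, ys, zs = np.nonzero(geom.status)
    with open(path, "w") as fh:
        for x, y, z in zip(xs, ys, zs):
            st = geom.status[x, y, z]
            fx, fy, fz = geom.fibre[x, y, z]
            fh.write(f"{x}, {y}, {z}, {st}, {fx:.17g}, {fy:.17g}, {fz:.17g}\n")


# ---------------------------------------------------------------------
# Synthetic geometry generators
# ---------------------------------------------------------------------

def _disk_like(radius, h, offset3, two_d: bool) -> GeometryGrid:
    if radius <= 0 or h <= 0:
        raise GeometryError("radius and h must be positive")
    if radius < h:
        raise GeometryError(
            f"radius {radius} < space step {h}: degenerate domain"
        )
    m = int(np.ceil(radius / h)) + 1          # centre index; >= 1-node rind
    n = 2 * m + 2                             # room for fractional offsets
    centre = np.array([(m + o) * h for o in offset3])
    idx = np.arange(n) * h
    if two_d:
        X, Y = np.meshgrid(idx, idx, indexing="ij")
        r2 = (X - centre[0]) ** 2 + (Y - centre[1]) ** 2
        status = (r2 <= radius**2 + 1e-14).astype(np.int32)[..., None]
        shape = (n, n, 1)
    else:
        X, Y, Z = np.meshgrid(idx, idx, idx, indexing="ij")
        r2 = (
            (X - centre[0]) ** 2
            + (Y - centre[1]) ** 2
            + (Z - centre[2]) ** 2
        )
        status = (r2 <= radius**2 + 1e-14).astype(np.int32)
        shape = (n, n, n)
    fibre = np.zeros(shape + (3,))
    fibre[..., 0] = 1.0
    geom = GeometryGrid(*shape, h, status, fibre)
    geom.validate()
    # the construction guarantees a void rind; assert it
    if (
        np.any(geom.status[0]) or np.any(geom.status[-1])
        or np.any(geom.status[:, 0]) or np.any(geom.status[:, -1])
        or (not two_d and (np.any(geom.status[:, :, 0]) or np.any(geom.status[:, :, -1])))
    ):
        raise GeometryError("tissue touches the grid boundary (no rind)")
    return geom


def make_disk(radius: float, h: float, centre_offset=(0.0, 0.0)) -> GeometryGrid:
    """2D disk of given physical radius, boundary included.

    ``centre_offset`` shifts the disk centre relative to the grid in
    units of ``h`` (used to probe grid-placement sensitivity of the
    discretization).  A one-node rind of void surrounds the disk, and
    fibres default to (1, 0, 0).
    """
    dx, dy = centre_offset
    return _disk_like(radius, h, (dx, dy, 0.0), two_d=True)


def make_ball(radius: float, h: float, centre_offset=(0.0, 0.0, 0.0)) -> GeometryGrid:
    """3D ball analogue of :func:`make_disk`."""
    return _disk_like(radius, h, tuple(centre_offset), two_d=False)


def make_box(nx: int, ny: int, nz: int = 1, h: float = 1.0, rind: int = 0) -> GeometryGrid:
    """Full cuboid of tissue, optionally surrounded by a void rind.

    With ``rind = r`` the tissue block keeps the given dimensions and the
    grid is enlarged by ``r`` void nodes on every side (``z`` only if
    ``nz > 1``).
    """
    if min(nx, ny, nz) < 1:
        raise GeometryError("box dimensions must be positive")
    rz = rind if nz > 1 else 0
    NX, NY, NZ = nx + 2 * rind, ny + 2 * rind, nz + 2 * rz
    status = np.zeros((NX, NY, NZ), dtype=np.int32)
    status[rind:rind + nx, rind:rind + ny, rz:rz + nz] = 1
    fibre = np.zeros((NX, NY, NZ, 3))
    fibre[..., 0] = 1.0
    geom = GeometryGrid(NX, NY, NZ, h, status, fibre)
    geom.validate()
    return geom


def make_thickness_step(
    nx: int, ny: int, z_thin: int, z_thick: int, x_step: int, h: float = 1.0
) -> GeometryGrid:
    """Slab whose thickness jumps from ``z_thin`` to ``z_thick`` at ``x_step``.

    Emulates the thickness-step domains used to study scroll-wave drift
    along sharp thickness variations.  One-node void rind on all sides.
    """
    if not (0 < z_thin <= z_thick):
        raise GeometryError("need 0 < z_thin <= z_thick")
    if not (0 < x_step < nx):
        raise GeometryError("x_step must split the x-range")
    NX, NY, NZ = nx + 2, ny + 2, z_thick + 2
    status = np.zeros((NX, NY, NZ), dtype=np.int32)
    status[1:1 + x_step, 1:1 + ny, 1:1 + z_thin] = 1
    status[1 + x_step:1 + nx, 1:1 + ny, 1:1 + z_thick] = 1
    fibre = np.zeros((NX, NY, NZ, 3))
    fibre[..., 0] = 1.0
    geom = GeometryGrid(NX, NY, NZ, h, status, fibre)
    geom.validate()
    return geom


# ---------------------------------------------------------------------
# Domain partitioning (planning only; no message passing)
# ---------------------------------------------------------------------

@dataclass
class Subdomain:
    """One cuboidal piece of a partition plan."""

    x_range: tuple[int, int]   # half-open [lo, hi)
    y_range: tuple[int, int]
    z_range: tuple[int, int]
    tissue_count: int
    allocated: bool


@dataclass
class SubdomainPlan:
    """Partition of the grid into near-equal cuboidal subdomains.

    Subdomains with no tissue points are flagged unallocated (idle
    partitions are not assigned to processes).
    """

    splits: tuple[int, int, int]
    subdomains: list[Subdomain] = field(default_factory=list)

    @property
    def n_allocated(self) -> int:
        return sum(s.allocated for s in self.subdomains)

    @property
    def load_stats(self) -> dict:
        loads = [s.tissue_count for s in self.subdomains if s.allocated]
        return {
            "max_tissue": max(loads),
            "mean_tissue": float(np.mean(loads)),
            "n_allocated": len(loads),
            "n_idle": len(self.subdomains) - len(loads),
        }


def _axis_intervals(n: int, s: int) -> list[tuple[int, int]]:
    """Split ``n`` nodes into ``s`` near-equal intervals.

    Remainder goes to the lowest-index subintervals, so interval lengths
    differ by at most one and sum to ``n``.
    """
    base, rem = divmod(n, s)
    bounds = [0]
    for i in range(s):
        bounds.append(bounds[-1] + base + (1 if i < rem else 0))
    return [(bounds[i], bounds[i + 1]) for i in range(s)]


def partition_plan(geom: GeometryGrid, splits: tuple[int, int, int]) -> SubdomainPlan:
    """Plan a domain decomposition into ``sx * sy * sz`` subdomains."""
    sx, sy, sz = splits
    for s, n, name in ((sx, geom.nx, "x"), (sy, geom.ny, "y"), (sz, geom.nz, "z")):
        if not 1 <= s <= n:
            raise GeometryError(
                f"splits along {name} must be in [1, {n}], got {s}"
            )
    plan = SubdomainPlan(splits=(sx, sy, sz))
    xint = _axis_intervals(geom.nx, sx)
    yint = _axis_intervals(geom.ny, sy)
    zint = _axis_intervals(geom.nz, sz)
    for xr in xint:
        for yr in yint:
            for zr in zint:
                count = int(
                    np.count_nonzero(
                        geom.status[xr[0]:xr[1], yr[0]:yr[1], zr[0]:zr[1]]
                    )
                )
                plan.subdomains.append(
                    Subdomain(xr, yr, zr, count, allocated=count > 0)
                )
    return plan
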