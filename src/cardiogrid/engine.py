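"""The device ring: ordered device execution, one turn per time step.

A simulation is an ordered list of *devices* sharing a 4D state grid
(space x layers) and a set of named global variables.  Each turn, every
device whose *when*-flag is nonzero executes, in declaration order; the
integer step counter ``t`` increments after the last device.  Devices
may be restricted to a cuboidal subgrid, or declared *nowhere* (they
touch only global variables).  Stimulation protocols, feedback loops,
measurements and file output are all assembled from devices, so a
complete experiment is described by one declarative configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import diffusion as _diff
from . import ode_solvers as _ode
from .cell_models import get_ionic_model, get_rhs_model
from .elliptic import EllipticProblem, EllipticSolver
from .expressions import ExpressionError, compile_expr, parse_program
from .geometry import GeometryGrid, make_box

__all__ = [
    "StateGrid", "Device", "DeviceRing", "EngineError", "StopRun",
    "KFunc", "Reduce", "KPoincare", "KPrint", "Record", "Stop",
    "Diff", "DiffStep", "EulerDevice", "RK4Device", "RushLarsenDevice",
    "EllipticDevice", "PpmOut", "SingZ", "Dump", "Load",
    "run_ring", "feedback_force", "phase_distribution_ic", "singz_find",
    "ppm_bytes", "DEVICE_REGISTRY",
]


class EngineError(RuntimeError):
    """Configuration or runtime error in the device ring."""


class StopRun(Exception):
    """Raised by the stop device to terminate the run."""


# ---------------------------------------------------------------------
# State
# ---------------------------------------------------------------------

class StateGrid:
    """4D computational grid plus named global variables.

    ``values`` has shape (nx, ny, nz, nv): three space dimensions and a
    layer index.  Dynamic fields, diffusion terms, scratch areas and
    space-dependent parameters all live in layers.  Global variables are
    single-valued reals shared by all devices; ``t`` is the integer turn
    counter.
    """

    def __init__(self, geom: GeometryGrid, nv: int, grid_only: bool = False):
        if nv < 1:
            raise EngineError("need at least one layer")
        self.geom = geom
        self.nv = nv
        self.values = np.zeros(geom.shape + (nv,))
        self.globals: dict[str, float] = {"t": 0}
        self.grid_only = grid_only
        self.log: list[str] = []

    @classmethod
    def from_box(cls, xmax: int, ymax: int, zmax: int = 1, vmax: int = 1,
                 h: float = 1.0) -> "StateGrid":
        """Geometry-less cuboid run; the outermost node shell is void,
        providing the extra rind of points that carries the no-flux
        boundary (z only if the grid is 3D)."""
        rz = 1 if zmax > 2 else 0
        geom = make_box(xmax - 2, ymax - 2, max(zmax - 2 * rz, 1), h=h, rind=1)
        return cls(geom, vmax, grid_only=True)

    @classmethod
    def from_geometry(cls, geom: GeometryGrid, vmax: int) -> "StateGrid":
        return cls(geom, vmax)

    def layer(self, v: int) -> np.ndarray:
        if not 0 <= v < self.nv:
            raise EngineError(f"layer index {v} out of range [0, {self.nv})")
        return self.values[..., v]

    @property
    def t(self) -> int:
        return int(self.globals["t"])

    def dims_context(self) -> dict:
        g = self.geom
        return {"xmax": g.nx, "ymax": g.ny, "zmax": g.nz, "vmax": self.nv}


def _region_slices(state: StateGrid, r: dict) -> tuple[slice, slice, slice]:
    g = state.geom
    x0 = int(r.get("x0", 0)); x1 = int(r.get("x1", g.nx - 1))
    y0 = int(r.get("y0", 0)); y1 = int(r.get("y1", g.ny - 1))
    z0 = int(r.get("z0", 0)); z1 = int(r.get("z1", g.nz - 1))
    if not (0 <= x0 <= x1 < g.nx and 0 <= y0 <= y1 < g.ny
            and 0 <= z0 <= z1 < g.nz):
        raise EngineError(f"space restriction {r} outside the grid")
    return slice(x0, x1 + 1), slice(y0, y1 + 1), slice(z0, z1 + 1)


# ---------------------------------------------------------------------
# Devices
# ---------------------------------------------------------------------

_RESTR_KEYS = ("x0", "x1", "y0", "y1", "z0", "z1")


class Device:
    """Base device: when-flag gating and space restriction plumbing."""

    devname = "device"

    def __init__(self, when: str | None = None, name: str | None = None,
                 nowhere: bool = False, **restriction):
        bad = set(restriction) - set(_RESTR_KEYS)
        if bad:
            raise EngineError(f"{self.devname}: unknown parameters {sorted(bad)}")
        self.when = when
        self.name = name or self.devname
        self.nowhere = bool(nowhere)
        self.restriction = restriction

    def setup(self, state: StateGrid) -> None:
        self._sl = _region_slices(state, self.restriction)

    def fires(self, state: StateGrid) -> bool:
        if self.when is None:
            return True
        try:
            return float(state.globals[self.when]) != 0.0
        except KeyError:
            raise EngineError(
                f"{self.name}: unknown when-variable {self.when!r}"
            ) from None

    def run(self, state: StateGrid) -> None:
        raise NotImplementedError

    def describe(self) -> str:
        parts = [self.devname]
        if self.name != self.devname:
            parts.append(f"name={self.name}")
        if self.when:
            parts.append(f"when={self.when}")
        if self.nowhere:
            parts.append("nowhere=1")
        parts += [f"{k}={v}" for k, v in self.restriction.items()]
        return " ".join(parts)


def _layer_index(target: str) -> int | None:
    import re
    m = re.fullmatch(r"u(\d+)", target)
    return int(m.group(1)) if m else None


class KFunc(Device):
    """Evaluate an ordered assignment program.

    In *nowhere* mode the targets are global variables and the program
    runs once per firing.  In grid mode the targets are layers
    (``u0``, ``u1``, ...) and the program is evaluated independently at
    every node of the restriction, with ``x, y, z`` bound to the node
    indices; assignments execute in order, each seeing the previous
    one's writes.
    """

    devname = "k_func"

    def __init__(self, pgm, **kw):
        super().__init__(**kw)
        self.pgm_src = pgm

    def setup(self, state):
        super().setup(state)
        self.prog = parse_program(self.pgm_src)
        for target, _ in self.prog:
            li = _layer_index(target)
            if self.nowhere and li is not None:
                raise EngineError(
                    f"{self.name}: layer write {target} in nowhere mode"
                )
            if not self.nowhere and li is not None and li >= state.nv:
                raise EngineError(f"{self.name}: layer {li} out of range")

    def run(self, state):
        if self.nowhere:
            ctx = dict(state.dims_context())
            ctx.update(state.globals)
            for target, ex in self.prog:
                val = ex(ctx)
                ctx[target] = val
                state.globals[target] = float(val)
            return
        sl = self._sl
        ctx = dict(state.dims_context())
        ctx.update(state.globals)
        shape = state.values[sl][..., 0].shape
        X, Y, Z = np.meshgrid(
            np.arange(sl[0].start, sl[0].stop),
            np.arange(sl[1].start, sl[1].stop),
            np.arange(sl[2].start, sl[2].stop),
            indexing="ij",
        )
        ctx.update({"x": X.astype(float), "y": Y.astype(float),
                    "z": Z.astype(float)})
        for v in range(state.nv):
            ctx[f"u{v}"] = state.values[sl + (v,)].copy()
        written = set()
        for target, ex in self.prog:
            li = _layer_index(target)
            if li is None:
                raise EngineError(
                    f"{self.name}: grid-mode target {target!r} is not a layer"
                )
            val = np.broadcast_to(np.asarray(ex(ctx), dtype=float), shape)
            ctx[target] = val.copy()
            written.add(li)
        for li in written:
            state.values[sl + (li,)] = ctx[f"u{li}"]


class Reduce(Device):
    """Reduce a layer over the tissue nodes of the restriction into a
    global variable (max, min, sum or mean)."""

    devname = "reduce"
    _OPS = {"max": np.max, "min": np.min, "sum": np.sum, "mean": np.mean}

    def __init__(self, operation: str, v0: int, result: str, **kw):
        super().__init__(**kw)
        if operation not in self._OPS:
            raise EngineError(f"reduce: unknown operation {operation!r}")
        self.operation = operation
        self.v0 = int(v0)
        self.result = result

    def setup(self, state):
        super().setup(state)
        self._mask = state.geom.tissue_mask[self._sl]
        if not np.any(self._mask):
            raise EngineError(
                f"{self.name}: restriction contains no tissue points"
            )

    def run(self, state):
        vals = state.values[self._sl + (self.v0,)][self._mask]
        state.globals[self.result] = float(self._OPS[self.operation](vals))


class KPoincare(Device):
    """Event detector on a global signal (Poincare cross-section).

    The first assignment of the program names the event flag and gives
    the monitored expression; the remaining assignments run only on the
    turn of an event.  With ``sign=+1`` an event fires when the
    expression becomes >= 0 after being < 0 on the previous turn
    (symmetric for ``sign=-1``).
    """

    devname = "k_poincare"

    def __init__(self, pgm, sign: int = 1, **kw):
        kw.setdefault("nowhere", True)
        super().__init__(**kw)
        if sign not in (1, -1):
            raise EngineError("k_poincare: sign must be +1 or -1")
        self.sign = sign
        self.pgm_src = pgm

    def setup(self, state):
        super().setup(state)
        prog = parse_program(self.pgm_src)
        if not prog:
            raise EngineError(f"{self.name}: empty program")
        self.flag_target, self.signal_expr = prog[0]
        self.event_prog = prog[1:]
        self._prev = None

    def run(self, state):
        ctx = dict(state.dims_context())
        ctx.update(state.globals)
        val = float(self.signal_expr(ctx))
        if self._prev is None:
            event = False
        elif self.sign == 1:
            event = self._prev < 0.0 <= val
        else:
            event = self._prev > 0.0 >= val
        self._prev = val
        state.globals[self.flag_target] = 1.0 if event else 0.0
        if event:
            ctx[self.flag_target] = 1.0
            for target, ex in self.event_prog:
                v = float(ex(ctx))
                ctx[target] = v
                state.globals[target] = v


class KPrint(Device):
    """Print a list of global expressions, one line per firing."""

    devname = "k_print"

    def __init__(self, expressions: list[str], file=None, **kw):
        kw.setdefault("nowhere", True)
        super().__init__(**kw)
        self.expr_src = list(expressions)
        self.file = file
        self.lines: list[str] = []

    def setup(self, state):
        super().setup(state)
        self.exprs = [compile_expr(e) for e in self.expr_src]
        if self.file:
            open(self.file, "w").close()

    def run(self, state):
        ctx = dict(state.dims_context())
        ctx.update(state.globals)
        line = " ".join(f"{float(e(ctx)):+.7e}" for e in self.exprs)
        self.lines.append(line)
        if self.file:
            with open(self.file, "a") as fh:
                fh.write(line + "\n")


class Record(Device):
    """Fixed-width ASCII output of a 4D subgrid, one line per firing.

    Values are formatted ``%+.7e`` and flattened x-fastest in space
    (then y, then z) with the layer index fastest of all, so each
    record's position in the file is computable.
    """

    devname = "record"

    def __init__(self, v0: int = 0, v1: int | None = None, file=None, **kw):
        super().__init__(**kw)
        self.v0 = int(v0)
        self.v1 = int(v1 if v1 is not None else v0)
        self.file = file
        self.lines: list[str] = []

    def setup(self, state):
        super().setup(state)
        if not 0 <= self.v0 <= self.v1 < state.nv:
            raise EngineError(f"{self.name}: bad layer range")
        if self.file:
            open(self.file, "w").close()

    def run(self, state):
        sl = self._sl
        block = state.values[sl + (slice(self.v0, self.v1 + 1),)]
        # (x, y, z, v) -> iterate z slowest, then y, then x, v fastest
        flat = block.transpose(2, 1, 0, 3).ravel()
        line = " ".join(f"{v:+.7e}" for v in flat)
        self.lines.append(line)
        if self.file:
            with open(self.file, "a") as fh:
                fh.write(line + "\n")


class Stop(Device):
    """Terminate the run at this ring position."""

    devname = "stop"

    def run(self, state):
        raise StopRun


class Diff(Device):
    """Compute the anisotropic diffusion term of layer v0 into layer v1."""

    devname = "diff"

    def __init__(self, v0: int, v1: int, Dpar: float | None = None,
                 Dtrans: float | None = None, D: float | None = None,
                 hx: float | None = None, **kw):
        super().__init__(**kw)
        if D is not None:
            Dpar = Dtrans = D
        if Dpar is None or Dtrans is None:
            raise EngineError(f"{self.devname}: diffusivities required")
        self.v0, self.v1 = int(v0), int(v1)
        self.Dpar, self.Dtrans = float(Dpar), float(Dtrans)
        self.hx = hx

    def setup(self, state):
        super().setup(state)
        h = self.hx if self.hx is not None else state.geom.h
        tensor = _diff.build_tensor(state.geom, self.Dpar, self.Dtrans)
        self.weights = _diff.build_weights(state.geom, tensor, h)
        self._mask = np.zeros(state.geom.shape, dtype=bool)
        self._mask[self._sl] = state.geom.tissue_mask[self._sl]

    def run(self, state):
        Lu = _diff.apply_diffusion(state.layer(self.v0), self.weights)
        state.values[..., self.v1][self._mask] = Lu[self._mask]


class DiffStep(Diff):
    """Diffusion substep: deposit the diffusion term in the scratch layer
    v1, then forward-Euler-advance layer v0 with it."""

    devname = "diffstep"

    def __init__(self, *args, ht: float, **kw):
        super().__init__(*args, **kw)
        if ht <= 0:
            raise EngineError("diffstep: ht must be positive")
        self.ht = float(ht)

    def run(self, state):
        Lu = _diff.apply_diffusion(state.layer(self.v0), self.weights)
        m = self._mask
        state.values[..., self.v1][m] = Lu[m]
        state.values[..., self.v0][m] += self.ht * Lu[m]


def _resolve_params(par: dict, state: StateGrid, sl, mask):
    """Resolve device kinetics parameters: numbers pass through,
    ``"@<layer>"`` binds to per-node layer values inside the restriction,
    strings evaluate as global expressions."""
    out = {}
    ctx = None
    for key, val in par.items():
        if isinstance(val, str):
            v = val.strip()
            if v.startswith("@"):
                out[key] = state.values[sl + (int(v[1:]),)][mask]
                continue
            if ctx is None:
                ctx = dict(state.dims_context())
                ctx.update(state.globals)
            out[key] = float(compile_expr(v)(ctx))
        else:
            out[key] = val
    return out


class EulerDevice(Device):
    """Forward Euler step of an rhs kinetics model on layers v0..v1."""

    devname = "euler"
    _step = staticmethod(_ode.euler_step)

    def __init__(self, v0: int, v1: int, ht: float, ode: str,
                 par: dict | None = None, **kw):
        super().__init__(**kw)
        self.v0, self.v1 = int(v0), int(v1)
        self.ht = float(ht)
        self.model = get_rhs_model(ode)
        self.par = par or {}

    def setup(self, state):
        super().setup(state)
        span = self.v1 - self.v0 + 1
        if span != self.model.n_var:
            raise EngineError(
                f"{self.name}: layers v0..v1 span {span} but model "
                f"{self.model.name} has {self.model.n_var} variables"
            )
        self._mask = state.geom.tissue_mask[self._sl]

    def run(self, state):
        sl = self._sl
        m = self._mask
        sub = state.values[sl + (slice(self.v0, self.v1 + 1),)]
        y = sub[m]
        params = _resolve_params(self.par, state, sl, m)
        sub[m] = self._step(y, self.model, params, self.ht)


class RK4Device(EulerDevice):
    """Classical RK4 step of an rhs kinetics model."""

    devname = "rk4"
    _step = staticmethod(_ode.rk4_step)


class RushLarsenDevice(Device):
    """Exponential (Rush-Larsen / matrix Rush-Larsen) step of an ionic
    model, with start-up tabulation of its univariate coefficients."""

    devname = "rushlarsen"

    def __init__(self, v0: int, v1: int, ht: float, ionic: str,
                 par: dict | None = None, tab_n: int = 20000,
                 ionic_kwargs: dict | None = None, **kw):
        super().__init__(**kw)
        self.v0, self.v1 = int(v0), int(v1)
        self.ht = float(ht)
        self.spec = get_ionic_model(ionic, **(ionic_kwargs or {}))
        self.par = par or {}
        self.tab_n = int(tab_n)

    def setup(self, state):
        super().setup(state)
        span = self.v1 - self.v0 + 1
        if span != self.spec.n_var:
            raise EngineError(
                f"{self.name}: layers span {span} != {self.spec.n_var} "
                f"variables of {self.spec.name}"
            )
        self._mask = state.geom.tissue_mask[self._sl]
        self.tables = _ode.tabulate_ionic(self.spec, self.ht, self.tab_n)

    def run(self, state):
        sl = self._sl
        m = self._mask
        sub = state.values[sl + (slice(self.v0, self.v1 + 1),)]
        params = _resolve_params(self.par, state, sl, m)
        sub[m] = _ode.ionic_step(sub[m], self.spec, self.ht, self.tables, params)


class EllipticDevice(Device):
    """Solve the elliptic equation A phi = S for layer v1 from the
    right-hand side in layer v0 (warm-started from the previous phi)."""

    devname = "elliptic"

    def __init__(self, v0: int, v1: int, Dpar: float, Dtrans: float,
                 hx: float | None = None, tolerance: float = 1e-8,
                 delta: float = 0.5, upper_level: int = 3, vcycles: int = 20,
                 preiter: int = 1, postiter: int = 2, maxiter: float = 1e6,
                 xpin: int | None = None, ypin: int = 0, zpin: int = 0,
                 upin: float = 0.0, strict: bool = True, **kw):
        super().__init__(**kw)
        self.v0, self.v1 = int(v0), int(v1)
        self.pars = dict(
            Dpar=Dpar, Dtrans=Dtrans, hx=hx, tolerance=tolerance, delta=delta,
            upper_level=upper_level, vcycles=vcycles, preiter=preiter,
            postiter=postiter, maxiter=maxiter,
        )
        self.pin = (int(xpin), int(ypin), int(zpin)) if xpin is not None else None
        self.upin = float(upin)
        self.strict = strict

    def setup(self, state):
        super().setup(state)
        p = self.pars
        g = state.geom
        h = p["hx"] if p["hx"] is not None else g.h
        tensor = _diff.build_tensor(g, p["Dpar"], p["Dtrans"])
        weights = _diff.build_weights(g, tensor, h)
        free_mask = None
        if self.restriction:
            free_mask = np.zeros(g.shape, dtype=bool)
            free_mask[self._sl] = True
        problem = EllipticProblem(
            g, weights, rhs=np.zeros(g.shape), pin=self.pin, upin=self.upin,
            free_mask=free_mask, tolerance=p["tolerance"], delta=p["delta"],
            upper_level=int(p["upper_level"]), vcycles=int(p["vcycles"]),
            preiter=int(p["preiter"]), postiter=int(p["postiter"]),
            maxiter=p["maxiter"],
            coarse_diffusivities=(p["Dpar"], p["Dtrans"]),
        )
        self.solver = EllipticSolver(problem)
        self.last_info = None

    def run(self, state):
        phi, info = self.solver.solve(
            state.layer(self.v0), u0=state.layer(self.v1)
        )
        self.last_info = info
        if not info.converged:
            msg = (f"{self.name}: elliptic solver not converged "
                   f"(residual {info.residual:.3e})")
            if self.strict:
                raise EngineError(msg)
            warnings.warn(msg, stacklevel=2)
        state.values[..., self.v1] = phi


# ---------------------------------------------------------------------
# Output devices and helpers
# ---------------------------------------------------------------------

def ppm_bytes(layers, ranges) -> bytes:
    """Discretize up to three layers to one byte per value, P6 format.

    ``layers``: (r, g, b) arrays of shape (nx, ny, nz) (None for a zero
    channel); ``ranges``: ((r0, r1), (g0, g1), (b0, b1)).  Byte value is
    round-half-up of 255 (v - v0)/(v1 - v0), clamped to [0, 255].  The
    image is nx wide and ny*nz tall (z-slices stacked), pixels ordered
    x-fastest, then y, then z.
    """
    shape = next(l.shape for l in layers if l is not None)
    nx, ny, nz = shape
    chans = []
    for lay, rng in zip(layers, ranges):
        if lay is None:
            chans.append(np.zeros(shape, dtype=np.uint8))
            continue
        v0, v1 = rng
        if v0 == v1:
            raise EngineError("ppmout: degenerate channel range")
        scaled = 255.0 * (lay - v0) / (v1 - v0)
        byte = np.floor(np.clip(scaled, 0.0, 255.0) + 0.5)
        chans.append(np.clip(byte, 0, 255).astype(np.uint8))
    # pixel order: x fastest, then y, then z -> index (z, y, x)
    rgb = np.stack([c.transpose(2, 1, 0) for c in chans], axis=-1)
    header = f"P6\n{nx} {ny * nz}\n255\n".encode()
    return header + rgb.tobytes()


class PpmOut(Device):
    """One-byte-per-value image output of up to three layers."""

    devname = "ppmout"

    def __init__(self, file: str, r=None, g=None, b=None,
                 r0=0.0, r1=1.0, g0=0.0, g1=1.0, b0=0.0, b1=1.0, **kw):
        super().__init__(**kw)
        self.file = file
        self.channels = (r, g, b)
        self.ranges = ((r0, r1), (g0, g1), (b0, b1))
        self.calls = 0
        self.last_bytes: bytes | None = None

    def run(self, state):
        layers = [
            state.layer(int(c))[self._sl] if c is not None else None
            for c in self.channels
        ]
        data = ppm_bytes(layers, self.ranges)
        self.last_bytes = data
        path = self.file % self.calls if "%" in self.file else self.file
        with open(path, "wb") as fh:
            fh.write(data)
        self.calls += 1


def singz_find(a: np.ndarray, b: np.ndarray, a0: float, b0: float,
               tissue: np.ndarray | None = None):
    """Phase singularities of a 2D slice: intersections of the isolines
    a = a0 and b = b0, located by linear interpolation along cell edges.

    Returns ``(tips, stats)`` where tips is a list of (x, y) in grid
    units and stats holds the count, per-coordinate means and standard
    deviations (NaN when no tips were found — flagged, not an error).
    Exact for fields linear in x and y.  Cells whose isoline topology is
    ambiguous (saddle cells with four edge crossings) are skipped.
    """
    a = np.asarray(a, dtype=float) - a0
    b = np.asarray(b, dtype=float) - b0
    nx, ny = a.shape
    if tissue is None:
        tissue = np.ones((nx, ny), dtype=bool)
    tips: list[tuple[float, float]] = []

    corners = ((0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0))

    def segment(f00, f10, f11, f01):
        vals = (f00, f10, f11, f01)
        pts = []
        for e in range(4):
            f1, f2 = vals[e], vals[(e + 1) % 4]
            if f1 == f2:
                continue
            if (f1 <= 0 < f2) or (f2 <= 0 < f1) or (f1 < 0 <= f2) or (f2 < 0 <= f1):
                tloc = f1 / (f1 - f2)
                if 0.0 <= tloc <= 1.0:
                    p1, p2 = corners[e], corners[(e + 1) % 4]
                    pts.append((p1[0] + tloc * (p2[0] - p1[0]),
                                p1[1] + tloc * (p2[1] - p1[1])))
        # drop duplicates (crossing exactly at a corner)
        uniq = []
        for p in pts:
            if all(abs(p[0] - q[0]) + abs(p[1] - q[1]) > 1e-12 for q in uniq):
                uniq.append(p)
        return uniq if len(uniq) == 2 else None

    for i in range(nx - 1):
        for j in range(ny - 1):
            if not (tissue[i, j] and tissue[i + 1, j] and tissue[i, j + 1]
                    and tissue[i + 1, j + 1]):
                continue
            sa = segment(a[i, j], a[i + 1, j], a[i + 1, j + 1], a[i, j + 1])
            if sa is None:
                continue
            sb = segment(b[i, j], b[i + 1, j], b[i + 1, j + 1], b[i, j + 1])
            if sb is None:
                continue
            (x1, y1), (x2, y2) = sa
            (x3, y3), (x4, y4) = sb
            den = (x2 - x1) * (y4 - y3) - (y2 - y1) * (x4 - x3)
            if den == 0.0:
                continue
            s = ((x3 - x1) * (y4 - y3) - (y3 - y1) * (x4 - x3)) / den
            if not 0.0 <= s <= 1.0:
                continue
            px, py = x1 + s * (x2 - x1), y1 + s * (y2 - y1)
            # the intersection must also lie within the b-segment
            lb2 = (x4 - x3) ** 2 + (y4 - y3) ** 2
            tb = ((px - x3) * (x4 - x3) + (py - y3) * (y4 - y3)) / lb2
            if not -1e-12 <= tb <= 1.0 + 1e-12:
                continue
            tips.append((i + px, j + py))

    if tips:
        arr = np.array(tips)
        stats = {
            "n": len(tips),
            "x_mean": float(arr[:, 0].mean()),
            "y_mean": float(arr[:, 1].mean()),
            "x_std": float(arr[:, 0].std()),
            "y_std": float(arr[:, 1].std()),
        }
    else:
        stats = {"n": 0, "x_mean": float("nan"), "y_mean": float("nan"),
                 "x_std": float("nan"), "y_std": float("nan")}
    return tips, stats


class SingZ(Device):
    """Find spiral-wave tips in a z-cross-section and publish their
    statistics as global variables (``<prefix>_n``, means, stds)."""

    devname = "singz"

    def __init__(self, v0: int, v1: int, c0: float, c1: float, z: int = 0,
                 file=None, prefix: str = "tip", **kw):
        super().__init__(**kw)
        self.v0, self.v1 = int(v0), int(v1)
        self.c0, self.c1 = float(c0), float(c1)
        self.z = int(z)
        self.file = file
        self.prefix = prefix
        self.tips: list = []

    def setup(self, state):
        super().setup(state)
        if self.file:
            open(self.file, "w").close()

    def run(self, state):
        a = state.layer(self.v0)[:, :, self.z]
        b = state.layer(self.v1)[:, :, self.z]
        tissue = state.geom.tissue_mask[:, :, self.z]
        tips, stats = singz_find(a, b, self.c0, self.c1, tissue)
        self.tips = tips
        for key, val in stats.items():
            state.globals[f"{self.prefix}_{key}"] = float(val)
        if self.file and tips:
            with open(self.file, "a") as fh:
                for x, y in tips:
                    fh.write(f"{state.t} {x:+.7e} {y:+.7e}\n")


class Dump(Device):
    """Full-precision binary dump of a 4D subgrid.

    Raw little-endian IEEE-754 doubles, ordered layer-slowest, then z,
    then y, with x fastest; :class:`Load` restores bit-exactly.
    """

    devname = "dump"

    def __init__(self, file: str, v0: int = 0, v1: int | None = None, **kw):
        super().__init__(**kw)
        self.file = file
        self.v0 = int(v0)
        self.v1 = v1

    def setup(self, state):
        super().setup(state)
        if self.v1 is None:
            self.v1 = state.nv - 1

    def run(self, state):
        sl = self._sl
        block = state.values[sl + (slice(self.v0, int(self.v1) + 1),)]
        data = block.transpose(3, 2, 1, 0).astype("<f8").tobytes()
        with open(self.file, "wb") as fh:
            fh.write(data)


class Load(Device):
    """Restore a subgrid from a :class:`Dump` file (bit-exact)."""

    devname = "load"

    def __init__(self, file: str, v0: int = 0, v1: int | None = None, **kw):
        super().__init__(**kw)
        self.file = file
        self.v0 = int(v0)
        self.v1 = v1

    def setup(self, state):
        super().setup(state)
        if self.v1 is None:
            self.v1 = state.nv - 1

    def run(self, state):
        sl = self._sl
        target = state.values[sl + (slice(self.v0, int(self.v1) + 1),)]
        shape = target.transpose(3, 2, 1, 0).shape
        with open(self.file, "rb") as fh:
            data = np.frombuffer(fh.read(), dtype="<f8")
        if data.size != target.size:
            raise EngineError(
                f"{self.name}: file holds {data.size} values, "
                f"subgrid needs {target.size}"
            )
        state.values[sl + (slice(self.v0, int(self.v1) + 1),)] = (
            data.reshape(shape).transpose(3, 2, 1, 0)
        )


# ---------------------------------------------------------------------
# Protocol helpers
# ---------------------------------------------------------------------

def feedback_force(T, Tfront, Tstart, Del, Dur, Amp, ht) -> float:
    """Feedback-stimulation force window.

    force = ht*Amp*ge(T,Tstart)*ge(T,Tfront+Del)*le(T,Tfront+Del+Dur):
    a pulse of amplitude Amp (scaled by the time step) lasting Dur,
    starting Del after the registered front-arrival time Tfront, armed
    only once T reaches Tstart.
    """
    on = float(T >= Tstart) * float(T >= Tfront + Del) * float(T <= Tfront + Del + Dur)
    return ht * Amp * on


def phase_distribution_ic(table: np.ndarray, phase_map: np.ndarray) -> np.ndarray:
    """Initial conditions by the phase-distribution method.

    ``table`` is a one-period recording (n rows of nv values),
    interpreted as a periodic tabulated vector-function of phase;
    ``phase_map`` assigns each node a phase in [0, 1).  Returns an array
    ``phase_map.shape + (nv,)`` with rows linearly interpolated
    (periodic wrap), so phase k/n reproduces row k verbatim.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 1:
        raise EngineError("phase table must be a non-empty 2D array")
    phases = np.asarray(phase_map, dtype=float)
    if not np.all(np.isfinite(phases)):
        raise EngineError("phase map contains non-finite values")
    n = table.shape[0]
    pos = np.mod(phases, 1.0) * n
    i0 = np.floor(pos).astype(int) % n
    i1 = (i0 + 1) % n
    frac = pos - np.floor(pos)
    return (1.0 - frac)[..., None] * table[i0] + frac[..., None] * table[i1]


# ---------------------------------------------------------------------
# The ring
# ---------------------------------------------------------------------

@dataclass
class DeviceRing:
    """Ordered device list; execution order is declaration order."""

    devices: list[Device] = field(default_factory=list)

    def append(self, device: Device) -> "DeviceRing":
        self.devices.append(device)
        return self

    def describe(self) -> str:
        return "\n".join(f"[{i}] {d.describe()}" for i, d in enumerate(self.devices))


def run_ring(ring: DeviceRing | list, state: StateGrid,
             max_turns: int | None = None, echo: bool = False) -> StateGrid:
    """Run the device ring until a stop device fires (or max_turns).

    One turn = one time step: each device executes iff its when-variable
    is nonzero, in ring order; ``t`` increments after the last device.
    The parsed ring is echoed to the run log.
    """
    devices = ring.devices if isinstance(ring, DeviceRing) else list(ring)
    has_stop = any(isinstance(d, Stop) for d in devices)
    if not has_stop and max_turns is None:
        raise EngineError("ring has no stop device and no max_turns guard")
    for d in devices:
        d.setup(state)
    echo_text = DeviceRing(devices).describe()
    state.log.append("device ring:\n" + echo_text)
    if echo:
        print(state.log[-1])
    while True:
        for d in devices:
            if not d.fires(state):
                continue
            try:
                d.run(state)
            except StopRun:
                state.log.append(f"stopped by {d.name} at t={state.t}")
                return state
            except (EngineError, ExpressionError, ZeroDivisionError) as exc:
                raise EngineError(
                    f"device {d.name!r} failed at t={state.t}: {exc}"
                ) from exc
        state.globals["t"] = state.t + 1
        if max_turns is not None and state.t >= max_turns:
            state.log.append(f"max_turns={max_turns} reached")
            return state


DEVICE_REGISTRY = {
    "k_func": KFunc,
    "reduce": Reduce,
    "k_poincare": KPoincare,
    "k_print": KPrint,
    "record": Record,
    "stop": Stop,
    "diff": Diff,
    "diffstep": DiffStep,
    "euler": EulerDevice,
    "rk4": RK4Device,
    "rushlarsen": RushLarsenDevice,
    "elliptic": EllipticDevice,
    "ppmout": PpmOut,
    "singz": SingZ,
    "dump": Dump,
    "load": Load,
}
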