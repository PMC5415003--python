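"""Device-ring semantics, devices, protocol assembly and file I/O."""

import numpy as np
import pytest

from cardiogrid.config import build_simulation
from cardiogrid.engine import (
    Diff,
    DiffStep,
    Dump,
    EngineError,
    EulerDevice,
    KFunc,
    KPoincare,
    KPrint,
    Load,
    PpmOut,
    Record,
    Reduce,
    SingZ,
    StateGrid,
    Stop,
    feedback_force,
    phase_distribution_ic,
    ppm_bytes,
    run_ring,
    singz_find,
)
from cardiogrid.geometry import make_box


def _flags(pgm):
    return KFunc(pgm=pgm, nowhere=True, name="timing")


def _ez_ring(record_file=None):
    """Compact analogue of the minimal spiral-simulation script: flag
    computation, cross-field initial conditions, periodic record,
    stop after 1000 steps, diffusion substep, Barkley kinetics."""
    state = StateGrid.from_box(12, 12, 1, vmax=3, h=0.4)
    ring = [
        _flags("begin = eq(t,0); out = eq(mod(t,10),0); end = ge(t,1000)"),
        KFunc(pgm="u0 = gt(y,6); u1 = 0.4*lt(x,6)", when="begin", name="IC"),
        Record(when="out", x0=3, x1=3, y0=4, y1=4, v0=0, v1=1,
               file=record_file),
        Stop(when="end"),
        DiffStep(v0=0, v1=2, ht=0.02, hx=0.4, D=1.0),
        EulerDevice(v0=0, v1=1, ht=0.02, ode="fhnbkl",
                    par={"a": 0.8, "b": 0.01, "eps": 0.02}),
    ]
    return state, ring


# ---------------------------------------------------------------------
# Ring semantics
# ---------------------------------------------------------------------

class TestRing:
    def test_ez_ring_fires_ic_once_and_records_101_lines(self):
        state, ring = _ez_ring()
        run_ring(ring, state)
        assert state.t == 1000
        record = ring[2]
        # record fires at t = 0, 10, ..., 1000 (it precedes stop)
        assert len(record.lines) == 101
        assert len(record.lines[0].split()) == 2   # u and v at one point
        # cross-field IC was applied exactly once, at t = 0
        assert state.values[:, :, 0, 0].max() > 0.0

    def test_stop_always_terminates_after_one_turn(self):
        state = StateGrid.from_box(4, 4, 1, vmax=1)
        run_ring([Stop()], state)
        assert state.t == 0                        # t increments after stop

    def test_ring_without_stop_needs_max_turns(self):
        state = StateGrid.from_box(4, 4, 1, vmax=1)
        with pytest.raises(EngineError, match="stop"):
            run_ring([_flags("a = 1")], state)
        run_ring([_flags("a = 1")], state, max_turns=3)
        assert state.t == 3

    def test_when_flag_gates_execution(self):
        state = StateGrid.from_box(4, 4, 1, vmax=1)
        ring = [
            _flags("odd = mod(t,2); n = 0"),
            KFunc(pgm="count = count + 1", when="odd", nowhere=True),
        ]
        state.globals["count"] = 0.0
        run_ring(ring, state, max_turns=6)
        assert state.globals["count"] == 3.0       # t = 1, 3, 5

    def test_determinism_bitwise(self):
        s1, r1 = _ez_ring()
        s2, r2 = _ez_ring()
        run_ring(r1, s1)
        run_ring(r2, s2)
        np.testing.assert_array_equal(s1.values, s2.values)

    def test_device_order_sensitivity(self):
        # splitting order matters: diffusion-then-reaction differs from
        # reaction-then-diffusion after a few turns
        def build(order):
            state = StateGrid.from_box(12, 12, 1, vmax=3, h=0.4)
            flags = _flags("begin = eq(t,0)")
            ic = KFunc(pgm="u0 = gt(y,6); u1 = 0.4*lt(x,6)", when="begin")
            d = DiffStep(v0=0, v1=2, ht=0.02, hx=0.4, D=1.0)
            e = EulerDevice(v0=0, v1=1, ht=0.02, ode="fhnbkl",
                            par={"a": 0.8, "b": 0.01, "eps": 0.02})
            ring = [flags, ic] + ([d, e] if order == "de" else [e, d])
            run_ring(ring, state, max_turns=10)
            return state.values[..., 0]

        u_de = build("de")
        u_ed = build("ed")
        assert np.abs(u_de - u_ed).max() > 1e-12

    def test_run_log_echoes_ring(self):
        state, ring = _ez_ring()
        run_ring(ring, state)
        assert "device ring" in state.log[0]
        assert "diffstep" in state.log[0]

    def test_device_error_names_device_and_turn(self):
        state = StateGrid.from_box(4, 4, 1, vmax=1)
        ring = [KFunc(pgm="a = 1/0", nowhere=True, name="boom")]
        with pytest.raises(EngineError, match="boom.*t=0"):
            run_ring(ring, state, max_turns=1)


# ---------------------------------------------------------------------
# k_func
# ---------------------------------------------------------------------

class TestKFunc:
    def test_cross_field_pattern(self):
        state = StateGrid.from_box(12, 12, 1, vmax=2)
        dev = KFunc(pgm="u0 = gt(y,6); u1 = 0.4*lt(x,6)")
        dev.setup(state)
        dev.run(state)
        X, Y = np.meshgrid(np.arange(12), np.arange(12), indexing="ij")
        np.testing.assert_array_equal(state.values[..., 0][:, :, 0], Y > 6)
        np.testing.assert_allclose(state.values[..., 1][:, :, 0],
                                   0.4 * (X < 6))

    def test_parameter_ramp_uses_dims(self):
        state = StateGrid.from_box(6, 6, 1, vmax=1)
        dev = KFunc(pgm="u0 = 0.7 + 0.1*(x - 0.5*xmax)")
        dev.setup(state)
        dev.run(state)
        expect = 0.7 + 0.1 * (np.arange(6) - 3.0)
        np.testing.assert_allclose(state.values[:, 2, 0, 0], expect)

    def test_assignments_sequential_within_turn(self):
        state = StateGrid.from_box(4, 4, 1, vmax=2)
        dev = KFunc(pgm="u0 = 2; u1 = u0 * 3")
        dev.setup(state)
        dev.run(state)
        assert state.values[1, 1, 0, 1] == 6.0

    def test_empty_program_is_noop(self):
        state = StateGrid.from_box(4, 4, 1, vmax=1)
        before = state.values.copy()
        dev = KFunc(pgm="")
        dev.setup(state)
        dev.run(state)
        np.testing.assert_array_equal(state.values, before)

    def test_layer_write_in_nowhere_mode_rejected(self):
        state = StateGrid.from_box(4, 4, 1, vmax=1)
        dev = KFunc(pgm="u0 = 1", nowhere=True)
        with pytest.raises(EngineError, match="nowhere"):
            dev.setup(state)

    def test_global_target_in_grid_mode_rejected(self):
        state = StateGrid.from_box(4, 4, 1, vmax=1)
        dev = KFunc(pgm="notalayer = 1")
        dev.setup(state)
        with pytest.raises(EngineError, match="not a layer"):
            dev.run(state)

    def test_restriction_limits_writes(self):
        state = StateGrid.from_box(8, 8, 1, vmax=1)
        dev = KFunc(pgm="u0 = 1", x0=2, x1=3, y0=2, y1=3)
        dev.setup(state)
        dev.run(state)
        assert state.values[2:4, 2:4, 0, 0].min() == 1.0
        assert state.values[..., 0].sum() == 4.0


# ---------------------------------------------------------------------
# Measurement devices
# ---------------------------------------------------------------------

class TestReduce:
    def test_max_of_constant(self):
        state = StateGrid.from_box(6, 6, 1, vmax=1)
        state.values[..., 0] = 2.5
        dev = Reduce("max", v0=0, result="sig")
        dev.setup(state)
        dev.run(state)
        assert state.globals["sig"] == 2.5

    def test_sum_over_block(self):
        state = StateGrid.from_box(6, 6, 1, vmax=1)
        state.values[1, 1, 0, 0] = 1.0
        state.values[2, 1, 0, 0] = 2.0
        state.values[1, 2, 0, 0] = 3.0
        state.values[2, 2, 0, 0] = 4.0
        dev = Reduce("sum", v0=0, result="s", x0=1, x1=2, y0=1, y1=2)
        dev.setup(state)
        dev.run(state)
        assert state.globals["s"] == 10.0

    def test_max_of_ramp_at_corner(self):
        state = StateGrid.from_box(6, 6, 1, vmax=1)
        X, Y = np.meshgrid(np.arange(6), np.arange(6), indexing="ij")
        state.values[..., 0] = (2 * X + Y)[..., None]
        dev = Reduce("max", v0=0, result="m")
        dev.setup(state)
        dev.run(state)
        # rind is void, so the max is at the largest tissue corner (4, 4)
        assert state.globals["m"] == 2 * 4 + 4

    def test_void_only_restriction_rejected(self):
        state = StateGrid.from_box(6, 6, 1, vmax=1)   # rind at x=0 is void
        dev = Reduce("max", v0=0, result="m", x0=0, x1=0)
        with pytest.raises(EngineError, match="no tissue"):
            dev.setup(state)


class TestPoincare:
    def _drive(self, values, sign=1):
        state = StateGrid.from_box(4, 4, 1, vmax=1)
        state.globals.update({"sig": 0.0, "T": 0.0, "Tfront": -1.0})
        dev = KPoincare(pgm="front = sig; Tfront = T", sign=sign)
        dev.setup(state)
        events = []
        for i, v in enumerate(values):
            state.globals["sig"] = v
            state.globals["T"] = float(i)
            dev.run(state)
            events.append(state.globals["front"])
        return state, events

    def test_upward_crossing_fires_once(self):
        state, events = self._drive([-1.0, -0.5, 0.2])
        assert events == [0.0, 0.0, 1.0]
        assert state.globals["Tfront"] == 2.0      # latched at the event

    def test_monotone_decrease_never_fires(self):
        _, events = self._drive([3.0, 2.0, 1.0, 0.5, 0.1])
        assert events == [0.0] * 5

    def test_downward_sign(self):
        _, events = self._drive([1.0, 0.5, -0.2, -0.5], sign=-1)
        assert events == [0.0, 0.0, 1.0, 0.0]

    def test_one_event_per_period_on_sinusoid(self):
        # start at the minimum so each of the 3 periods has exactly one
        # upward zero crossing inside the window
        ts = np.arange(0, 3.0, 0.01)
        _, events = self._drive(np.sin(2 * np.pi * ts - np.pi / 2))
        assert sum(events) == 3.0


def test_feedback_force_window():
    ht, Amp = 0.02, 3.0
    base = dict(Tfront=10.0, Tstart=1.0, Del=6.0, Dur=0.1, Amp=Amp, ht=ht)
    assert feedback_force(T=0.5, **base) == 0.0            # before Tstart
    assert feedback_force(T=16.0, **base) == ht * Amp      # window start
    assert feedback_force(T=16.05, **base) == ht * Amp     # inside
    assert feedback_force(T=16.1 + 1e-9, **base) == 0.0    # just after
    assert feedback_force(T=12.0, **base) == 0.0           # before delay


# ---------------------------------------------------------------------
# Full feedback-stimulation protocol on a 1D cable
# ---------------------------------------------------------------------

def test_feedback_protocol_fires_del_after_front_arrival():
    """reduce -> k_poincare -> k_func(feedback) -> diff -> stimulus ->
    euler, assembled purely from devices: the stimulus must switch on
    exactly Del after the front reaches the registration electrode."""
    ht, Del, Dur, Amp = 0.02, 5.0, 0.5, 2.0
    state = StateGrid.from_box(80, 3, 1, vmax=3, h=0.5)
    state.globals.update({
        "ht": ht, "Del": Del, "Dur": Dur, "Amp": Amp,
        "Tstart": 0.1, "Tfront": -1000.0, "signal": -2.0, "front": 0.0,
    })
    kprint = KPrint(expressions=["T", "force", "signal"])
    ring = [
        _flags(f"T = t*{ht}; begin = eq(t,0); end = ge(T,40)"),
        KFunc(pgm="u0 = ifle0(x-6, 1.7, -1.04); u1 = ifle0(x-6, 0.7, -0.66)",
              when="begin", name="IC"),
        Reduce("max", v0=0, result="signal", x0=55, x1=59, y0=1, y1=1),
        KPoincare(pgm="front = signal; Tfront = T"),
        KFunc(pgm="force = ht*Amp*ge(T,Tstart)*ge(T,Tfront+Del)"
                  "*le(T,Tfront+Del+Dur)", nowhere=True, name="feedback"),
        Diff(v0=0, v1=2, D=1.0, hx=0.5),
        KFunc(pgm="u2 = u2 + force", when="force", name="stim"),
        EulerDevice(v0=0, v1=1, ht=ht, ode="fhncub",
                    par={"eps": 0.3, "bet": 0.71, "gam": 0.5, "Iu": "@2"}),
        kprint,
        Stop(when="end"),
    ]
    run_ring(ring, state)

    rows = np.array([[float(v) for v in line.split()] for line in kprint.lines])
    T, force = rows[:, 0], rows[:, 1]
    assert state.globals["Tfront"] > 0.0           # the front arrived
    on = np.nonzero(force > 0.0)[0]
    assert on.size > 0                             # the stimulus fired
    t_first = T[on[0]]
    assert abs(t_first - (state.globals["Tfront"] + Del)) <= ht + 1e-12
    # pulse duration matches Dur to one step
    assert abs(T[on[-1]] - T[on[0]] - Dur) <= ht + 1e-12


# ---------------------------------------------------------------------
# Phase singularities
# ---------------------------------------------------------------------

class TestSingz:
    def test_linear_fields_exact(self):
        X, Y = np.meshgrid(np.arange(10, dtype=float),
                           np.arange(10, dtype=float), indexing="ij")
        tips, stats = singz_find(X - 5.3, Y - 2.7, 0.0, 0.0)
        assert stats["n"] == 1
        np.testing.assert_allclose(tips[0], (5.3, 2.7), atol=1e-12)
        assert stats["x_std"] == 0.0

    def test_rotated_linear_system_root(self):
        # a = x + 2y - 9,  b = 3x - y - 5  =>  tip at the 2x2 solve
        X, Y = np.meshgrid(np.arange(12, dtype=float),
                           np.arange(12, dtype=float), indexing="ij")
        a = X + 2 * Y - 9.0
        b = 3 * X - Y - 5.0
        expect = np.linalg.solve([[1, 2], [3, -1]], [9.0, 5.0])
        tips, stats = singz_find(a, b, 0.0, 0.0)
        assert stats["n"] == 1
        np.testing.assert_allclose(tips[0], expect, atol=1e-12)

    def test_no_isoline_gives_empty_flagged_stats(self):
        ones = np.ones((6, 6))
        grad = np.arange(36, dtype=float).reshape(6, 6)
        tips, stats = singz_find(ones, grad, 0.0, 17.0)
        assert tips == [] and stats["n"] == 0
        assert np.isnan(stats["x_mean"])

    def test_device_publishes_stats(self):
        state = StateGrid.from_box(12, 12, 1, vmax=2)
        X, Y = np.meshgrid(np.arange(12, dtype=float),
                           np.arange(12, dtype=float), indexing="ij")
        state.values[..., 0] = (X - 5.5)[..., None]
        state.values[..., 1] = (Y - 6.25)[..., None]
        dev = SingZ(v0=0, v1=1, c0=0.0, c1=0.0, prefix="tip")
        dev.setup(state)
        dev.run(state)
        assert state.globals["tip_n"] == 1.0
        np.testing.assert_allclose(
            (state.globals["tip_x_mean"], state.globals["tip_y_mean"]),
            (5.5, 6.25), atol=1e-12,
        )


# ---------------------------------------------------------------------
# Output formats
# ---------------------------------------------------------------------

class TestPpm:
    def test_byte_discretization(self):
        lay = np.array([[[0.0]], [[1.0]], [[0.5]], [[2.0]], [[-1.0]]])
        data = ppm_bytes((lay, None, None), (((0.0, 1.0)), (0, 1), (0, 1)))
        header, payload = data.split(b"\n255\n", 1)
        assert header == b"P6\n5 1"
        reds = payload[0::3]
        assert list(reds) == [0, 255, 128, 255, 0]   # clamp + round-half-up

    def test_3d_stacked_slices_dimensions(self):
        lay = np.zeros((3, 2, 2))
        data = ppm_bytes((lay, lay, lay), ((0, 1), (0, 1), (0, 1)))
        header, payload = data.split(b"\n255\n", 1)
        assert header == b"P6\n3 4"                  # ny*nz = 4 rows
        assert len(payload) == 3 * 4 * 3             # rgb bytes

    def test_degenerate_range_rejected(self):
        lay = np.zeros((2, 2, 1))
        with pytest.raises(EngineError, match="degenerate"):
            ppm_bytes((lay, None, None), ((1.0, 1.0), (0, 1), (0, 1)))

    def test_device_writes_numbered_files(self, tmp_path):
        state = StateGrid.from_box(4, 4, 1, vmax=1)
        dev = PpmOut(file=str(tmp_path / "%04d.ppm"), r=0, r0=0.0, r1=1.0)
        dev.setup(state)
        dev.run(state)
        dev.run(state)
        assert (tmp_path / "0000.ppm").exists()
        assert (tmp_path / "0001.ppm").exists()


def test_kprint_three_columns():
    state = StateGrid.from_box(4, 4, 1, vmax=1)
    state.globals.update({"T": 1.5, "force": 0.06, "signal": -2.0})
    dev = KPrint(expressions=["T", "force", "signal"])
    dev.setup(state)
    dev.run(state)
    cols = dev.lines[0].split()
    assert len(cols) == 3
    assert float(cols[0]) == 1.5
    assert cols[0].startswith("+")                   # %+.7e format


def test_record_fixed_width_format(tmp_path):
    state = StateGrid.from_box(5, 5, 1, vmax=2)
    state.values[2, 3, 0, 0] = 1.25
    state.values[2, 3, 0, 1] = -0.5
    f = tmp_path / "rec.dat"
    dev = Record(x0=2, x1=2, y0=3, y1=3, v0=0, v1=1, file=str(f))
    dev.setup(state)
    dev.run(state)
    line = f.read_text().strip()
    assert line == "+1.2500000e+00 -5.0000000e-01"


class TestDumpLoad:
    def test_bit_exact_roundtrip(self, tmp_path, rng):
        state = StateGrid.from_box(5, 6, 1, vmax=3)
        state.values[:] = rng.normal(size=state.values.shape)
        original = state.values.copy()
        f = str(tmp_path / "state.dump")
        dump = Dump(file=f)
        dump.setup(state)
        dump.run(state)
        state.values[:] = 0.0
        load = Load(file=f)
        load.setup(state)
        load.run(state)
        np.testing.assert_array_equal(state.values, original)

    def test_layer_order_in_file(self, tmp_path):
        state = StateGrid.from_box(3, 3, 1, vmax=2)
        state.values[..., 0] = 1.0
        state.values[..., 1] = 2.0
        f = tmp_path / "s.dump"
        dump = Dump(file=str(f))
        dump.setup(state)
        dump.run(state)
        raw = np.frombuffer(f.read_bytes(), dtype="<f8")
        assert raw.size == 18
        np.testing.assert_array_equal(raw[:9], 1.0)   # layer-slowest
        np.testing.assert_array_equal(raw[9:], 2.0)

    def test_size_mismatch_rejected(self, tmp_path):
        state = StateGrid.from_box(4, 4, 1, vmax=1)
        f = tmp_path / "bad.dump"
        f.write_bytes(b"\x00" * 8)
        load = Load(file=str(f))
        load.setup(state)
        with pytest.raises(EngineError, match="values"):
            load.run(state)


class TestPhaseDistribution:
    def test_constant_phase_zero_gives_row_zero(self):
        table = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]])
        out = phase_distribution_ic(table, np.zeros((4, 4)))
        np.testing.assert_array_equal(out, np.broadcast_to([1.0, 10.0], (4, 4, 2)))

    def test_exact_row_phases(self):
        table = np.array([[1.0], [2.0], [3.0], [4.0]])
        for k in range(4):
            out = phase_distribution_ic(table, np.array([k / 4]))
            np.testing.assert_allclose(out[0], table[k])

    def test_half_row_phase_interpolates(self):
        table = np.array([[1.0], [2.0], [3.0], [4.0]])
        out = phase_distribution_ic(table, np.array([0.5 / 4]))
        np.testing.assert_allclose(out[0], [1.5])

    def test_periodic_wrap(self):
        table = np.array([[0.0], [1.0]])
        out = phase_distribution_ic(table, np.array([0.75]))
        np.testing.assert_allclose(out[0], [0.5])    # halfway row1 -> row0

    def test_nonfinite_phase_rejected(self):
        with pytest.raises(EngineError, match="non-finite"):
            phase_distribution_ic(np.ones((2, 1)), np.array([np.nan]))


# ---------------------------------------------------------------------
# Declarative configs
# ---------------------------------------------------------------------

class TestConfig:
    CFG = {
        "macros": {"u": 0, "v": 1, "i": 2},
        "state": {"xmax": 12, "ymax": 12, "vmax": 3, "hx": 0.4},
        "globals": {"ht": 0.02},
        "devices": [
            {"device": "k_func", "nowhere": True,
             "pgm": "begin = eq(t,0); end = ge(t,20)"},
            {"device": "k_func", "when": "begin",
             "pgm": "u[u] = gt(y,6); u[v] = 0.4*lt(x,6)"},
            {"device": "diffstep", "v0": "[u]", "v1": "[i]", "ht": 0.02,
             "hx": 0.4, "D": 1.0},
            {"device": "euler", "v0": 0, "v1": 1, "ht": 0.02,
             "ode": "fhnbkl", "par": {"a": 0.8, "b": 0.01, "eps": 0.02}},
            {"device": "stop", "when": "end"},
        ],
    }

    def test_build_and_run(self):
        state, ring = build_simulation(self.CFG)
        run_ring(ring, state)
        assert state.t == 20
        assert np.isfinite(state.values).all()

    def test_macro_substitution(self):
        state, ring = build_simulation(self.CFG)
        assert ring.devices[2].v0 == 0 and ring.devices[2].v1 == 2

    def test_parameter_overrides_set_globals(self):
        state, _ = build_simulation(self.CFG, overrides={"grad": 0.25})
        assert state.globals["grad"] == 0.25

    def test_unknown_device_rejected(self):
        bad = dict(self.CFG, devices=[{"device": "nosuch"}])
        with pytest.raises(EngineError, match="unknown device"):
            build_simulation(bad)

    def test_yaml_roundtrip(self, tmp_path):
        import yaml

        from cardiogrid.config import load_config

        p = tmp_path / "sim.yaml"
        p.write_text(yaml.safe_dump(self.CFG))
        state, ring = build_simulation(load_config(p))
        run_ring(ring, state)
        assert state.t == 20
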