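"""Explicit and exponential time stepping."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiogrid.cell_models import (
    RHSModel,
    hodgkin_huxley_ionic,
    toy_markov_channel,
)
from cardiogrid.ode_solvers import (
    NumericError,
    euler_step,
    ionic_step,
    matrix_rush_larsen_step,
    rk4_step,
    rl_step_matrix,
    rush_larsen_gate_step,
    tabulate,
    tabulate_ionic,
)


def _decay_model():
    return RHSModel("decay", 1, {}, lambda s, p: -s)


def _zero_model():
    return RHSModel("zero", 1, {}, lambda s, p: np.zeros_like(s))


# ---------------------------------------------------------------------
# Explicit schemes
# ---------------------------------------------------------------------

class TestExplicit:
    def test_euler_single_and_double_step(self):
        m = _decay_model()
        y = euler_step(np.array([1.0]), m, k=0.1)
        np.testing.assert_allclose(y, [0.9])
        np.testing.assert_allclose(euler_step(y, m, k=0.1), [0.81])

    def test_zero_rhs_is_identity(self):
        y0 = np.array([1.7, -0.3])
        m = RHSModel("zero2", 2, {}, lambda s, p: np.zeros_like(s))
        np.testing.assert_array_equal(euler_step(y0, m, k=0.5), y0)
        np.testing.assert_array_equal(rk4_step(y0, m, k=0.5), y0)

    def test_rk4_decay_matches_degree4_taylor(self):
        # one RK4 step of dy/dt = -y equals the degree-4 Taylor
        # polynomial of exp(-k): 1 - .1 + .005 - 1/6e-3*... = 0.9048375
        y = rk4_step(np.array([1.0]), _decay_model(), k=0.1)
        np.testing.assert_allclose(y, [0.9048375], rtol=1e-12)

    def test_rk4_linear_system_matches_truncated_matrix_exponential(self, rng):
        A = rng.normal(size=(3, 3))
        m = RHSModel("lin", 3, {}, lambda s, p: s @ A.T)
        y0 = rng.normal(size=3)
        k = 0.05
        import math
        truncated = sum(
            np.linalg.matrix_power(k * A, j) / math.factorial(j)
            for j in range(5)
        )
        np.testing.assert_allclose(rk4_step(y0, m, k=k), truncated @ y0,
                                   rtol=1e-12)

    def test_direct_step_models_delegate(self):
        def stepper(state, params, k):
            return state * np.exp(-k)      # exact integrator as direct step

        m = RHSModel("direct", 1, {}, lambda s, p: -s, direct_step=stepper)
        np.testing.assert_allclose(
            euler_step(np.array([2.0]), m, k=0.3), [2.0 * np.exp(-0.3)]
        )

    def test_nonfinite_derivative_names_variable(self):
        m = RHSModel("bad", 2, {}, lambda s, p: np.array([0.0, np.inf]))
        with pytest.raises(NumericError, match="variable index"):
            euler_step(np.zeros(2), m, k=0.1)

    @pytest.mark.parametrize("stepper,expected_order,tol", [
        (euler_step, 1.0, 0.1), (rk4_step, 4.0, 0.2),
    ])
    def test_measured_convergence_order(self, stepper, expected_order, tol):
        # integrate dy/dt = -y to t=1 at halved steps; log-log slope of
        # the end-point error against k estimates the global order
        m = _decay_model()
        ks, errs = [], []
        for n in (8, 16, 32, 64):
            k = 1.0 / n
            y = np.array([1.0])
            for _ in range(n):
                y = stepper(y, m, k=k)
            ks.append(k)
            errs.append(abs(float(y[0]) - np.exp(-1.0)))
        slope = np.polyfit(np.log(ks), np.log(errs), 1)[0]
        assert abs(slope - expected_order) < tol


# ---------------------------------------------------------------------
# Rush-Larsen gate step
# ---------------------------------------------------------------------

class TestGateStep:
    def test_closed_form_value(self):
        # alpha = beta = 1, y = 0, k = ln 2:
        # y' = 1/2 (1 - e^{-2 ln 2}) = 0.375
        np.testing.assert_allclose(
            rush_larsen_gate_step(0.0, 1.0, 1.0, np.log(2.0)), 0.375, rtol=1e-14
        )

    def test_large_step_reaches_equilibrium(self):
        y = rush_larsen_gate_step(0.1, 3.0, 1.0, 1e6)
        np.testing.assert_allclose(y, 0.75, atol=1e-12)

    def test_zero_rates_leave_gate_unchanged(self):
        assert rush_larsen_gate_step(0.42, 0.0, 0.0, 1.0) == 0.42

    @settings(max_examples=100, deadline=None)
    @given(
        y=st.floats(0, 1), alpha=st.floats(1e-6, 50), beta=st.floats(1e-6, 50),
        k=st.floats(1e-6, 1e3),
    )
    def test_unconditional_stability_and_range(self, y, alpha, beta, k):
        yinf = alpha / (alpha + beta)
        y1 = float(rush_larsen_gate_step(y, alpha, beta, k))
        assert 0.0 <= y1 <= 1.0
        assert abs(y1 - yinf) <= abs(y - yinf) + 1e-15


# ---------------------------------------------------------------------
# Matrix Rush-Larsen
# ---------------------------------------------------------------------

def _random_generator_matrix(rng, n):
    """Random Markov rate matrix: non-negative off-diagonals, zero
    column sums."""
    M = rng.uniform(0.1, 2.0, size=(n, n))
    np.fill_diagonal(M, 0.0)
    M -= np.diag(M.sum(axis=0))
    return M


class TestMatrixRL:
    def test_zero_matrix_is_identity(self):
        u = np.array([0.3, 0.7])
        np.testing.assert_array_equal(
            matrix_rush_larsen_step(u, np.zeros((2, 2)), 1.0), u
        )

    def test_two_state_closed_form(self):
        M = np.array([[-1.0, 1.0], [1.0, -1.0]])
        u = matrix_rush_larsen_step(np.array([1.0, 0.0]), M, 0.5)
        expect = [0.5 * (1 + np.exp(-1.0)), 0.5 * (1 - np.exp(-1.0))]
        np.testing.assert_allclose(u, expect, rtol=1e-12)
        np.testing.assert_allclose(u, [0.683940, 0.316060], atol=5e-7)

    def test_long_time_stationary(self):
        M = np.array([[-1.0, 1.0], [1.0, -1.0]])
        u = matrix_rush_larsen_step(np.array([1.0, 0.0]), M, 1e3)
        np.testing.assert_allclose(u, [0.5, 0.5], atol=1e-12)

    def test_matches_dense_exponential_on_random_chains(self, rng):
        for n in (2, 3, 4, 5, 6):
            for _ in range(5):
                M = _random_generator_matrix(rng, n)
                u = rng.dirichlet(np.ones(n))
                k = float(rng.uniform(0.01, 2.0))
                oracle = scipy.linalg.expm(k * M) @ u
                got = matrix_rush_larsen_step(u, M, k)
                np.testing.assert_allclose(got, oracle, atol=1e-10)
                # zero column sums -> total probability conserved
                np.testing.assert_allclose(got.sum(), u.sum(), atol=1e-12)

    def test_defective_matrix_falls_back_with_warning(self):
        M = np.array([[0.0, 1.0], [0.0, 0.0]])     # Jordan block, defective
        with pytest.warns(UserWarning, match="falling back"):
            T = rl_step_matrix(M, 1.0)
        np.testing.assert_allclose(T, scipy.linalg.expm(M), rtol=1e-12)


# ---------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------

class TestTabulation:
    def test_grid_node_values_exact(self):
        tab = tabulate(lambda v: np.array([v * v]), -2.0, 2.0, 41)
        for v in np.linspace(-2, 2, 41):
            np.testing.assert_array_equal(tab.lookup(v), [v * v])

    def test_midpoint_tie_goes_to_lower_index(self):
        tab = tabulate(lambda v: np.array([v]), 0.0, 1.0, 2)
        np.testing.assert_array_equal(tab.lookup(0.5), [0.0])

    def test_out_of_range_clamps_and_counts(self):
        tab = tabulate(lambda v: np.array([v]), 0.0, 1.0, 11)
        np.testing.assert_array_equal(tab.lookup(2.5), [1.0])
        np.testing.assert_array_equal(tab.lookup(-1.0), [0.0])
        assert tab.n_clamped == 2

    def test_tabulated_hh_tracks_direct_evaluation(self):
        # over a full action potential the tabulated run stays close to
        # the directly evaluated one, and refining the table shrinks the
        # deviation (nearest-node lookup error is O(1/n))
        spec = hodgkin_huxley_ionic()
        k = 0.01

        def run(tabs):
            y = spec.initial_state.copy()
            traj, vmax = [], -100.0
            for i in range(2000):                  # 20 ms, one AP
                par = {"Iu": 10.0 if i < 100 else 0.0}
                y = ionic_step(y, spec, k, tabs, par)
                traj.append(float(y[0]))
                vmax = max(vmax, float(y[0]))
            return np.array(traj), vmax

        direct, vmax = run(None)
        assert vmax > 0.0                          # the AP actually fired
        coarse, _ = run(tabulate_ionic(spec, k, n=25_000))
        fine, _ = run(tabulate_ionic(spec, k, n=100_000))
        err_coarse = np.max(np.abs(coarse - direct))
        err_fine = np.max(np.abs(fine - direct))
        assert err_fine < 1e-2
        assert err_fine < err_coarse


# ---------------------------------------------------------------------
# Full ionic step
# ---------------------------------------------------------------------

class TestIonicStep:
    def test_single_part_equals_matrix_rl(self, rng):
        M = _random_generator_matrix(rng, 3)
        spec = toy_markov_channel(3, rate_spec={"M0": M, "M1": np.zeros((3, 3))})
        u0 = np.zeros(4)
        u0[1:] = rng.dirichlet(np.ones(3))
        k = 0.3
        out = ionic_step(u0, spec, k)
        np.testing.assert_allclose(
            out[1:], matrix_rush_larsen_step(u0[1:], M, k), atol=1e-12
        )

    def test_commuting_parts_split_exactly(self, rng):
        # M1 = 2 M0 commutes with M0; Lie splitting is then exact and
        # must match the whole-matrix exponential oracle
        M0 = _random_generator_matrix(rng, 4)
        spec = toy_markov_channel(4, rate_spec={
            "M0": M0, "M1": 2.0 * M0, "sigma": lambda v: 1.0,
        })
        u0 = np.zeros(5)
        u0[1:] = rng.dirichlet(np.ones(4))
        k = 0.2
        out = ionic_step(u0, spec, k)
        oracle = scipy.linalg.expm(k * 3.0 * M0) @ u0[1:]
        np.testing.assert_allclose(out[1:], oracle, atol=1e-10)

    def test_hh_gates_exact_at_clamped_voltage(self):
        spec = hodgkin_huxley_ionic()
        V = -40.0
        y = np.array([V, 0.2, 0.4, 0.6])
        k = 0.7

        def clamp_rhs(state, params):
            return np.zeros_like(np.asarray(state[..., 0]))[..., None]

        spec.other_rhs = clamp_rhs
        out = ionic_step(y, spec, k)
        for g in spec.gates:
            a, b = float(g.alpha(V)), float(g.beta(V))
            yinf = a / (a + b)
            exact = yinf + (y[g.index] - yinf) * np.exp(-(a + b) * k)
            np.testing.assert_allclose(out[g.index], exact, rtol=1e-13)

    def test_remainder_advanced_by_forward_euler(self, rng):
        M0 = _random_generator_matrix(rng, 2)
        R = _random_generator_matrix(rng, 2) * 0.01
        spec = toy_markov_channel(2, rate_spec={"M0": M0, "M1": np.zeros((2, 2))})
        spec.markov_chains[0].remainder = lambda state: R
        u0 = np.array([0.0, 0.7, 0.3])
        k = 0.1
        out = ionic_step(u0, spec, k)
        expect = matrix_rush_larsen_step(u0[1:], M0, k)
        expect = expect + k * R @ expect
        np.testing.assert_allclose(out[1:], expect, atol=1e-12)
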