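"""Cost function, costate backpropagation, and analytic gradients."""

import numpy as np
import pytest

import surbop as sb
from surbop.cost import _ensemble
from surbop.quaternions import quat_mul

DT = 0.5e-6
U_90 = sb.target_rotation(90)
U_180 = sb.target_rotation(180)


def fd_gradient(pulse, band, u_f, weights, delta=1e-3):
    """Central finite differences of the total cost (the gradient oracle)."""
    gx = np.empty(pulse.n_steps)
    gy = np.empty(pulse.n_steps)
    for k in range(pulse.n_steps):
        e = np.zeros(pulse.n_steps)
        e[k] = delta
        up = sb.total_cost(pulse.with_controls(pulse.u_x + e, pulse.u_y), band, u_f, weights)
        dn = sb.total_cost(pulse.with_controls(pulse.u_x - e, pulse.u_y), band, u_f, weights)
        gx[k] = (up - dn) / (2 * delta)
        up = sb.total_cost(pulse.with_controls(pulse.u_x, pulse.u_y + e), band, u_f, weights)
        dn = sb.total_cost(pulse.with_controls(pulse.u_x, pulse.u_y - e), band, u_f, weights)
        gy[k] = (up - dn) / (2 * delta)
    return gx, gy


class TestIsochromatCosts:
    @pytest.mark.parametrize(
        "x,u_f,expected",
        [
            (U_180, U_180, 0.0),
            (-U_180, U_180, 4.0),  # the opposite cover carries the full penalty
            ((0, 0, 0, 1), U_180, 2.0),
        ],
    )
    def test_passband_values(self, x, u_f, expected):
        assert sb.passband_cost(np.asarray(x, float), u_f) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "x,expected",
        [
            ((0, 0, np.sin(0.4), np.cos(0.4)), 0.0),  # z-rotations are free
            (U_180, 1.0),
            (U_90, 0.5),
        ],
    )
    def test_stopband_values(self, x, expected):
        assert sb.stopband_cost(np.asarray(x, float)) == pytest.approx(expected)

    def test_cost_is_nonnegative(self, band, limits):
        for seed in range(5):
            p = sb.random_start(10, DT, limits, seed=seed)
            assert sb.total_cost(p, band, U_90, sb.CostWeights()) >= 0.0


class TestFreeEvolutionClosedForm:
    @pytest.mark.parametrize("u_f,angle", [(U_90, 90), (U_180, 180)])
    def test_zero_pulse_cost_matches_closed_form(self, band, u_f, angle):
        """Without rf the propagator is a known z-rotation at every offset, so
        the passband cost has the closed form 2 - 2*cos(a/2)*cos(pi*nu*T)."""
        n = 40
        p = sb.ShapedPulse(np.zeros(n), np.zeros(n), DT)
        w = sb.CostWeights(w_sel=1.0, w_0=0.0)
        got = sb.total_cost(p, band, u_f, w)
        t = n * DT
        d_f = np.cos(np.deg2rad(angle) / 2)
        per_iso = 2.0 - 2.0 * d_f * np.cos(np.pi * band.passband_offsets * t)
        want = per_iso.mean() / 2.0  # the implemented 1/(2n) ensemble averaging
        assert got == pytest.approx(want, rel=1e-12)


class TestCostates:
    def test_passband_at_target_vanishes(self):
        np.testing.assert_array_equal(
            sb.terminal_costate(U_90, U_90, sb.CostWeights(), "passband"), np.zeros(4)
        )

    def test_stopband_pure_z_vanishes(self):
        x = np.array([0.0, 0.0, np.sin(0.3), np.cos(0.3)])
        np.testing.assert_array_equal(
            sb.terminal_costate(x, U_90, sb.CostWeights(), "stopband"), np.zeros(4)
        )

    def test_identity_vs_half_turn_costate(self):
        p = sb.terminal_costate(
            np.array([0.0, 0.0, 0.0, 1.0]), U_180, sb.CostWeights(w_sel=1.0), "passband"
        )
        np.testing.assert_allclose(p, [-2.0, 0.0, 0.0, 2.0])

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError):
            sb.terminal_costate(U_90, U_90, sb.CostWeights(), "transition")


class TestBackpropagation:
    def test_identity_steps_leave_costate_unchanged(self):
        steps = np.tile(np.array([0.0, 0.0, 0.0, 1.0]), (6, 1, 1))
        p_n = np.array([[0.5, -0.25, 1.0, 2.0]])
        P = sb.backpropagate(p_n, steps)
        np.testing.assert_array_equal(P, np.tile(p_n, (6, 1, 1)))

    def test_single_step_transport(self):
        rng = np.random.default_rng(0)
        q = rng.normal(size=(2, 1, 4))
        q /= np.linalg.norm(q, axis=-1, keepdims=True)
        p_n = rng.normal(size=(1, 4))
        P = sb.backpropagate(p_n, q)
        # row-vector transport P_{N-1} = P_N R_N equals the matrix product
        want = sb.composition_matrix(q[1, 0]).T @ p_n[0]
        np.testing.assert_allclose(P[0, 0], want, atol=1e-14)
        np.testing.assert_array_equal(P[1], p_n)

    def test_pairing_with_forward_transport_is_invariant(self, limits):
        """<P_k|X_k> is constant over k when the costate starts at X_N."""
        p = sb.random_start(30, DT, limits, seed=4)
        X = sb.propagate(p, 9_000.0)
        q = sb.step_quaternion(p.u_x, p.u_y, np.full(30, 9_000.0), DT)
        P = sb.backpropagate(X[-1][None, :], q[:, None, :])
        pairings = np.einsum("kc,kc->k", P[:, 0, :], X)
        np.testing.assert_allclose(pairings, 1.0, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sb.backpropagate(np.zeros((2, 4)), np.zeros((3, 1, 4)))


class TestGradient:
    def test_matches_finite_differences(self, band, limits):
        w = sb.CostWeights(w_sel=1.3, w_0=0.7)
        for seed, n in [(0, 8), (1, 14)]:
            p = sb.random_start(n, DT, limits, seed=seed)
            g = sb.assemble_gradient(p, band, U_90, w)
            gx, gy = fd_gradient(p, band, U_90, w)
            scale = max(np.abs(gx).max(), np.abs(gy).max())
            assert np.abs(g.g_x - gx).max() / scale < 1e-4
            assert np.abs(g.g_y - gy).max() / scale < 1e-4

    def test_first_order_scheme_approximates_exact(self, band, limits):
        p = sb.random_start(12, DT, limits, seed=2)
        w = sb.CostWeights()
        g_exact = sb.assemble_gradient(p, band, U_90, w, scheme="exact")
        g_first = sb.assemble_gradient(p, band, U_90, w, scheme="first_order")
        scale = max(np.abs(g_exact.g_x).max(), np.abs(g_exact.g_y).max())
        # small-rotation generators: agreement to a few percent per step
        assert np.abs(g_first.g_x - g_exact.g_x).max() / scale < 0.05
        assert np.abs(g_first.g_y - g_exact.g_y).max() / scale < 0.05

    def test_linear_in_weights(self, band, limits):
        p = sb.random_start(10, DT, limits, seed=3)
        g1 = sb.assemble_gradient(p, band, U_180, sb.CostWeights(w_sel=1.0, w_0=0.0))
        g2 = sb.assemble_gradient(p, band, U_180, sb.CostWeights(w_sel=2.0, w_0=0.0))
        np.testing.assert_allclose(g2.g_x, 2 * g1.g_x, rtol=1e-12, atol=1e-18)
        np.testing.assert_allclose(g2.g_y, 2 * g1.g_y, rtol=1e-12, atol=1e-18)

    def test_vanishes_at_an_exact_minimum(self, band):
        """A zero-amplitude pulse has exactly zero stopband cost, so the
        stopband-only gradient must vanish identically."""
        p = sb.ShapedPulse(np.zeros(12), np.zeros(12), DT)
        w = sb.CostWeights(w_sel=0.0, w_0=1.0)
        assert sb.total_cost(p, band, U_90, w) == 0.0
        g = sb.assemble_gradient(p, band, U_90, w)
        assert np.abs(g.g_x).max() < 1e-10
        assert np.abs(g.g_y).max() < 1e-10


class TestStopbandSymmetry:
    def test_time_and_phase_reversal_preserve_stopband_cost(self, band, limits):
        """Symmetric stopbands make the cost invariant under time reversal and
        phase (y-control) reversal of the shape."""
        p = sb.random_start(24, DT, limits, seed=5)
        w = sb.CostWeights(w_sel=0.0, w_0=1.0)
        ref = sb.total_cost(p, band, U_180, w)
        variants = [
            p.with_controls(p.u_x, -p.u_y),
            p.with_controls(p.u_x[::-1].copy(), p.u_y[::-1].copy()),
            p.with_controls(p.u_x[::-1].copy(), -p.u_y[::-1].copy()),
        ]
        for v in variants:
            assert sb.total_cost(v, band, U_180, w) == pytest.approx(ref, abs=1e-15)


def test_ensemble_weights_sum_to_one(band):
    """Passband and stopband members each average to 1/2 of the total."""
    _, _, is_pass, avg_w = _ensemble(band)
    assert avg_w[is_pass].sum() == pytest.approx(0.5)
    assert avg_w[~is_pass].sum() == pytest.approx(0.5)
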