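"""Ansatz construction, root finding, Jacobians and stability verdicts."""

import numpy as np
import pytest

from tipstalk.core_model import (
    INFINITE,
    LatticeState,
    ModelParams,
    pack_full,
    rhs_full_vec,
)
from tipstalk.errors import IncompatibleLatticeError, UnsupportedVariantError
from tipstalk.steady_state import (
    assess_stability,
    build_ansatz,
    check_interface_balance,
    jacobian,
    solve_pattern,
    uniform_state,
)


def het_params(**kw):
    defaults = dict(b0=0.8, K=0.01, kd=1.0, kf0=0.3, h=0.0, W=0.0, n_cells=12)
    defaults.update(kw)
    return ModelParams(**defaults)


class TestBuildAnsatz:
    def test_spacing_zero_single_position(self):
        a = build_ansatz(0, het_params())
        assert a.period == 1
        assert a.tiling == (0,) * 12

    def test_spacing_two_tiles(self):
        a = build_ansatz(2, het_params())
        assert a.period == 3
        assert len(set(a.tiling)) == 3
        assert len(a.y0) == 9  # 3 fields x period for finite W

    def test_single_pool_unknown_count(self):
        a = build_ansatz(2, het_params(W=INFINITE))
        assert len(a.y0) == 6  # 2 fields x period

    def test_incompatible_period_rejected(self):
        with pytest.raises(IncompatibleLatticeError):
            build_ansatz(4, het_params())  # period 5 does not divide 12


class TestUniformState:
    def test_classical_value_matches_fixed_point_oracle(self):
        p = ModelParams(b0=0.5, K=1.0, kd=1.0, kf0=0.1, W=INFINITE, n_cells=12)
        u = uniform_state(p)
        assert u.D[0] == pytest.approx(0.496, abs=5e-4)
        assert np.ptp(u.D) == 0

    def test_large_K_limit_removes_inhibition(self):
        p = het_params(K=1e6)
        u = uniform_state(p)
        assert u.D[0] == pytest.approx(p.b0, rel=1e-4)

    def test_uniform_is_a_root_of_the_dynamics(self):
        p = het_params(W=2.0)
        u = uniform_state(p)
        d = rhs_full_vec(u.D, u.N_left, u.N_right, p)
        assert np.max(np.abs(np.concatenate(d))) < 1e-10


class TestSolvePattern:
    def test_spacing_zero_equals_uniform_state(self):
        for p in (het_params(), het_params(W=INFINITE),
                  het_params(h=0.076, lam=10.0, kf0=40.0, K=0.1, kd=0.4, b0=0.9)):
            r = solve_pattern(p, 0)
            u = uniform_state(p)
            np.testing.assert_allclose(r.state.D, u.D, atol=1e-8)

    def test_returned_residual_is_on_full_lattice(self):
        r = solve_pattern(het_params(), 2)
        assert r is not None
        assert r.residual_norm <= 1e-10
        assert r.state.n_cells == 12

    def test_known_stable_salt_and_pepper(self):
        r = solve_pattern(het_params(kf0=0.1), 1)
        assert r.stable == "stable"
        assert r.spacing_observed == 1

    def test_not_found_is_none_not_exception(self):
        # spacing-3 pattern has no genuine root in the classical model
        p = ModelParams(b0=0.5, K=1.0, kd=1.0, kf0=0.1, W=INFINITE, n_cells=12)
        r = solve_pattern(p, 3)
        assert r is None or r.collapsed

    def test_stability_invariant_under_lattice_rotation(self):
        r = solve_pattern(het_params(), 2)
        rolled = LatticeState(np.roll(r.state.D, 4), np.roll(r.state.N_left, 4),
                              np.roll(r.state.N_right, 4))
        eig_r = np.linalg.eigvals(jacobian(rolled, r.params))
        assert assess_stability(eig_r) == r.stable
        assert np.max(eig_r.real) == pytest.approx(r.max_real_eigenvalue, abs=1e-7)


class TestJacobian:
    @staticmethod
    def _oracle(fun, y, h=1e-4):
        """Independent Richardson-extrapolated central differences."""
        m = fun(y).size
        J = np.empty((m, y.size))
        for i in range(y.size):
            e = np.zeros_like(y)
            e[i] = 1.0
            d1 = (fun(y + h * e) - fun(y - h * e)) / (2 * h)
            d2 = (fun(y + h / 2 * e) - fun(y - h / 2 * e)) / h
            J[:, i] = (4 * d2 - d1) / 3
        return J

    @pytest.mark.parametrize("variant_kw", [
        dict(W=0.0, h=0.0),
        dict(W=3.0, h=0.0),
        dict(W=0.0, h=0.076, lam=10.0, kf0=4.0),
    ])
    def test_matches_independent_differencing_oracle(self, variant_kw, rng):
        p = het_params(n_cells=6, **variant_kw)
        st = LatticeState(rng.uniform(0.1, 0.7, 6), rng.uniform(0.05, 0.8, 6),
                          rng.uniform(0.05, 0.8, 6))
        J = jacobian(st, p)

        def fun(y):
            D, N_l, N_r = y[:6], y[6:12], y[12:]
            return np.concatenate(rhs_full_vec(D, N_l, N_r, p))

        J_oracle = self._oracle(fun, pack_full(st))
        np.testing.assert_allclose(J, J_oracle, atol=1e-5)

    def test_no_direct_delta_delta_coupling_at_h_zero(self):
        p = het_params(n_cells=6)
        u = uniform_state(p)
        J = jacobian(u, p)
        dD_block = J[:6, :6]
        np.testing.assert_allclose(dD_block, -np.eye(6), atol=1e-9)


class TestAssessStability:
    def test_all_negative_is_stable(self):
        assert assess_stability(np.array([-1.0, -0.5])) == "stable"

    def test_positive_real_part_is_unstable(self):
        assert assess_stability(np.array([-1.0, 0.5])) == "unstable"

    def test_marginal_band(self):
        assert assess_stability(np.array([-1.0, 1e-12])) == "marginal"


class TestInterfaceBalance:
    def test_symmetric_uniform_state_balances_exactly(self):
        p = ModelParams(b0=0.9, K=0.1, kd=0.0225, kf0=3.719, h=0.0052,
                        lam=30.0, W=INFINITE, n_cells=12)
        r = solve_pattern(p, 0)
        assert check_interface_balance(r, p) <= 1e-12

    def test_wrong_variant_rejected(self):
        p = het_params()
        r = solve_pattern(p, 1)
        with pytest.raises(UnsupportedVariantError):
            check_interface_balance(r, p)
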