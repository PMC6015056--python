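"""Time integration, relaxation and perturbation."""

import numpy as np
import pytest

from tipstalk.core_model import LatticeState, ModelParams
from tipstalk.dynamics import integrate, perturb, relax_to_steady
from tipstalk.errors import InvalidStateError
from tipstalk.steady_state import solve_pattern, uniform_state


def het_params(**kw):
    defaults = dict(b0=0.8, K=0.01, kd=1.0, kf0=0.1, h=0.0, W=0.0, n_cells=12)
    defaults.update(kw)
    return ModelParams(**defaults)


class TestPerturb:
    def test_zero_magnitude_is_identity(self):
        st = uniform_state(het_params())
        out = perturb(st, 0.0, seed=3)
        np.testing.assert_array_equal(out.D, st.D)

    def test_deterministic_given_seed(self):
        st = uniform_state(het_params())
        a, b = perturb(st, 0.05, seed=7), perturb(st, 0.05, seed=7)
        np.testing.assert_array_equal(a.D, b.D)
        np.testing.assert_array_equal(a.N_left, b.N_left)

    def test_relative_bound_respected(self):
        st = uniform_state(het_params())
        out = perturb(st, 0.01, seed=1)
        rel = np.abs(out.D - st.D) / st.D
        assert np.max(rel) <= 0.01 + 1e-12

    def test_result_is_admissible(self):
        st = LatticeState(np.full(12, 0.5), np.full(12, 0.999), np.full(12, 0.001))
        out = perturb(st, 0.5, seed=0)
        out.validate()


class TestIntegrate:
    def test_steady_root_is_invariant(self):
        r = solve_pattern(het_params(), 1)
        traj = integrate(r.params, r.state, t_end=50.0)
        np.testing.assert_allclose(traj.final_state.D, r.state.D, atol=1e-8)

    def test_snapshots_start_at_zero_and_increase(self):
        p = het_params()
        traj = integrate(p, uniform_state(p), t_end=10.0, n_snapshots=20)
        assert traj.times[0] == 0.0
        assert np.all(np.diff(traj.times) > 0)

    def test_invalid_initial_state_rejected(self):
        p = het_params()
        bad = LatticeState(np.full(12, 0.1), np.full(12, 1.5), np.full(12, 0.1))
        with pytest.raises(InvalidStateError):
            integrate(p, bad, t_end=1.0)

    def test_perturbed_uniform_relaxes_to_salt_and_pepper(self):
        # at strong nonlinearity the uniform state is unstable and a 1%
        # kick is enough to reach the alternating pattern
        from tipstalk.patterns import classify_spacing

        p = het_params()
        init = perturb(uniform_state(p), 0.01, seed=2)
        state, ok = relax_to_steady(p, init)
        assert ok
        assert classify_spacing(state).spacing == 1

    def test_forward_invariance_of_bounds(self, rng):
        p = het_params(W=1.0, h=0.076, lam=10.0, kf0=4.0, n_cells=6)
        init = LatticeState(rng.uniform(0, p.b0, 6), rng.uniform(0, 1, 6),
                            rng.uniform(0, 1, 6))
        traj = integrate(p, init, t_end=200.0, n_snapshots=50)
        for st in traj.states:
            assert np.all(st.N_left >= -1e-7) and np.all(st.N_left <= 1 + 1e-7)
            assert np.all(st.N_right >= -1e-7) and np.all(st.N_right <= 1 + 1e-7)
            assert np.all(st.D >= -1e-7) and np.all(st.D <= p.b0 + 1e-7)

    def test_rotation_symmetry_preserved(self, rng):
        p = het_params(n_cells=6)
        init = LatticeState(rng.uniform(0.01, 0.7, 6), rng.uniform(0, 1, 6),
                            rng.uniform(0, 1, 6))
        rolled = LatticeState(np.roll(init.D, 2), np.roll(init.N_left, 2),
                              np.roll(init.N_right, 2))
        t1 = integrate(p, init, t_end=20.0, n_snapshots=5)
        t2 = integrate(p, rolled, t_end=20.0, n_snapshots=5)
        np.testing.assert_allclose(
            t2.final_state.D, np.roll(t1.final_state.D, 2), atol=1e-6
        )


class TestRelaxToSteady:
    def test_already_steady_returns_immediately(self):
        r = solve_pattern(het_params(), 1)
        state, ok = relax_to_steady(r.params, r.state)
        assert ok
        np.testing.assert_allclose(state.D, r.state.D, atol=1e-9)

    def test_stable_root_recaptures_small_perturbations(self):
        r = solve_pattern(het_params(), 1)
        assert r.stable == "stable"
        init = perturb(r.state, 0.01, seed=11)
        state, ok = relax_to_steady(r.params, init)
        assert ok
        assert np.max(np.abs(state.D - r.state.D)) < 1e-6

    def test_unstable_root_sheds_small_perturbations(self):
        # the uniform state at salt-and-pepper parameters is unstable
        p = het_params()
        u = uniform_state(p)
        r = solve_pattern(p, 0)
        assert r.stable == "unstable"
        init = perturb(u, 0.01, seed=5)
        state, ok = relax_to_steady(p, init)
        assert ok
        assert np.max(np.abs(state.D - u.D)) > 1e-3
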