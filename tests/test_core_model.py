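"""Unit and property tests for parameters, interface law and rhs."""

import math

import numpy as np
import pytest

from tipstalk.core_model import (
    INFINITE,
    DimensionalParams,
    LatticeState,
    ModelParams,
    binding_rate,
    interface_distance,
    interface_rates,
    nondimensionalize,
    rhs_classical,
    rhs_full,
)
from tipstalk.errors import (
    DegenerateInterfaceError,
    InvalidParameterError,
    InvalidStateError,
    UnsupportedVariantError,
)
from tipstalk.steady_state import uniform_state


def make_params(**kw):
    defaults = dict(b0=0.8, K=0.1, kd=1.0, kf0=0.3, h=0.0, W=0.0, n_cells=6)
    defaults.update(kw)
    return ModelParams(**defaults)


class TestParams:
    def test_positive_invariants_enforced(self):
        with pytest.raises(InvalidParameterError):
            ModelParams(b0=-1, K=0.1, kd=1, kf0=0.1)
        with pytest.raises(InvalidParameterError):
            ModelParams(b0=1, K=0.1, kd=1, kf0=0.1, h=-0.5)
        with pytest.raises(InvalidParameterError):
            ModelParams(b0=1, K=0.1, kd=1, kf0=0.1, n_cells=1)

    def test_variant_dispatch(self):
        assert make_params(W=INFINITE, h=0.0).variant == "classical"
        assert make_params(W=INFINITE, h=0.1).variant == "tension"
        assert make_params(W=0.0).variant == "heterogeneous"
        assert make_params(W=50.0, h=0.1).variant == "heterogeneous"


class TestNondimensionalize:
    def test_equal_decay_rates_give_unit_kd(self):
        dim = DimensionalParams(B0=2.0, k_D=0.5, k_N=0.5, k=1.0, K_F=1.0,
                                N0_total=3.0, F_Notch=0.0, L=1.0)
        p = nondimensionalize(dim)
        assert p.kd == pytest.approx(1.0)
        assert p.W == 0.0

    def test_inhibitory_ratio_identity(self):
        dim = DimensionalParams(B0=1.0, k_D=1.0, k_N=2.0, k=3.0, K_F=1.0,
                                N0_total=3.0, F_Notch=0.1, L=2.0)
        p = nondimensionalize(dim)
        assert p.K == pytest.approx(1.0)
        # W = F_Notch / (L^2 k_D N0)
        assert p.W == pytest.approx(0.1 / (4.0 * 1.0 * 3.0))
        # kf0 = K_F D0 / (2 k_D) with D0 = kd / B0
        assert p.kf0 == pytest.approx(1.0 * 2.0 / 2.0 / 1.0)

    def test_rejects_nonpositive(self):
        with pytest.raises(InvalidParameterError):
            DimensionalParams(B0=0.0, k_D=1, k_N=1, k=1, K_F=1,
                              N0_total=1, F_Notch=0, L=1)


class TestInterfaceDistance:
    def test_limiting_reagent_hand_value(self):
        # each direction contributes min(free Notch, facing Delta)
        assert interface_distance(0.5, 0.8, 0.2, 0.1) == pytest.approx(1 / 0.6)

    def test_free_receptors_with_no_ligand_is_degenerate(self):
        # no Delta anywhere: no adhesive contact can form
        with pytest.raises(DegenerateInterfaceError):
            interface_distance(0.0, 0.0, 0.0, 0.0)

    def test_fully_bound_no_ligand_is_degenerate(self):
        with pytest.raises(DegenerateInterfaceError):
            interface_distance(1.0, 0.0, 1.0, 0.0)

    def test_saturated_contacts_give_unit_capacity(self):
        # plenty of Delta and free Notch on both directions
        assert interface_distance(0.0, 2.0, 0.0, 2.0) == pytest.approx(0.5)


class TestBindingRate:
    def test_h_zero_gives_baseline_everywhere(self):
        p = make_params(kf0=0.7, h=0.0)
        x = np.array([0.2, 1.0, 30.0])
        assert np.all(binding_rate(x, p) == 0.7)

    def test_optimum_distance_gives_baseline(self):
        p = make_params(kf0=5.0, h=0.3, lam=4.0)
        assert binding_rate(4.0, p) == pytest.approx(5.0)

    def test_scalar_evaluation(self):
        p = make_params(kf0=40.0, h=0.076, lam=10.0)
        assert binding_rate(0.5, p) == pytest.approx(
            40.0 * math.exp(-0.076 * 9.5**2), rel=1e-12
        )
        assert binding_rate(0.5, p) == pytest.approx(0.0420, abs=2e-4)

    def test_bounded_by_baseline(self, rng):
        p = make_params(kf0=3.0, h=0.05, lam=10.0)
        x = rng.uniform(0.1, 50.0, 100)
        kf = binding_rate(x, p)
        assert np.all(kf > 0) and np.all(kf <= 3.0)


class TestRhsFull:
    def test_uniform_state_is_fixed_point(self):
        p = make_params(W=2.0)
        u = uniform_state(p)
        d = rhs_full(u, p)
        assert max(np.max(np.abs(d.D)), np.max(np.abs(d.N_left)),
                   np.max(np.abs(d.N_right))) < 1e-10

    def test_diffusion_term_vanishes_for_symmetric_sides(self, rng):
        D = rng.uniform(0.05, 0.8, 6)
        N = rng.uniform(0.0, 0.9, 6)
        st = LatticeState(D, N.copy(), N.copy())
        d0 = rhs_full(st, make_params(W=0.0))
        d5 = rhs_full(st, make_params(W=5.0))
        np.testing.assert_allclose(d0.N_left, d5.N_left, atol=1e-14)
        np.testing.assert_allclose(d0.N_right, d5.N_right, atol=1e-14)

    def test_symmetric_sides_sum_to_classical_form(self, rng):
        # with h=0 and N_l=N_r=N, each side's derivative uses kf0 on its
        # own neighbour; their sum reproduces the one-pool balance with
        # the neighbours entering separately
        p = make_params(h=0.0, W=0.0)
        D = rng.uniform(0.05, 0.8, 6)
        N = rng.uniform(0.0, 0.9, 6)
        st = LatticeState(D, N.copy(), N.copy())
        d = rhs_full(st, p)
        total = d.N_left + d.N_right
        expected = (
            -2 * p.kd * N
            + p.kf0 * (np.roll(D, 1) + np.roll(D, -1)) * (1 - N)
        )
        np.testing.assert_allclose(total, expected, atol=1e-12)

    def test_translation_equivariance(self, rng):
        p = make_params(h=0.076, lam=10.0, W=1.0)
        st = LatticeState(rng.uniform(0.05, 0.8, 6), rng.uniform(0, 1, 6),
                          rng.uniform(0, 1, 6))
        d = rhs_full(st, p)
        for k in range(1, 6):
            rolled = LatticeState(np.roll(st.D, k), np.roll(st.N_left, k),
                                  np.roll(st.N_right, k))
            dr = rhs_full(rolled, p)
            np.testing.assert_allclose(dr.D, np.roll(d.D, k), atol=1e-13)
            np.testing.assert_allclose(dr.N_left, np.roll(d.N_left, k), atol=1e-13)
            np.testing.assert_allclose(dr.N_right, np.roll(d.N_right, k), atol=1e-13)

    def test_mirror_symmetry(self, rng):
        # reversing the lattice and swapping left/right commutes with rhs
        p = make_params(h=0.076, lam=10.0, W=1.0)
        st = LatticeState(rng.uniform(0.05, 0.8, 6), rng.uniform(0, 1, 6),
                          rng.uniform(0, 1, 6))
        d = rhs_full(st, p)
        mirror = LatticeState(st.D[::-1].copy(), st.N_right[::-1].copy(),
                              st.N_left[::-1].copy())
        dm = rhs_full(mirror, p)
        np.testing.assert_allclose(dm.D, d.D[::-1], atol=1e-13)
        np.testing.assert_allclose(dm.N_left, d.N_right[::-1], atol=1e-13)
        np.testing.assert_allclose(dm.N_right, d.N_left[::-1], atol=1e-13)

    def test_rejects_single_pool_params(self):
        st = LatticeState(np.full(6, 0.1), np.full(6, 0.1), np.full(6, 0.1))
        with pytest.raises(UnsupportedVariantError):
            rhs_full(st, make_params(W=INFINITE))

    def test_rejects_invalid_state(self):
        st = LatticeState(np.full(6, -0.5), np.full(6, 0.1), np.full(6, 0.1))
        with pytest.raises(InvalidStateError):
            rhs_full(st, make_params(W=0.0))


class TestRhsClassical:
    def test_no_inhibition_without_notch(self):
        p = make_params(W=INFINITE)
        D = np.full(6, 0.3)
        dD, _ = rhs_classical(D, np.zeros(6), p)
        np.testing.assert_allclose(dD, -D + p.b0)

    def test_half_maximal_inhibition_at_K(self):
        p = make_params(W=INFINITE)
        dD, _ = rhs_classical(np.zeros(6), np.full(6, p.K), p)
        np.testing.assert_allclose(dD, np.full(6, p.b0 / 2))

    def test_uniform_fixed_point_matches_oracle(self):
        # independent damped fixed-point iteration oracle
        p = ModelParams(b0=0.5, K=1.0, kd=1.0, kf0=0.1, W=INFINITE, n_cells=6)
        D = 0.25
        for _ in range(400):
            N = 2 * p.kf0 * D / (p.kd + 2 * p.kf0 * D)
            D = 0.5 * D + 0.5 * p.b0 / (1 + (N / p.K) ** 2)
        assert D == pytest.approx(0.4959, abs=1e-3)
        dD, dN = rhs_classical(np.full(6, D), np.full(6, N), p)
        assert np.max(np.abs(np.r_[dD, dN])) < 1e-7

    def test_rejects_tension_params(self):
        p = make_params(W=INFINITE, h=0.1)
        with pytest.raises(UnsupportedVariantError):
            rhs_classical(np.full(6, 0.1), np.full(6, 0.1), p)


class TestInterfaceRates:
    def test_h_zero_all_rates_equal_baseline(self, rng):
        p = make_params(h=0.0, W=0.0)
        st = LatticeState(rng.uniform(0.05, 0.8, 6), rng.uniform(0, 1, 6),
                          rng.uniform(0, 1, 6))
        rates = interface_rates(st, p)
        assert np.all(rates.kf == p.kf0)

    def test_rates_never_exceed_baseline(self, rng):
        p = make_params(h=0.076, lam=10.0, W=0.0)
        st = LatticeState(rng.uniform(0.05, 0.8, 6), rng.uniform(0, 0.95, 6),
                          rng.uniform(0, 0.95, 6))
        rates = interface_rates(st, p)
        assert np.all(rates.kf >= 0) and np.all(rates.kf <= p.kf0)
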