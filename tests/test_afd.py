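"""Adaptive Fourier decomposition: analytic lift, greedy selection, energy ledger."""

import numpy as np
import pytest

import teanir as tn
from teanir.afd import (AnalyticSignal, PoleGrid, _direct_inner_products,
                        afd_decompose, afd_reconstruct, discrete_szego_norm,
                        inner, szego_evaluator, to_analytic, weighted_blaschke)
from teanir.dataset import ValidationError


class TestToAnalytic:
    def test_single_harmonic(self):
        t = 2 * np.pi * np.arange(64) / 64
        sig = to_analytic(np.cos(t))
        np.testing.assert_allclose(sig.fplus, np.exp(1j * t) / 2, atol=1e-12)
        np.testing.assert_allclose(sig.to_real(), np.cos(t), atol=1e-12)

    def test_constant_signal(self):
        sig = to_analytic(np.full(16, 5.0))
        np.testing.assert_allclose(sig.fplus, 5.0, atol=1e-12)
        assert sig.c0 == 5.0

    def test_random_round_trip(self, rng):
        f = rng.standard_normal(101)
        sig = to_analytic(f)
        assert np.max(np.abs(sig.to_real() - f)) < 1e-10

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            to_analytic(np.ones(4))


class TestSzegoEvaluator:
    def test_zero_pole_is_constant_one(self):
        t = 2 * np.pi * np.arange(32) / 32
        np.testing.assert_allclose(szego_evaluator(0.0, t), 1.0)

    @pytest.mark.parametrize("r", [0.1, 0.4, 0.7])
    def test_unit_quadrature_norm_for_moderate_radii(self, r):
        t = 2 * np.pi * np.arange(128) / 128
        e = szego_evaluator(r * np.exp(0.7j), t)
        assert inner(e, e).real == pytest.approx(1.0, abs=1e-6)

    def test_discrete_norm_closed_form_matches_quadrature(self):
        t = 2 * np.pi * np.arange(64) / 64
        for a in (0.3, 0.9 * np.exp(1.2j), 0.98):
            e = szego_evaluator(a, t)
            assert discrete_szego_norm(a, 64) == pytest.approx(
                np.sqrt(inner(e, e).real), abs=1e-12)

    def test_no_zeros_on_grid_and_boundary_pole_rejected(self):
        t = 2 * np.pi * np.arange(32) / 32
        assert np.all(np.abs(szego_evaluator(0.5j, t)) > 0)
        with pytest.raises(ValidationError):
            szego_evaluator(1.0, t)


class TestWeightedBlaschke:
    def test_first_order_with_zero_pole_is_one(self):
        t = 2 * np.pi * np.arange(32) / 32
        np.testing.assert_allclose(weighted_blaschke([0.0], t), 1.0)

    def test_moebius_factors_unimodular_on_circle(self, rng):
        t = 2 * np.pi * np.arange(64) / 64
        poles = 0.8 * np.exp(1j * rng.uniform(0, 2 * np.pi, 3))
        B3 = weighted_blaschke(poles, t)
        e3 = szego_evaluator(poles[-1], t)
        np.testing.assert_allclose(np.abs(B3), np.abs(e3), atol=1e-12)

    def test_tm_system_orthonormal_under_quadrature(self, rng):
        # long grid so the O(r^2N) aliasing error is negligible
        t = 2 * np.pi * np.arange(1024) / 1024
        poles = 0.85 * np.exp(1j * rng.uniform(0, 2 * np.pi, 3))
        B = [weighted_blaschke(poles[:k + 1], t) for k in range(3)]
        G = np.array([[inner(B[i], B[j]) for j in range(3)] for i in range(3)])
        assert np.max(np.abs(G - np.eye(3))) < 1e-6


class TestDecompose:
    def test_constant_signal_one_step_at_origin(self):
        t = 2 * np.pi * np.arange(32) / 32
        sig = AnalyticSignal(t, np.full(32, 3.0 + 0j), 3.0)
        res = afd_decompose(sig)
        assert res.level == 1
        assert res.poles[0] == 0
        assert res.coefficients[0] == pytest.approx(3.0)
        assert res.ree_trace[0] == pytest.approx(0.0, abs=1e-12)

    def test_planted_evaluator_recovered_in_one_step(self):
        t = 2 * np.pi * np.arange(64) / 64
        a_star = 0.4 * np.exp(1j * t[7])
        sig = AnalyticSignal(t, szego_evaluator(a_star, t), 0.0)
        res = afd_decompose(sig)
        assert res.level == 1
        assert res.poles[0] == pytest.approx(a_star, abs=1e-12)
        assert abs(res.coefficients[0]) == pytest.approx(1.0, abs=1e-10)
        assert res.ree_trace[0] < 1e-6

    def test_energy_ledger_exact_at_every_step(self, rng):
        f = rng.standard_normal(64)
        sig = to_analytic(f)
        res = afd_decompose(sig, max_level=15, energy_retention=1.0)
        z = np.exp(1j * sig.t)
        fk = sig.fplus.copy()
        for a, d in zip(res.poles, res.coefficients):
            before = inner(fk, fk).real
            atom = szego_evaluator(a, sig.t) / discrete_szego_norm(a, 64)
            fk = (fk - d * atom) * (1 - np.conj(a) * z) / (z - a)
            after = inner(fk, fk).real
            assert after == pytest.approx(before - abs(d) ** 2, abs=1e-8)

    def test_greedy_step_equals_direct_grid_argmax(self, rng):
        f = rng.standard_normal(64)
        sig = to_analytic(f)
        grid = PoleGrid()
        res = afd_decompose(sig, grid, max_level=1, energy_retention=1.0)
        cand = grid.poles(sig.t)
        ip = _direct_inner_products(sig.fplus, cand, sig.t)
        k = int(np.argmax(np.abs(ip) ** 2))
        assert res.poles[0] == pytest.approx(cand[k], abs=1e-12)

    def test_ree_trace_non_increasing_and_deterministic(self, rng):
        f = rng.standard_normal(48)
        sig = to_analytic(f)
        r1 = afd_decompose(sig, max_level=12, energy_retention=1.0)
        r2 = afd_decompose(sig, max_level=12, energy_retention=1.0)
        assert np.all(np.diff(r1.ree_trace) <= 1e-12)
        np.testing.assert_array_equal(r1.poles, r2.poles)
        np.testing.assert_array_equal(r1.coefficients, r2.coefficients)

    def test_scaling_equivariance(self, rng):
        f = rng.standard_normal(48)
        sig = to_analytic(f)
        res = afd_decompose(sig, max_level=6, energy_retention=1.0)
        scaled = AnalyticSignal(sig.t, 2.5 * sig.fplus, 2.5 * sig.c0)
        res2 = afd_decompose(scaled, max_level=6, energy_retention=1.0)
        np.testing.assert_array_equal(res.poles, res2.poles)
        np.testing.assert_allclose(res2.coefficients, 2.5 * res.coefficients,
                                   atol=1e-10)

    def test_zero_signal_gives_empty_result(self):
        t = 2 * np.pi * np.arange(16) / 16
        res = afd_decompose(AnalyticSignal(t, np.zeros(16, complex), 0.0))
        assert res.level == 0


class TestReconstruct:
    def test_constant_one_term(self):
        t = 2 * np.pi * np.arange(32) / 32
        sig = AnalyticSignal(t, np.full(32, 2.0 + 0j), 2.0)
        res = afd_decompose(sig)
        np.testing.assert_allclose(afd_reconstruct(res), 2.0, atol=1e-12)

    def test_recomputed_ree_matches_trace(self, rng):
        f = rng.standard_normal(64)
        sig = to_analytic(f)
        res = afd_decompose(sig, max_level=10, energy_retention=1.0)
        rec = afd_reconstruct(res)
        ree = np.sqrt(inner(sig.fplus - rec, sig.fplus - rec).real / sig.energy)
        assert ree == pytest.approx(res.ree_trace[-1], abs=1e-8)

    def test_ree_converges_to_zero_with_depth(self, rng):
        f = rng.standard_normal(32)
        sig = to_analytic(f)
        res = afd_decompose(sig, max_level=60, energy_retention=1.0)
        assert res.ree_trace[-1] < 0.05
        assert np.all(np.diff(res.ree_trace) <= 1e-12)


class TestFeaturizer:
    def test_identical_rows_give_identical_features(self):
        row = 0.5 + 0.1 * np.sin(np.linspace(0, 6, 40))
        X = np.tile(row, (4, 1))
        F = tn.AFDFeaturizer().fit_transform(X)
        assert np.allclose(F, F[0])

    def test_feature_count_fixed_at_dataset_max_level(self, rng):
        X = 0.5 + 0.05 * rng.standard_normal((5, 40)).cumsum(axis=1)
        feat = tn.AFDFeaturizer().fit(X)
        F = feat.transform(X)
        assert F.shape == (5, feat.n_levels_)

    def test_feature_energy_bounded_by_signal_energy(self, rng):
        X = 0.5 + 0.05 * rng.standard_normal((5, 40)).cumsum(axis=1)
        F = tn.AFDFeaturizer().fit_transform(X)
        for row, feats in zip(X, F):
            assert feats.sum() <= to_analytic(row).energy + 1e-10
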