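"""Tests for the penalized joint fitter: proximal operators, ADMM solution
quality against an independent solver, fusion/sparsity limits, phase
extraction, and the AIC-type grid search."""

import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tests.oracles import smoothed_objective as _smoothed_objective

from tgnet.fitter import (
    FitConfig,
    _QuadLoss,
    _offdiag_mask,
    aic_select,
    block_soft_threshold,
    extract_phases,
    fit_joint,
    lambda1_max,
    refit_structure,
    soft_threshold,
)
from tgnet.synthetic import make_scenario, sample_panel
from tgnet.tgm import HWeight, TGMParams


class TestProximalOperators:
    @pytest.mark.parametrize(
        "x,t,expected", [(0.5, 1.0, 0.0), (-2.0, 0.5, -1.5), (3.0, 0.0, 3.0)]
    )
    def test_soft_threshold_values(self, x, t, expected):
        assert soft_threshold(x, t) == expected

    @given(st.floats(-50, 50), st.floats(0, 20))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_soft_threshold_shrinks_toward_zero(self, x, t):
        out = soft_threshold(x, t)
        assert abs(out) <= abs(x)
        assert out * x >= 0

    def test_block_full_shrinkage(self):
        X = np.array([[0.0, 0.6], [0.6, 0.0]])  # frobenius norm < 1
        assert np.all(block_soft_threshold(X, 2.0) == 0.0)

    def test_block_scaling(self):
        X = np.array([[0.0, 2.0], [0.0, 0.0]])  # frobenius norm 2
        np.testing.assert_allclose(block_soft_threshold(X, 1.0), X / 2)

    def test_block_identity_at_zero(self):
        X = np.arange(4.0).reshape(2, 2)
        np.testing.assert_array_equal(block_soft_threshold(X, 0.0), X)


class TestFitJoint:
    def test_objective_matches_convex_oracle(self, small_panel):
        cfg = FitConfig(lambda1=0.05, lambda2=0.05, standardize=False)
        res = fit_joint(small_panel, cfg)
        oracle = _smoothed_objective(small_panel, cfg)
        assert res.objective == pytest.approx(oracle, rel=1e-4)

    def test_lambda2_zero_equals_independent_fits(self, small_panel):
        cfg = FitConfig(lambda1=0.05, lambda2=0.0, standardize=False)
        joint = fit_joint(small_panel, cfg)
        separate = sum(
            fit_joint([Y], FitConfig(lambda1=0.05, lambda2=0.0, standardize=False)).objective
            for Y in small_panel
        )
        assert joint.objective == pytest.approx(separate, abs=1e-4)

    def test_large_lambda1_empties_graphs_and_fuses(self, small_panel):
        lmax = lambda1_max(small_panel)
        res = fit_joint(small_panel, FitConfig(lambda1=2.5 * lmax, lambda2=0.01, standardize=False))
        for est in res.estimates:
            off = est.Theta - np.diag(np.diag(est.Theta))
            assert np.all(off == 0.0)
        assert res.phases == [(1, len(small_panel))]
        assert res.change_points == []

    def test_large_lambda2_collapses_to_pooled_fit(self, small_panel):
        cfg = FitConfig(lambda1=0.05, lambda2=50.0, standardize=False)
        res = fit_joint(small_panel, cfg)
        assert res.phases == [(1, len(small_panel))]
        # oracle: minimize with off-diagonals tied across periods
        oracle = _smoothed_objective(small_panel, cfg, tie_offdiag=True)
        # at this lambda2 the fusion term is exactly zero in both solutions
        assert res.objective == pytest.approx(oracle, rel=1e-4)

    def test_objective_never_worse_than_reference_points(self, small_panel):
        cfg = FitConfig(lambda1=0.08, lambda2=0.08, standardize=False)
        res = fit_joint(small_panel, cfg)
        p = small_panel[0].shape[1]
        from tgnet.fitter import objective_value

        zero = [TGMParams(np.zeros((p, p)), np.zeros(p)) for _ in small_panel]
        assert res.objective <= objective_value(small_panel, zero, cfg.lambda1, cfg.lambda2) + 1e-8
        unpen = [
            fit_joint([Y], FitConfig(lambda1=0.0, lambda2=0.0, standardize=False)).estimates[0]
            for Y in small_panel
        ]
        assert res.objective <= objective_value(small_panel, unpen, cfg.lambda1, cfg.lambda2) + 1e-8

    def test_edge_count_monotone_in_lambda1(self, small_panel):
        lmax = lambda1_max(small_panel)
        counts = []
        for frac in (0.05, 0.15, 0.4, 1.1):
            res = fit_joint(small_panel, FitConfig(lambda1=frac * lmax, lambda2=0.01, standardize=False))
            iu = np.triu_indices(small_panel[0].shape[1], k=1)
            counts.append(sum(int(np.count_nonzero(e.Theta[iu])) for e in res.estimates))
        assert counts == sorted(counts, reverse=True)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_joint([np.ones((1, 3))], FitConfig())


class TestExtractPhases:
    def test_single_period(self):
        prm = TGMParams(np.eye(3), np.zeros(3))
        phases, cps = extract_phases([prm])
        assert phases == [(1, 1)] and cps == []

    def test_identical_matrices_merge(self):
        prm = TGMParams(np.eye(4) + 0.1, np.zeros(4))
        phases, cps = extract_phases([prm] * 4)
        assert phases == [(1, 4)] and cps == []

    def test_distinct_offdiagonals_split(self):
        T1 = np.eye(3)
        T2 = np.eye(3).copy()
        T2[0, 1] = T2[1, 0] = 0.5
        phases, cps = extract_phases([TGMParams(T1, np.zeros(3)), TGMParams(T2, np.zeros(3))])
        assert phases == [(1, 1), (2, 2)] and cps == [1]

    def test_diagonal_differences_ignored(self):
        # phases are defined by the off-diagonal part only
        phases, _ = extract_phases([TGMParams(np.eye(3), np.zeros(3)), TGMParams(2 * np.eye(3), np.zeros(3))])
        assert phases == [(1, 2)]


class TestAicSelect:
    def test_single_grid_point_returned(self, small_panel):
        cfg = FitConfig(standardize=False)
        l1, l2, res, table = aic_select(small_panel, [0.05], [0.02], cfg)
        assert (l1, l2) == (0.05, 0.02)
        assert len(table) == 1

    def test_df_formula_one_phase(self):
        # a 1-phase fit with k shared edges and p nodes contributes k + p
        from tgnet.fitter import _phase_df, FitResult

        p = 10
        T = np.eye(p)
        T[0, 1] = T[1, 0] = 0.3
        T[2, 5] = T[5, 2] = -0.2
        ests = [TGMParams(T, np.zeros(p))] * 3
        res = FitResult(ests, [(1, 3)], [], 0.0, {})
        assert _phase_df(res, p) == 2 + p

    def test_tie_break_prefers_larger_lambdas(self, small_panel):
        # duplicated grid values force exact AIC ties
        cfg = FitConfig(standardize=False)
        lmax = lambda1_max(small_panel)
        l1, l2, _, _ = aic_select(small_panel, [3 * lmax, 3 * lmax], [0.01, 0.01], cfg)
        assert l1 == 3 * lmax

    def test_empty_grid_rejected(self, small_panel):
        with pytest.raises(ValueError):
            aic_select(small_panel, [], [0.1], FitConfig())


class TestRefitStructure:
    def test_refit_matches_unpenalized_on_full_support(self, small_panel):
        p = small_panel[0].shape[1]
        iu = np.triu_indices(p, k=1)
        supports = [np.ones(len(iu[0]), dtype=bool)]
        ests = refit_structure([small_panel[0]], [(1, 1)], supports)
        from tgnet.tgm import fit_unpenalized

        direct = fit_unpenalized(small_panel[0])
        np.testing.assert_allclose(ests[0].Theta, direct.Theta, atol=1e-8)

    def test_refit_respects_support_zeros(self, small_panel):
        p = small_panel[0].shape[1]
        iu = np.triu_indices(p, k=1)
        supp = np.zeros(len(iu[0]), dtype=bool)
        ests = refit_structure(small_panel, [(1, 2)], [supp])
        for e in ests:
            assert np.all(e.Theta[iu] == 0.0)
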