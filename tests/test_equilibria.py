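"""Cure, recurrence, and coexistence steady states."""

import dataclasses

import numpy as np
import pytest

from gliostem import (coexistence_equilibria, cure_equilibrium, cure_state,
                      eval_rhs_gbm, recurrence_equilibria,
                      solve_recruitment_C)
from gliostem.equilibria import recurrence_L
from gliostem.exceptions import DomainError


class TestCureState:
    def test_untreated_cure_levels(self, params):
        st = cure_state(params)
        assert st.as_array() == pytest.approx(
            [0.0, 0.0, 0.0, 9135.0, 0.0, 100.0, 0.0])

    def test_ctl_level_scales_with_dose(self, params):
        st = cure_state(params.replace(N=1.0))
        assert st.C == pytest.approx(1.0 / 0.007)

    @pytest.mark.parametrize("N", [0.0, 1.0, 1e6, 1.08783e15])
    def test_residual_contract(self, params, N):
        eq = cure_equilibrium(params.replace(N=N))
        scale = max(1.0, float(np.max(eq.state.as_array())))
        assert eq.residual <= 1e-10 * scale
        assert np.max(np.abs(eval_rhs_gbm(eq.state, eq_params(params, N)))) \
            <= 1e-10 * scale

    def test_untreated_cure_state_is_unstable(self, params):
        eq = cure_equilibrium(params)
        assert eq.label == "unstable"
        assert max(eq.eigenvalues.real) == pytest.approx(params.r2)


def eq_params(params, N):
    return params.replace(N=N)


class TestRecruitmentBalance:
    def test_constant_inflow_gives_ctl_steady_state(self, params):
        # the concrete model has no recruitment: C_p = N/muC for any burden
        p = params.replace(N=1.0)
        assert solve_recruitment_C(70.0, 30.0, params=p) \
            == pytest.approx(1.0 / p.muC, rel=1e-12)
        assert solve_recruitment_C(p.K1, p.K2, params=p) \
            == pytest.approx(1.0 / p.muC, rel=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_root_agrees_with_dense_grid_oracle(self, seed):
        from gliostem import random_a2_forms
        forms, mu, meta = random_a2_forms(seed)
        T, S = meta["K1"] / 3.0, meta["K2"] / 4.0
        C = solve_recruitment_C(T, S, forms=forms, mu=mu)
        x_p = forms.fx(T + S) / mu.mux

        def H(c):
            v = forms.fv(x_p) * forms.gv(forms.fy(c) / mu.muy) / mu.muv
            return forms.fC((T + S) * v) * forms.gC(x_p) \
                - mu.muC * c + forms.N_const

        grid = np.linspace(0.0, 4.0 * C, 1_000_001)
        hv = np.vectorize(H)(grid)
        idx = np.nonzero(np.sign(hv[:-1]) * np.sign(hv[1:]) < 0)[0]
        assert idx.size == 1  # H strictly decreasing: a single root
        lo, hi = grid[idx[0]], grid[idx[0] + 1]
        assert lo <= C <= hi

    def test_no_inflow_no_recruitment_is_rejected(self, params):
        with pytest.raises(DomainError):
            solve_recruitment_C(10.0, 10.0, params=params)  # N = 0, fC = 0


class TestRecurrenceStates:
    def test_untreated_stem_pool_saturates_at_capacity(self, params):
        roots = recurrence_equilibria(params, 0.0)
        assert len(roots) == 1
        assert roots[0].S == pytest.approx(params.K2)
        assert roots[0].label == "stable"

    def test_strong_treatment_clears_all_roots(self, params):
        from gliostem import recurrence_thresholds
        _, Nthr = recurrence_thresholds(params)
        assert recurrence_equilibria(params, Nthr * 1.01) == []

    def test_odd_root_count_below_local_threshold(self, params):
        """Whenever the stem pool still grows at the origin the flow
        must cross zero an odd number of times before the capacity."""
        for N in (0.0, 0.5, 1.0, 1e4):
            L = recurrence_L(params, N)
            roots = recurrence_equilibria(params, N)
            if float(L(0.0)) > 0:
                assert len(roots) % 2 == 1

    def test_roots_agree_with_million_point_sign_scan(self, params):
        N = 1.0
        L = recurrence_L(params, N)
        Sg = np.linspace(0.0, params.K2, 1_000_001)
        v = np.asarray(L(Sg))
        idx = np.nonzero(np.sign(v[:-1]) * np.sign(v[1:]) < 0)[0]
        roots = recurrence_equilibria(params, N)
        assert len(roots) == idx.size
        for r, i in zip(roots, idx):
            assert Sg[i] <= r.S <= Sg[i + 1]


class TestCoexistenceStates:
    def test_untreated_tumor_saturates_both_capacities(self, params):
        pts = coexistence_equilibria(params, 0.0)
        assert any(p.T == pytest.approx(params.K1, rel=1e-9)
                   and p.S == pytest.approx(params.K2, rel=1e-9)
                   for p in pts)
        full = [p for p in pts if p.T == pytest.approx(params.K1, rel=1e-9)]
        assert full[0].label == "stable"
        assert full[0].parity_label == "stable"

    def test_residual_contract(self, params):
        for p in coexistence_equilibria(params, 0.0):
            assert p.residual <= 1e-8

    def test_cure_dose_leaves_no_coexistence_state(self, params):
        from gliostem import compute_thresholds
        rep = compute_thresholds(params)
        assert coexistence_equilibria(params, rep.Ncure * 1.000001) == []

    def test_coarse_grid_rejected(self, params):
        with pytest.raises(DomainError):
            coexistence_equilibria(params, 0.0, grid=50)
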