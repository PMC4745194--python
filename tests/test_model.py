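"""Parameters, state containers, and the two right-hand-side routes."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gliostem import (DeathRates, ModelParameters, SystemState,
                      eval_rhs_abstract, eval_rhs_gbm, eval_rhs_reduced,
                      kronik_forms, tgfb_qss)
from gliostem.exceptions import ConfigurationError, DomainError
from gliostem.model import STATE_VARS, rhs_gbm_array

from conftest import random_states


class TestParameters:
    def test_defaults_match_published_table(self, params):
        assert params.r1 == 1e-3
        assert params.K1 == 1e8
        assert params.aS == pytest.approx(0.1 * params.aT)
        assert params.gbeta == 6.3945e4
        assert params.eS == params.eT
        assert params.hS == params.hT
        assert params.abetaS == params.abetaT
        assert params.N == 0.0

    @pytest.mark.parametrize("bad", [
        {"r1": -1.0}, {"K1": 0.0}, {"muC": 0.0}, {"aTbeta": 1.5},
        {"mubeta": -2.0},
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(DomainError):
            ModelParameters(**bad)

    def test_unknown_key_rejected_by_name(self):
        with pytest.raises(ConfigurationError, match="r3"):
            ModelParameters.from_dict({"r3": 1.0})

    def test_dict_round_trip(self, params):
        assert ModelParameters.from_dict(params.to_dict()) == params


class TestState:
    def test_negative_component_rejected(self):
        with pytest.raises(DomainError):
            SystemState(-1.0, 0, 0, 0, 0, 0, 0)

    def test_array_round_trip(self):
        y = np.arange(7.0)
        assert np.array_equal(SystemState.from_array(y).as_array(), y)


class TestConcreteRHS:
    """Direct substitutions into the printed system."""

    def test_ctl_and_ifn_rates_at_reference_state(self, params):
        r = eval_rhs_gbm(SystemState(70, 30, 250, 50, 50, 50, 50), params)
        # dC/dt = -muC*C with no treatment; dFgamma/dt = agammaC*C - mugamma*Fg
        assert r[2] == pytest.approx(-1.75, abs=1e-12)
        assert r[4] == pytest.approx(-5.0745, abs=1e-12)

    def test_zero_state_rates_are_basal_productions(self, params):
        r = eval_rhs_gbm(np.zeros(7), params)
        expected = np.zeros(7)
        expected[3] = params.gbeta   # basal TGF-beta
        expected[5] = params.gMI     # basal MHC-I expression
        assert np.array_equal(r, expected)

    def test_nonfinite_state_rejected(self, params):
        with pytest.raises(DomainError):
            eval_rhs_gbm(np.array([np.nan, 0, 0, 0, 0, 0, 0]), params)

    def test_boundary_orthant_invariance(self, params, rng):
        """A vanishing coordinate never has a negative rate."""
        for y in random_states(rng, 40):
            for i in range(7):
                z = y.copy()
                z[i] = 0.0
                assert eval_rhs_gbm(z, params)[i] >= 0.0


class TestAbstractRHS:
    def test_builtin_forms_match_concrete_system(self, params, forms, mu,
                                                 rng):
        worst = 0.0
        for y in random_states(rng, 100):
            a = eval_rhs_gbm(y, params)
            b = eval_rhs_abstract(y, forms, mu)
            worst = max(worst, float(np.max(
                np.abs(a - b) / np.maximum(np.abs(a), 1e-300))))
        assert worst <= 1e-12

    def test_zero_alpha_keeps_tumor_axis_invariant(self, forms, mu):
        f0 = dataclasses.replace(forms, alpha=lambda T, S: 0.0)
        r = eval_rhs_abstract(np.array([0.0, 1e5, 1e3, 50, 50, 50, 50]),
                              f0, mu)
        assert r[0] == 0.0

    def test_ctl_rate_nonnegative_without_inflow_or_cells(self, forms, mu):
        f0 = dataclasses.replace(forms, N_const=0.0)
        r = eval_rhs_abstract(np.array([10.0, 10.0, 0.0, 50, 50, 50, 50]),
                              f0, mu)
        assert r[2] >= 0.0

    def test_missing_form_rejected(self, forms):
        with pytest.raises(ConfigurationError, match="fT"):
            dataclasses.replace(forms, fT=None)


class TestFastTgfbReduction:
    def test_quasi_steady_level_at_empty_and_full_tumor(self, params):
        assert tgfb_qss(0.0, 0.0, params) == pytest.approx(9135.0)
        assert tgfb_qss(params.K1, params.K2, params) == pytest.approx(
            9225.357142857143)

    def test_reduced_rates_equal_full_rates_at_qss(self, params, rng):
        for y in random_states(rng, 20):
            y[3] = tgfb_qss(y[0], y[1], params)
            full = eval_rhs_gbm(y, params)
            red = eval_rhs_reduced(np.delete(y, 3), params)
            assert np.allclose(red, np.delete(full, 3), rtol=1e-12, atol=0)

    def test_zero_death_rate_rejected(self):
        with pytest.raises(DomainError):
            DeathRates(muC=0.007, mux=0.0, muy=0.1, muu=0.01, muv=0.01)


@given(st.floats(min_value=0.0, max_value=1e8),
       st.floats(min_value=0.0, max_value=1e7))
def test_tgfb_qss_is_affine_in_burden(T, S):
    p = ModelParameters()
    expected = (p.gbeta + p.abetaT * T + p.abetaS * S) / p.mubeta
    assert tgfb_qss(T, S, p) == pytest.approx(expected, rel=1e-14)


def test_cure_state_is_an_equilibrium_of_the_rhs(params):
    from gliostem import cure_state
    for N in (0.0, 1.0, 1.08783e15):
        p = params.replace(N=N)
        st_ = cure_state(p)
        scale = max(1.0, float(np.max(st_.as_array())))
        assert np.max(np.abs(rhs_gbm_array(st_.as_array(), p))) \
            <= 1e-10 * scale
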