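"""Jacobians, cure-state spectra, and the stability certificates."""

import numpy as np
import pytest

from gliostem import (cure_decay_rates, cure_eigenvalues,
                      cure_eigenvalues_closed_form, cure_state,
                      dissipativity_constants, integrate, is_cure_stable,
                      jacobian_at, random_a2_forms, verify_global_cure,
                      ModelParameters, SystemState)
from gliostem.equilibria import cure_state_forms
from gliostem.stability import is_cure_stable_forms, jacobian_at_forms
from gliostem.thresholds import fbarS

from conftest import random_states


class TestJacobian:
    def test_linear_couplings_are_exact_constants(self, params, rng):
        for y in random_states(rng, 5):
            J = jacobian_at(y, params, analytic=True)
            assert J[4, 2] == params.agammaC   # IFN-gamma <- CTL secretion
            assert J[5, 0] == 0.0              # MHC-I has no T dependence
            assert J[3, 0] == params.abetaT    # TGF-beta <- tumor burden

    def test_finite_difference_matches_analytic(self, params, rng):
        worst = 0.0
        for y in random_states(rng, 50):
            Jf = jacobian_at(y, params)
            Ja = jacobian_at(y, params, analytic=True)
            worst = max(worst, float(np.max(np.abs(Jf - Ja))
                                     / np.max(np.abs(Ja))))
        assert worst <= 1e-6


class TestCureSpectrum:
    def test_cascade_clearance_rates_in_spectrum(self, params):
        for N in (0.0, 1.0, 1e12):
            lam = cure_eigenvalues(params, N).real
            assert np.min(np.abs(lam + 7.0)) < 1e-9       # TGF-beta
            assert np.min(np.abs(lam + 0.102)) < 1e-9     # IFN-gamma

    def test_untreated_spectrum_contains_growth_rates(self, params):
        lam = cure_eigenvalues(params, 0.0).real
        assert np.min(np.abs(lam - params.r1)) < 1e-12
        assert np.min(np.abs(lam - params.r2)) < 1e-12

    def test_cure_dose_stabilises_spectrum(self, params):
        assert np.all(cure_eigenvalues(params, 1.08783e15).real < 0)

    @pytest.mark.parametrize("seed", range(50))
    def test_closed_form_matches_numerics_on_random_bundles(self, seed):
        forms, mu, _ = random_a2_forms(seed)
        y0 = cure_state_forms(forms, mu)
        num = np.linalg.eigvals(jacobian_at_forms(y0, forms, mu))
        cf = cure_eigenvalues_closed_form(forms, mu)
        num = np.sort_complex(num[np.argsort(num.real)])
        rad = float(np.max(np.abs(cf)))
        assert np.max(np.abs(num - np.sort_complex(cf))) <= 1e-8 * rad


class TestCureStability:
    def test_untreated_cure_unstable(self, params):
        stable, margin = is_cure_stable(params, 0.0)
        assert not stable
        assert margin == pytest.approx(-params.r2)

    def test_cure_dose_stable(self, params):
        stable, margin = is_cure_stable(params, 1.08783e15)
        assert stable and margin > 0

    def test_abstract_inequalities_agree_with_spectrum(self):
        forms, mu, _ = random_a2_forms(3, N=1e6)
        verdict, margin = is_cure_stable_forms(forms, mu)
        y0 = cure_state_forms(forms, mu)
        top = float(np.max(np.linalg.eigvals(
            jacobian_at_forms(y0, forms, mu)).real))
        assert verdict == (top < 0)


class TestDecayCertificates:
    def test_tgfb_ceiling(self, params):
        x_max = (params.gbeta + params.abetaT * params.K1
                 + params.abetaS * params.K2) / params.mubeta
        assert x_max == pytest.approx(9225.357142857143)

    def test_no_certificate_without_treatment(self, params):
        a1, a2 = cure_decay_rates(params, 0.0)
        assert a1 < 0 and a2 < 0

    def test_positive_stem_certificate_bounds_simulated_decay(self, params):
        """With the immune cascade at its treated steady level, a2 > 0
        certifies S(t) <= S(0) exp(-hS(K2) fS(x_max) a2 t)."""
        p = params.replace(N=1e9)
        a1, a2 = cure_decay_rates(p)
        assert a2 > 0
        x_max = (p.gbeta + p.abetaT * p.K1 + p.abetaS * p.K2) / p.mubeta
        rate = a2 * float(fbarS(x_max, p)) / (p.hS + p.K2)
        cs = cure_state(p)
        init = SystemState(0.0, 1e6, cs.C, cs.Fbeta, cs.Fgamma, cs.MI,
                           cs.MII)
        traj = integrate(p, init, 100.0)
        bound = 1e6 * np.exp(-rate * traj.times * (1 - 1e-3))
        resolvable = bound >= 1e-6   # above solver floor
        assert np.all(traj.states[resolvable, 1]
                      <= bound[resolvable] * (1 + 1e-9))


class TestDissipativity:
    def test_published_constants(self, params):
        d = dissipativity_constants(params)
        assert d.delta == pytest.approx(1e-3)     # min clearance = r1
        assert d.a1 == pytest.approx(1e5)         # r1 K1
        assert d.b1 == params.r1

    def test_logistic_linear_bound_on_grid(self, params):
        d = dissipativity_constants(params)
        T = np.linspace(0.0, params.K1, 10_001)
        lhs = params.r1 * T * (1.0 - T / params.K1)
        assert np.all(lhs <= d.a1 - d.b1 * T + 1e-9 * d.a1)
        S = np.linspace(0.0, params.K2, 10_001)
        assert np.all(params.r2 * S * (1.0 - S / params.K2)
                      <= d.a2 - d.b2 * S + 1e-9 * d.a2)

    def test_state_sum_respects_absorbing_bound(self, scenario_runs):
        for name, (sc, traj, _) in scenario_runs.items():
            d = dissipativity_constants(sc.params, C0=sc.init.C)
            W = traj.states.sum(axis=1)
            assert np.all(W <= max(W[0], d.A / d.delta) * (1 + 1e-6)), name


class TestGlobalCureCertificate:
    def test_certificate_at_cure_dose_and_not_untreated(self, params):
        from gliostem import compute_thresholds
        rep = compute_thresholds(params)
        assert verify_global_cure(params, rep.Ncure * (1 + 1e-6))
        assert not verify_global_cure(params, 0.0)

    def test_monotone_in_dose(self, params):
        ladder = np.geomspace(1e6, 1e16, 10)
        verdicts = [verify_global_cure(params, float(N)) for N in ladder]
        assert verdicts == sorted(verdicts)  # False ... False True ... True
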