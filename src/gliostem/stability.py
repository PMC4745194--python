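"""Jacobians, cure-state spectra, decay-rate and dissipativity
certificates.

The cure state's local stability is an eigenvalue statement: the
cytokine/receptor cascade contributes its five clearance rates, and the
two cancer compartments contribute ``r_i - (kill pressure at C*)``.
Beyond local stability the module provides three certificates:

* exponential **decay rates** ``(a1, a2)`` bounding ``T' <= -a1 T`` and
  ``S' <= -a2 S`` when positive (worst-case kill over the whole state
  space);
* **dissipativity constants** ``(A, delta)`` with
  ``dW/dt <= A - delta W`` for the state sum ``W``, implying a compact
  global attractor with asymptotic bound ``W <= A/delta``;
* the **global-cure certificate**: a grid check that the reduced
  per-capita rates are negative everywhere on
  ``[0, K1] x [0, K2]``, which makes the cure state globally attracting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError
from .model import (DeathRates, FunctionalForms, ModelParameters,
                    eval_rhs_abstract, finite_difference_jacobian,
                    jacobian_gbm, rhs_gbm_array, spectral_label)
from .equilibria import cure_state, cure_state_forms
from . import thresholds as thr

__all__ = [
    "DissipativityConstants",
    "jacobian_at",
    "jacobian_at_forms",
    "cure_eigenvalues",
    "cure_eigenvalues_closed_form",
    "is_cure_stable",
    "is_cure_stable_forms",
    "cure_decay_rates",
    "cure_decay_rates_forms",
    "dissipativity_constants",
    "verify_global_cure",
]


def jacobian_at(state, params: ModelParameters,
                analytic: bool = False) -> np.ndarray:
    """7x7 Jacobian of the concrete RHS.

    Central finite differences with per-component relative step 1e-6
    (absolute floor 1e-8) by default; ``analytic=True`` selects the
    hand-derived Jacobian (the two must agree — tested).
    """
    if analytic:
        return jacobian_gbm(state, params)
    y = np.asarray(state if not hasattr(state, "as_array")
                   else state.as_array(), dtype=float)
    if not np.all(np.isfinite(y)):
        raise DomainError("state contains non-finite components")
    return finite_difference_jacobian(lambda z: rhs_gbm_array(z, params), y)


def jacobian_at_forms(state, forms: FunctionalForms,
                      mu: DeathRates) -> np.ndarray:
    """Finite-difference Jacobian of an abstract bundle's RHS."""
    y = np.asarray(state if not hasattr(state, "as_array")
                   else state.as_array(), dtype=float)
    return finite_difference_jacobian(
        lambda z: eval_rhs_abstract(z, forms, mu), y)


def cure_eigenvalues(params: ModelParameters,
                     N: float | None = None) -> np.ndarray:
    """Numerical spectrum of the Jacobian at the cure state, sorted by
    real part (ascending)."""
    p = params if N is None else params.replace(N=N)
    eig = np.linalg.eigvals(jacobian_gbm(cure_state(p), p))
    return eig[np.argsort(eig.real)]


def cure_eigenvalues_closed_form(forms: FunctionalForms, mu: DeathRates
                                 ) -> np.ndarray:
    """Closed-form cure-state spectrum of an abstract bundle.

    ``{-muC, -mux, -muy, -muu, -muv, R2(0) - C* fS(x*) gS(u*) hS(0),
    R1(0) - C* fT(x*) gT(u*) hT(0)}`` with the steady chain
    ``C* = N/muC``, ``x* = fx(0)/mux``, ``u* = fu(fy(C*)/muy)/muu``.
    For bundles with ``hT(0) = hS(0) = 1`` this is the plain abstract
    result; the concrete instantiation's ``hT(0) = 1/hT`` saturation
    factor enters automatically.
    """
    C = forms.N_const / mu.muC
    x = forms.fx(0.0) / mu.mux
    u = forms.fu(forms.fy(C) / mu.muy) / mu.muu
    lam_T = float(forms.R1(0.0)) - C * forms.fT(x) * forms.gT(u) * forms.hT(0.0)
    lam_S = float(forms.R2(0.0)) - C * forms.fS(x) * forms.gS(u) * forms.hS(0.0)
    eig = np.array([-mu.muC, -mu.mux, -mu.muy, -mu.muu, -mu.muv,
                    lam_S, lam_T], dtype=complex)
    return eig[np.argsort(eig.real)]


def is_cure_stable(params: ModelParameters, N: float | None = None,
                   tol: float = 1e-12) -> tuple[bool, float]:
    """Local asymptotic stability of the concrete cure state.

    Uses the maximal real part of the cure-state spectrum; the margin is
    its negation (positive margin = stable, in 1/h).  Within ``tol``
    times the spectral radius of zero the verdict is False with zero
    margin (marginal case).
    """
    eig = cure_eigenvalues(params, N)
    top = float(np.max(eig.real))
    rad = float(np.max(np.abs(eig)))
    if abs(top) <= tol * max(rad, 1e-300):
        return False, 0.0
    return top < 0, -top


def is_cure_stable_forms(forms: FunctionalForms, mu: DeathRates
                         ) -> tuple[bool, float]:
    """Abstract-mode verdict from the two closed-form inequalities
    ``N > r_i muC / (f_i(x*) g_i(u*) h_i(0))``; the margin is the
    negated largest cancer-compartment eigenvalue (1/h)."""
    eig = cure_eigenvalues_closed_form(forms, mu)
    top = float(np.max(eig.real))
    return top < 0, -top


def cure_decay_rates(params: ModelParameters,
                     N: float | None = None) -> tuple[float, float]:
    """Exponential decay certificates ``(a1, a2)`` for the concrete
    model; positive values certify ``T(t) <= T(0) e^{-a1 t}`` (likewise
    S) from suitable initial conditions.

    ``a1 = gT(u*) C* - (r1 + ralpha K1^2/4) / (hT(K1) fT(x_max))`` with
    ``x_max`` the maximal quasi-steady TGF-beta level, and the analogous
    ``a2`` without the differentiation influx.  The concrete kill
    saturation means ``hT(K1) = 1/(hT + K1)``.

    ``a1`` and ``a2`` are quoted on the scale in which they are derived:
    the per-capita decay rate they certify (once the immune state has
    reached its treated steady level) is ``hT(K1) fT(x_max) a1`` for T
    and ``hS(K2) fS(x_max) a2`` for S, in 1/h.
    """
    p = params if N is None else params.replace(N=N)
    st = cure_state(p)
    C = st.C
    u = st.MI
    x_max = (p.gbeta + p.abetaT * p.K1 + p.abetaS * p.K2) / p.mubeta
    gT_u = p.aT * u / (u + p.eT)
    gS_u = p.aS * u / (u + p.eS)
    # concrete kill saturation: hT(K1) = 1/(hT + K1), hS(K2) = 1/(hS + K2)
    a1 = gT_u * C - (p.r1 + p.ralpha * p.K1 ** 2 / 4.0) \
        * (p.hT + p.K1) / float(thr.fbarT(x_max, p))
    a2 = gS_u * C - p.r2 * (p.hS + p.K2) / float(thr.fbarS(x_max, p))
    return float(a1), float(a2)


def cure_decay_rates_forms(forms: FunctionalForms, mu: DeathRates,
                           r1: float, r2: float, ralpha: float,
                           K1: float, K2: float) -> tuple[float, float]:
    """Abstract-bundle decay certificates; the structural constants of
    the growth terms must be supplied explicitly."""
    C = forms.N_const / mu.muC
    u = forms.fu(forms.fy(C) / mu.muy) / mu.muu
    x_max = forms.fx(K1 + K2) / mu.mux
    a1 = forms.gT(u) * C \
        - (r1 + ralpha * K1 ** 2 / 4.0) / (forms.hT(K1) * forms.fT(x_max))
    a2 = forms.gS(u) * C - r2 / (forms.hS(K2) * forms.fS(x_max))
    return float(a1), float(a2)


@dataclass(frozen=True)
class DissipativityConstants:
    """Constants of the linear absorbing bound ``dW/dt <= A - delta W``
    for the state sum ``W = T+S+C+Fbeta+Fgamma+MI+MII``."""

    a1: float       # R1(T) T <= a1 - b1 T on [0, K1]
    b1: float
    a2: float       # R2(S) S <= a2 - b2 S on [0, K2]
    b2: float
    c_max: float    # supremum of the CTL recruitment term
    fbar_x: float   # supremum of TGF-beta production
    fbar_y: float   # supremum of IFN-gamma production
    fbar_u: float   # supremum of MHC-I production
    fbar_v: float   # supremum of MHC-II production
    A: float        # aggregate inflow (units of W per hour)
    delta: float    # uniform decay rate (1/h)


def dissipativity_constants(params: ModelParameters,
                            C0: float = 0.0) -> DissipativityConstants:
    """Dissipativity constants of the concrete system.

    ``b1 = r1, a1 = r1 K1`` (valid since ``r1 T (1 - T/K1) <= r1 K1 -
    r1 T`` is ``(T - K1)^2 >= 0``), analogously for S.  The concrete
    recruitment term is identically zero, so ``c_max = 0`` and the CTL
    ceiling is ``max(N/muC, C0)``; pass the initial CTL load ``C0`` when
    bounding a specific trajectory.
    """
    p = params
    a1, b1 = p.r1 * p.K1, p.r1
    a2, b2 = p.r2 * p.K2, p.r2
    c_max = 0.0
    C_ceil = max((c_max + p.N) / p.muC, float(C0))
    fbar_x = p.gbeta + p.abetaT * p.K1 + p.abetaS * p.K2
    fbar_y = p.agammaC * C_ceil
    fbar_u = p.gMI + p.aMIgamma
    fbar_v = p.aMIIgamma
    delta = min(b1, b2, p.muC, p.mubeta, p.mugamma, p.muMI, p.muMII)
    A = a1 + a2 + c_max + p.N + fbar_x + fbar_y + fbar_u + fbar_v
    return DissipativityConstants(a1=a1, b1=b1, a2=a2, b2=b2, c_max=c_max,
                                  fbar_x=fbar_x, fbar_y=fbar_y,
                                  fbar_u=fbar_u, fbar_v=fbar_v,
                                  A=A, delta=delta)


def verify_global_cure(params: ModelParameters, N: float,
                       grid: int = 256, mode: str = "paper") -> bool:
    """Sufficient global-cure certificate on a grid.

    True iff ``L1(T,S) + ralpha K1 < 0`` and ``L2(T,S) < 0`` everywhere
    on ``[0, K1] x [0, K2]`` — then the comparison system has no
    equilibrium but the origin and the cure state attracts globally.
    """
    if grid < 128:
        raise DomainError("grid must be >= 128")
    p = params
    Tg = np.linspace(0.0, p.K1, grid)
    Sg = np.linspace(0.0, p.K2, grid)
    TT, SS = np.meshgrid(Tg, Sg, indexing="ij")
    l1 = np.asarray(thr.L1(TT, SS, p, N, mode)) + p.ralpha * p.K1
    l2 = np.asarray(thr.L2(TT, SS, p, N, mode))
    return bool(np.all(l1 < 0.0) and np.all(l2 < 0.0))
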