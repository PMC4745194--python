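"""Equilibria of the full and reduced systems.

Three families of steady states are located:

* the **cure** state (no tumor cells, no stem cells) — explicit from the
  cytokine/receptor cascade at the steady CTL level ``C* = N/muC``;
* **recurrence** states of the reduced stem-only flow ``S' = S L_N(S)``
  — roots of ``L_N`` on ``(0, K2]``, classified by the direction of the
  sign crossing (an equilibrium is stable when ``L_N`` falls through
  zero);
* **coexistence** states of the reduced two-compartment flow
  ``T' = T M1(T,S)``, ``S' = S M2(T,S)`` — simultaneous zeros of
  ``M1`` and ``M2`` found by a 2-D grid sign scan refined with a root
  polish, classified by the 2x2 Jacobian and by the odd/even crossing
  parity along the nullclines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, root

from .exceptions import DomainError, RootNotFoundError
from .model import (DeathRates, FunctionalForms, ModelParameters, SystemState,
                    eval_rhs_gbm, jacobian_gbm, kronik_forms, spectral_label)
from . import thresholds as thr

__all__ = [
    "EquilibriumPoint",
    "RecurrenceRoot",
    "CoexistencePoint",
    "cure_state",
    "cure_state_forms",
    "cure_equilibrium",
    "solve_recruitment_C",
    "recurrence_L",
    "recurrence_equilibria",
    "coexistence_M",
    "coexistence_equilibria",
]


@dataclass(frozen=True)
class EquilibriumPoint:
    """A steady state with its residual, spectrum, and stability label."""

    state: SystemState
    residual: float          # max-norm of the RHS at the state
    eigenvalues: np.ndarray  # 7 complex values
    label: str               # stable / unstable / marginal


@dataclass(frozen=True)
class RecurrenceRoot:
    """A stem-only steady state of the reduced recurrence flow."""

    S: float
    label: str               # stable / unstable / marginal
    residual: float          # |L_N(S)|


@dataclass(frozen=True)
class CoexistencePoint:
    """A coexistence steady state of the reduced two-compartment flow."""

    T: float
    S: float
    label: str               # Jacobian-based stability of (T M1, S M2)
    residual: float          # max(|M1|, |M2|)
    parity_index: tuple[int, int]  # (j, i): crossing indices along T and S
    parity_label: str        # stable when both indices odd, else unstable


# ---------------------------------------------------------------------------
# Cure state
# ---------------------------------------------------------------------------

def cure_state(params: ModelParameters) -> SystemState:
    """Tumor-free steady state of the concrete system.

    All levels follow from the CTL balance ``C* = N/muC`` through the
    cytokine/receptor cascade; the stem/tumor compartments are zero.
    """
    p = params
    C = p.N / p.muC
    Fb = p.gbeta / p.mubeta
    Fg = p.agammaC * C / p.mugamma
    MI = (p.gMI + p.aMIgamma * Fg / (Fg + p.eMIgamma)) / p.muMI
    MII = (p.aMIIgamma * Fg / (Fg + p.eMIIgamma)) \
        * (p.aMIIbeta + p.eMIIbeta * (1.0 - p.aMIIbeta) / (Fb + p.eMIIbeta)) \
        / p.muMII
    return SystemState(T=0.0, S=0.0, C=C, Fbeta=Fb, Fgamma=Fg, MI=MI, MII=MII)


def cure_state_forms(forms: FunctionalForms, mu: DeathRates) -> np.ndarray:
    """Tumor-free steady state of an abstract bundle (array in state
    order), using the full steady-state chain C* -> y* -> u* and
    v* = fv(x*) gv(y*)/muv."""
    C = forms.N_const / mu.muC
    x = forms.fx(0.0) / mu.mux
    y = forms.fy(C) / mu.muy
    u = forms.fu(y) / mu.muu
    v = forms.fv(x) * forms.gv(y) / mu.muv
    return np.array([0.0, 0.0, C, x, y, u, v])


def cure_equilibrium(params: ModelParameters) -> EquilibriumPoint:
    """Cure state with residual, eigenvalues, and stability label."""
    st = cure_state(params)
    rhs = eval_rhs_gbm(st, params)
    eig = np.linalg.eigvals(jacobian_gbm(st, params))
    return EquilibriumPoint(state=st, residual=float(np.max(np.abs(rhs))),
                            eigenvalues=eig, label=spectral_label(eig))


# ---------------------------------------------------------------------------
# CTL recruitment balance
# ---------------------------------------------------------------------------

def solve_recruitment_C(T: float, S: float,
                        params: ModelParameters | None = None,
                        forms: FunctionalForms | None = None,
                        mu: DeathRates | None = None,
                        N: float | None = None,
                        hi_cap: float = 1e30) -> float:
    """Unique positive CTL level balancing recruitment, death, and inflow
    at fixed tumor burden (T, S).

    Solves ``H(C) = fC((T+S) v*(C)) gC(x_p) - muC C + N = 0`` with the
    MHC-II level slaved to C through the cytokine chain.  ``H`` is
    strictly decreasing with ``H(0) = N > 0``, so bracketed bisection
    after bracket doubling finds the single root.
    """
    if params is not None:
        forms = kronik_forms(params)
        mu = DeathRates(params.muC, params.mubeta, params.mugamma,
                        params.muMI, params.muMII)
    if forms is None or mu is None:
        raise DomainError("provide either params or (forms, mu)")
    if N is None:
        N = forms.N_const
    x_p = forms.fx(T + S) / mu.mux
    gC_x = forms.gC(x_p)
    fv_x = forms.fv(x_p)

    def H(C: float) -> float:
        v = fv_x * forms.gv(forms.fy(C) / mu.muy) / mu.muv
        return forms.fC((T + S) * v) * gC_x - mu.muC * C + N

    h0 = H(0.0)
    if h0 < 0:
        raise DomainError("H(0) < 0: no positive recruitment balance")
    if h0 == 0.0:
        raise DomainError(
            "H(0) = 0: need N > 0 or a non-trivial recruitment function")
    hi = 1.0
    while H(hi) > 0:
        hi *= 2.0
        if hi > hi_cap:
            raise RootNotFoundError(
                f"no sign change of H up to C = {hi_cap:g}")
    return float(brentq(H, 0.0, hi, xtol=1e-300, rtol=1e-14, maxiter=500))


# ---------------------------------------------------------------------------
# Recurrence states (stem-only reduced flow)
# ---------------------------------------------------------------------------

def recurrence_L(params: ModelParameters, N: float, mode: str = "paper"):
    """Vectorized ``L_N(S) = R2(S) - G2(N) fbarS(0,S)/(hS+S)``."""
    return lambda S: thr.L2(0.0, S, params, N, mode)


def recurrence_equilibria(params: ModelParameters, N: float,
                          mode: str = "paper",
                          n_scan: int = 10_000) -> list[RecurrenceRoot]:
    """All roots of ``L_N`` on ``(0, K2]`` by sign scan + bisection.

    A root where ``L_N`` crosses from positive to negative attracts the
    stem flow (stable); the reverse crossing repels; a touch without a
    sign change is reported as marginal.  An empty list is a valid
    result (treatment above the recurrence threshold).
    """
    p = params
    L = recurrence_L(p, N, mode)
    grid = np.linspace(0.0, p.K2, n_scan + 1)
    vals = np.asarray(L(grid), dtype=float)
    roots: list[float] = []
    for i in range(n_scan):
        a, b = grid[i], grid[i + 1]
        va, vb = vals[i], vals[i + 1]
        if va == 0.0 and a > 0.0:
            roots.append(float(a))
        elif va * vb < 0.0:
            roots.append(float(brentq(lambda s: float(L(s)), a, b,
                                      xtol=1e-300, rtol=1e-14, maxiter=200)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    roots = sorted(set(roots))

    out: list[RecurrenceRoot] = []
    eps = p.K2 * 1e-9
    for s in roots:
        left = float(L(max(s - eps, 0.0)))
        if s >= p.K2 - eps:  # boundary root: classify from the left side
            label = "stable" if left > 0 else ("unstable" if left < 0
                                               else "marginal")
        else:
            right = float(L(s + eps))
            if left > 0 and right < 0:
                label = "stable"
            elif left < 0 and right > 0:
                label = "unstable"
            else:
                label = "marginal"
        out.append(RecurrenceRoot(S=s, label=label,
                                  residual=abs(float(L(s)))))
    return out


# ---------------------------------------------------------------------------
# Coexistence states (two-compartment reduced flow)
# ---------------------------------------------------------------------------

def coexistence_M(params: ModelParameters, N: float, mode: str = "paper"):
    """Vectorized per-capita rates ``(M1, M2)`` of the reduced flow
    ``T' = T M1``, ``S' = S M2``."""
    p = params

    def M1(T, S):
        return thr.L1(T, S, p, N, mode) \
            + p.ralpha * (np.asarray(S, float) / p.K2) \
            * (p.K1 - np.asarray(T, float)) / p.K1

    def M2(T, S):
        return thr.L2(T, S, p, N, mode) \
            - p.ralpha * (np.asarray(T, float) / p.K2) \
            * (p.K1 - np.asarray(T, float)) / p.K1

    return M1, M2


def _parity_index(fun, coord: float, lo: float, hi: float,
                  n: int = 2048) -> int:
    """1-based index of ``coord`` among the roots of ``fun`` on (lo, hi]."""
    grid = np.linspace(lo, hi, n + 1)
    vals = np.asarray(fun(grid), dtype=float)
    roots = []
    for i in range(n):
        if vals[i] == 0.0 and grid[i] > lo:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0.0:
            roots.append(brentq(lambda z: float(fun(z)), grid[i], grid[i + 1],
                                rtol=1e-12, maxiter=200))
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    roots = sorted(set(roots))
    if not roots:
        return 1
    return 1 + int(np.argmin([abs(r - coord) for r in roots]))


def coexistence_equilibria(params: ModelParameters, N: float,
                           mode: str = "paper", grid: int = 512,
                           residual_tol: float = 1e-8
                           ) -> list[CoexistencePoint]:
    """Simultaneous zeros of ``M1`` and ``M2`` on ``(0, K1] x (0, K2]``.

    A ``grid x grid`` sign scan selects cells where both rates change
    sign (or vanish on a corner); each candidate is polished with a
    damped Newton solve in capacity-scaled coordinates and kept when the
    residual contract ``max(|M1|, |M2|) <= residual_tol`` holds.
    Stability comes from the 2x2 Jacobian of ``(T M1, S M2)``; the
    odd/even crossing parity along the two nullcline sections through
    the point is reported alongside.
    """
    if grid < 100:
        raise DomainError("grid resolution must be >= 100")
    p = params
    M1, M2 = coexistence_M(p, N, mode)
    Tg = np.linspace(0.0, p.K1, grid + 1)
    Sg = np.linspace(0.0, p.K2, grid + 1)
    TT, SS = np.meshgrid(Tg, Sg, indexing="ij")
    V1 = np.asarray(M1(TT, SS), dtype=float)
    V2 = np.asarray(M2(TT, SS), dtype=float)

    def spans_zero(block):
        return (block.min() <= 0.0) and (block.max() >= 0.0) \
            and not (block.min() == 0.0 and block.max() == 0.0)

    candidates: list[tuple[float, float]] = []
    c1 = np.minimum.reduce([V1[:-1, :-1], V1[1:, :-1], V1[:-1, 1:], V1[1:, 1:]])
    C1 = np.maximum.reduce([V1[:-1, :-1], V1[1:, :-1], V1[:-1, 1:], V1[1:, 1:]])
    c2 = np.minimum.reduce([V2[:-1, :-1], V2[1:, :-1], V2[:-1, 1:], V2[1:, 1:]])
    C2 = np.maximum.reduce([V2[:-1, :-1], V2[1:, :-1], V2[:-1, 1:], V2[1:, 1:]])
    mask = (c1 <= 0) & (C1 >= 0) & (c2 <= 0) & (C2 >= 0) \
        & ~((c1 == 0) & (C1 == 0)) & ~((c2 == 0) & (C2 == 0))
    ii, jj = np.nonzero(mask)
    for i, j in zip(ii, jj):
        candidates.append((0.5 * (Tg[i] + Tg[i + 1]),
                           0.5 * (Sg[j] + Sg[j + 1])))
    # grid nodes that are exact simultaneous zeros (e.g. the (K1, K2)
    # corner of the untreated system)
    node = (np.abs(V1) == 0.0) & (np.abs(V2) == 0.0)
    for i, j in zip(*np.nonzero(node)):
        if Tg[i] > 0 and Sg[j] > 0:
            candidates.append((float(Tg[i]), float(Sg[j])))

    def fun_scaled(z):
        T, S = z[0] * p.K1, z[1] * p.K2
        return [float(M1(T, S)), float(M2(T, S))]

    found: list[tuple[float, float]] = []
    for T0, S0 in candidates:
        res0 = max(abs(float(M1(T0, S0))), abs(float(M2(T0, S0))))
        if res0 <= 1e-14:
            Tr, Sr = T0, S0
        else:
            sol = root(fun_scaled, x0=[T0 / p.K1, S0 / p.K2], method="hybr",
                       options={"xtol": 1e-13})
            if not sol.success:
                continue
            Tr, Sr = float(sol.x[0]) * p.K1, float(sol.x[1]) * p.K2
        if not (0.0 < Tr <= p.K1 * (1 + 1e-9) and
                0.0 < Sr <= p.K2 * (1 + 1e-9)):
            continue
        Tr, Sr = min(Tr, p.K1), min(Sr, p.K2)
        if max(abs(float(M1(Tr, Sr))), abs(float(M2(Tr, Sr)))) > residual_tol:
            continue
        if any(abs(Tr - a) <= 1e-6 * p.K1 and abs(Sr - b) <= 1e-6 * p.K2
               for a, b in found):
            continue
        found.append((Tr, Sr))

    out: list[CoexistencePoint] = []
    for Tr, Sr in sorted(found):
        J = _reduced_jacobian(M1, M2, Tr, Sr, p)
        eig = np.linalg.eigvals(J)
        j_idx = _parity_index(lambda t: M1(t, Sr), Tr, 0.0, p.K1)
        i_idx = _parity_index(lambda s: M2(Tr, s), Sr, 0.0, p.K2)
        parity = "stable" if (j_idx % 2 == 1 and i_idx % 2 == 1) \
            else "unstable"
        out.append(CoexistencePoint(
            T=Tr, S=Sr, label=spectral_label(eig),
            residual=max(abs(float(M1(Tr, Sr))), abs(float(M2(Tr, Sr)))),
            parity_index=(j_idx, i_idx), parity_label=parity))
    return out


def _reduced_jacobian(M1, M2, T: float, S: float,
                      p: ModelParameters) -> np.ndarray:
    """Central-difference 2x2 Jacobian of (T M1, S M2)."""
    def F(z):
        return np.array([z[0] * float(M1(z[0], z[1])),
                         z[1] * float(M2(z[0], z[1]))])

    J = np.zeros((2, 2))
    z0 = np.array([T, S])
    for k, scale in enumerate((p.K1, p.K2)):
        h = max(1e-7 * abs(z0[k]), 1e-9 * scale)
        zp, zm = z0.copy(), z0.copy()
        zp[k] += h
        zm[k] -= h
        J[:, k] = (F(zp) - F(zm)) / (2.0 * h)
    return J
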