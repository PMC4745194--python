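"""Treatment-threshold calculus.

For a constant CTL infusion rate ``N`` the long-run per-capita kill
pressure on tumor cells and stem cells is summarised by two strictly
increasing maps ``G1(N)`` and ``G2(N)`` (kill activation at the steady
CTL level ``C* = N/muC``).  From them the module computes, per
compartment:

* ``N_min``  — the dose below which the compartment cannot be eliminated
  even locally (the cure state has a positive eigenvalue);
* ``aleph``  — the dimensionless amplification needed to pass from local
  to global elimination (the worst-case ratio of growth to kill pressure
  over the whole population range);
* ``N_thr = G^{-1}(G(N_min) * aleph)`` — a sufficient dose for global
  elimination of the compartment;
* ``N_cure = max(N_thr_T, N_thr_S)`` — a sufficient dose for a globally
  asymptotically stable cure state.

Two computation modes are exposed.  Mode ``"paper"`` builds ``G1/G2``
from the MHC-I *production* rate ``X(N) = gMI + aMIgamma*Fgamma*/(Fgamma*
+ eMIgamma)`` and uses the stem-side maximand ``R2(S)*S*(hS+S)/fbarS`` —
the published worked example's reading, which reproduces its printed
numbers.  Mode ``"consistent"`` uses the MHC-I *steady state*
``MI* = X/muMI`` (the kill coefficient the simulated dynamics actually
see) and the literal stem-side maximand without the extra factor of
``S``.  The default everywhere is ``"paper"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .exceptions import DomainError, InversionError
from .model import ModelParameters

__all__ = [
    "ThresholdReport",
    "G1",
    "G2",
    "mi_production",
    "fbarT",
    "fbarS",
    "tgfb_level",
    "L1",
    "L2",
    "invert_monotone",
    "compute_thresholds",
    "recurrence_thresholds",
]

MODES = ("paper", "consistent")


def _check_mode(mode: str) -> None:
    if mode not in MODES:
        raise DomainError(f"mode must be one of {MODES}, got {mode!r}")


def mi_production(N, params: ModelParameters):
    """MHC-I production rate ``X(N)`` at the steady CTL/IFN-gamma levels
    induced by infusion ``N`` (rec/cell/h)."""
    p = params
    Fg = p.agammaC * np.asarray(N, dtype=float) / (p.mugamma * p.muC)
    return p.gMI + p.aMIgamma * Fg / (Fg + p.eMIgamma)


def G1(N, params: ModelParameters, mode: str = "paper"):
    """Kill pressure on the tumor-cell compartment (cells/h scale),
    strictly increasing in ``N``.  Accepts scalars or arrays."""
    _check_mode(mode)
    p = params
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise DomainError("treatment rate N must be >= 0")
    X = mi_production(N, p)
    drive = X if mode == "paper" else X / p.muMI
    return (p.aT * drive / (drive + p.eT)) * N / p.muC


def G2(N, params: ModelParameters, mode: str = "paper"):
    """Kill pressure on the stem-cell compartment; see :func:`G1`."""
    _check_mode(mode)
    p = params
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise DomainError("treatment rate N must be >= 0")
    X = mi_production(N, p)
    drive = X if mode == "paper" else X / p.muMI
    return (p.aS * drive / (drive + p.eS)) * N / p.muC


def tgfb_level(T, S, params: ModelParameters):
    """Quasi-steady TGF-beta at tumor burden (T, S)."""
    p = params
    return (p.gbeta + p.abetaT * np.asarray(T, dtype=float)
            + p.abetaS * np.asarray(S, dtype=float)) / p.mubeta


def fbarT(x, params: ModelParameters):
    """TGF-beta kill-suppression factor on T, evaluated at cytokine level x."""
    p = params
    return p.aTbeta + p.eTbeta * (1.0 - p.aTbeta) / (np.asarray(x, float)
                                                     + p.eTbeta)


def fbarS(x, params: ModelParameters):
    p = params
    return p.aSbeta + p.eSbeta * (1.0 - p.aSbeta) / (np.asarray(x, float)
                                                     + p.eSbeta)


def L1(T, S, params: ModelParameters, N: float, mode: str = "paper"):
    """Net per-capita growth of T in the reduced flow, before the
    stem->tumor influx: ``R1(T) - G1(N) * H1(T,S)`` with
    ``H1 = fbarT/(hT+T)``."""
    p = params
    T = np.asarray(T, dtype=float)
    H1 = fbarT(tgfb_level(T, S, p), p) / (p.hT + T)
    return p.r1 * (1.0 - T / p.K1) - G1(N, p, mode) * H1


def L2(T, S, params: ModelParameters, N: float, mode: str = "paper"):
    """Net per-capita growth of S before the differentiation drain:
    ``R2(S) - G2(N) * H2(T,S)`` with ``H2 = fbarS/(hS+S)``."""
    p = params
    S = np.asarray(S, dtype=float)
    H2 = fbarS(tgfb_level(T, S, p), p) / (p.hS + S)
    return p.r2 * (1.0 - S / p.K2) - G2(N, p, mode) * H2


def invert_monotone(g: Callable[[float], float], target: float,
                    lo: float = 0.0, hi: float = 1.0,
                    rtol: float = 1e-12, hi_cap: float = 1e30) -> float:
    """Invert a strictly increasing map by bracket doubling + bisection.

    Raises :class:`InversionError` when ``target < g(lo)`` or the bracket
    overflows ``hi_cap`` without covering the target.
    """
    g_lo = g(lo)
    if target < g_lo:
        raise InversionError(
            f"target {target!r} lies below g({lo!r}) = {g_lo!r}")
    if target == g_lo:
        return lo
    while g(hi) < target:
        hi *= 2.0
        if hi > hi_cap:
            raise InversionError(
                f"bracket exceeded {hi_cap:g} without covering target")
    root = brentq(lambda n: g(n) - target, lo, hi,
                  xtol=1e-300, rtol=max(rtol, 1e-15), maxiter=500)
    return float(root)


def _maximize(f: Callable[[np.ndarray], np.ndarray], lo: float, hi: float,
              n_grid: int = 100_001, rtol: float = 1e-10) -> tuple[float, float]:
    """Maximum of ``f`` on ``[lo, hi]`` by dense grid + golden-section
    refinement around the grid argmax.  Returns ``(argmax, max)``."""
    grid = np.linspace(lo, hi, n_grid)
    vals = np.asarray(f(grid), dtype=float)
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, n_grid - 1)]
    best_x, best_v = float(grid[i]), float(vals[i])
    if b > a:
        res = minimize_scalar(lambda x: -float(f(np.asarray(x))),
                              bounds=(a, b), method="bounded",
                              options={"xatol": rtol * max(abs(hi), 1.0)})
        if res.success and -res.fun > best_v:
            best_x, best_v = float(res.x), float(-res.fun)
    return best_x, best_v


@dataclass(frozen=True)
class ThresholdReport:
    """Sufficient treatment doses (cells/h) and amplification factors
    (dimensionless) for the coexistence system, plus the recurrence
    submodel's pair, and the computation mode used."""

    Nmin_T: float
    Nmin_S: float
    aleph_T: float
    aleph_S: float
    Nthr_T: float
    Nthr_S: float
    Ncure: float
    recurrence_Nmin: float
    recurrence_Nthr: float
    mode: str

    def to_dict(self) -> dict:
        return {
            "Nmin_T": self.Nmin_T, "Nmin_S": self.Nmin_S,
            "aleph_T": self.aleph_T, "aleph_S": self.aleph_S,
            "Nthr_T": self.Nthr_T, "Nthr_S": self.Nthr_S,
            "Ncure": self.Ncure,
            "recurrence_Nmin": self.recurrence_Nmin,
            "recurrence_Nthr": self.recurrence_Nthr,
            "mode": self.mode,
        }


def compute_thresholds(params: ModelParameters, mode: str = "paper",
                       n_grid: int = 100_001) -> ThresholdReport:
    """Full threshold calculus for the two-compartment (coexistence)
    system, plus the recurrence submodel's pair.

    ``Nmin_T`` inverts ``G1`` at ``r1/fbarT(gbeta/mubeta)``; ``Nmin_S``
    inverts ``G2`` at ``(r2 - ralpha*K1/(4*K2))/fbarS(gbeta/mubeta)``.
    The amplifications maximize the worst-case growth-to-kill ratio over
    the compartment's full range (tumor side against ``S = K2``, stem
    side against ``T = K1``).
    """
    _check_mode(mode)
    p = params
    x0 = p.gbeta / p.mubeta

    g1 = lambda n: float(G1(n, p, mode))
    g2 = lambda n: float(G2(n, p, mode))

    G1_min = p.r1 / float(fbarT(x0, p))
    Nmin_T = invert_monotone(g1, G1_min)
    target_S = (p.r2 - p.ralpha * p.K1 / (4.0 * p.K2)) / float(fbarS(x0, p))
    if target_S < 0:
        raise DomainError(
            "stem-side inversion target is negative: differentiation drain "
            "exceeds stem growth (r2 < ralpha*K1/(4*K2))")
    G2_min = target_S
    Nmin_S = invert_monotone(g2, G2_min)

    def aleph_T_maximand(T):
        T = np.asarray(T, dtype=float)
        num = (p.r1 * (1.0 - T / p.K1) + p.ralpha * p.K1) * (p.hT + T)
        den = G1_min * fbarT(tgfb_level(T, p.K2, p), p)
        return num / den

    _, aleph_T = _maximize(aleph_T_maximand, 0.0, p.K1, n_grid)

    def aleph_S_maximand(S):
        S = np.asarray(S, dtype=float)
        num = p.r2 * (1.0 - S / p.K2) * (p.hS + S)
        if mode == "paper":
            num = num * S
        den = G2_min * fbarS(tgfb_level(p.K1, S, p), p)
        return num / den

    _, aleph_S = _maximize(aleph_S_maximand, 0.0, p.K2, n_grid)

    Nthr_T = invert_monotone(g1, G1_min * aleph_T)
    Nthr_S = invert_monotone(g2, G2_min * aleph_S)
    rec_Nmin, rec_Nthr = recurrence_thresholds(p, mode, n_grid)

    return ThresholdReport(
        Nmin_T=Nmin_T, Nmin_S=Nmin_S, aleph_T=aleph_T, aleph_S=aleph_S,
        Nthr_T=Nthr_T, Nthr_S=Nthr_S, Ncure=max(Nthr_T, Nthr_S),
        recurrence_Nmin=rec_Nmin, recurrence_Nthr=rec_Nthr, mode=mode)


def recurrence_thresholds(params: ModelParameters, mode: str = "paper",
                          n_grid: int = 100_001) -> tuple[float, float]:
    """(N_min, N_thr) for the recurrence submodel (tumor cells absent,
    only the stem compartment persists).

    ``N_min = G2^{-1}(r2/fbarS(gbeta/mubeta))``; the amplification is the
    maximum of ``R2(S)/(G2(N_min) H(S))`` with ``H(S) = fbarS(0,S)/(hS+S)``.
    """
    _check_mode(mode)
    p = params
    x0 = p.gbeta / p.mubeta
    g2 = lambda n: float(G2(n, p, mode))
    G_min = p.r2 / float(fbarS(x0, p))
    Nmin = invert_monotone(g2, G_min)

    def maximand(S):
        S = np.asarray(S, dtype=float)
        num = p.r2 * (1.0 - S / p.K2) * (p.hS + S)
        den = G_min * fbarS(tgfb_level(0.0, S, p), p)
        return num / den

    _, aleph = _maximize(maximand, 0.0, p.K2, n_grid)
    Nthr = invert_monotone(g2, G_min * aleph)
    return Nmin, Nthr
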