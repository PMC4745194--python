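"""Core model: parameters, state, and right-hand sides.

The model couples seven populations in a glioblastoma under cytotoxic-T-
lymphocyte (CTL) immunotherapy:

* ``T``   differentiated (non-stem) tumor cells, logistic growth to ``K1``,
  replenished by stem cells and killed by CTLs;
* ``S``   cancer stem cells, logistic growth to ``K2``; as the stem pool
  fills, stem divisions are diverted into producing tumor cells (the
  ``alpha`` coupling);
* ``C``   alloreactive CTLs, infused at constant rate ``N`` and dying at
  rate ``muC``;
* ``Fbeta``  TGF-beta, an immunosuppressive cytokine with basal production
  ``gbeta`` plus tumor-proportional production;
* ``Fgamma`` IFN-gamma, secreted by CTLs;
* ``MI``, ``MII``  MHC class I / II receptor densities per tumor cell,
  which gate CTL killing and recruitment.

Two right-hand sides are provided: :func:`eval_rhs_gbm` is the concrete
glioblastoma instantiation (saturating Michaelis-Menten kill terms,
TGF-beta-modulated kill efficiency), and :func:`eval_rhs_abstract`
evaluates the abstract system in which every interaction is a pluggable
function (:class:`FunctionalForms`).  ``kronik_forms`` builds the bundle
that reproduces the concrete system term for term, so the two routes can
be cross-checked numerically.

Time is measured in hours throughout; populations in cells, cytokines in
pg, receptor densities in receptors per cell.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .exceptions import ConfigurationError, DomainError

__all__ = [
    "ModelParameters",
    "SystemState",
    "DeathRates",
    "FunctionalForms",
    "STATE_VARS",
    "kronik_forms",
    "death_rates",
    "random_a2_forms",
    "eval_rhs_gbm",
    "eval_rhs_abstract",
    "eval_rhs_reduced",
    "tgfb_qss",
    "jacobian_gbm",
    "finite_difference_jacobian",
    "spectral_label",
]

#: Order of the state variables everywhere an array is used.
STATE_VARS = ("T", "S", "C", "Fbeta", "Fgamma", "MI", "MII")

# Fields that must be strictly positive (carrying capacities and death rates).
_STRICT_POSITIVE = ("K1", "K2", "muC", "mubeta", "mugamma", "muMI", "muMII")
# Dimensionless suppression floors, constrained to [0, 1].
_UNIT_INTERVAL = ("aTbeta", "aSbeta", "aMIIbeta")


@dataclass(frozen=True)
class ModelParameters:
    """Flat immutable record of all model constants plus the treatment rate.

    Defaults are the published glioblastoma parameterisation (rates per
    hour).  ``N`` is the CTL infusion rate in cells/h; ``N = 0`` means no
    immunotherapy.  Derived quantities are never cached here.
    """

    r1: float = 1e-3          # tumor-cell growth rate (1/h)
    K1: float = 1e8           # tumor-cell carrying capacity (cells)
    aT: float = 0.12          # maximal CTL kill rate on T (1/h)
    eT: float = 50.0          # MHC-I half-saturation for killing T (rec/cell)
    aTbeta: float = 0.69      # TGF-beta suppression floor for killing T (-)
    eTbeta: float = 1e4       # TGF-beta scale of kill suppression (pg)
    hT: float = 5e8           # tumor-burden kill saturation for T (cells)
    r2: float = 0.1           # stem-cell growth rate (1/h)
    K2: float = 1e7           # stem-cell carrying capacity (cells)
    ralpha: float = 6e-3      # stem -> tumor differentiation rate (1/h)
    aS: float = 0.012         # maximal CTL kill rate on S (= .1*aT) (1/h)
    eS: float = 50.0          # MHC-I half-saturation for killing S (rec/cell)
    aSbeta: float = 0.69      # TGF-beta suppression floor for killing S (-)
    eSbeta: float = 1e4       # TGF-beta scale for S kill suppression (pg)
    hS: float = 5e8           # tumor-burden kill saturation for S (cells)
    muC: float = 7e-3         # CTL death rate (1/h)
    gbeta: float = 6.3945e4   # basal TGF-beta production (pg/h)
    abetaT: float = 5.75e-6   # TGF-beta production per tumor cell (pg/cell/h)
    abetaS: float = 5.75e-6   # TGF-beta production per stem cell (pg/cell/h)
    mubeta: float = 7.0       # TGF-beta degradation rate (1/h)
    gMI: float = 1.44         # basal MHC-I expression rate (rec/cell/h)
    aMIgamma: float = 2.88    # IFN-gamma-driven MHC-I expression (rec/cell/h)
    eMIgamma: float = 3.38e5  # IFN-gamma half-saturation for MHC-I (pg)
    muMI: float = 0.0144      # MHC-I decay rate (1/h)
    aMIIgamma: float = 8660.0  # IFN-gamma-driven MHC-II expression (rec/cell/h)
    eMIIgamma: float = 1420.0  # IFN-gamma half-saturation for MHC-II (pg)
    aMIIbeta: float = 0.012   # TGF-beta suppression floor for MHC-II (-)
    eMIIbeta: float = 1e5     # TGF-beta scale of MHC-II suppression (pg)
    muMII: float = 0.0144     # MHC-II decay rate (1/h)
    agammaC: float = 1.02e-4  # IFN-gamma secretion per CTL (pg/cell/h)
    mugamma: float = 0.102    # IFN-gamma degradation rate (1/h)
    N: float = 0.0            # CTL infusion rate (cells/h)

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise DomainError(f"parameter {f.name} is not finite: {v!r}")
            if v < 0:
                raise DomainError(f"parameter {f.name} must be >= 0, got {v!r}")
        for name in _STRICT_POSITIVE:
            if getattr(self, name) <= 0:
                raise DomainError(f"parameter {name} must be > 0")
        for name in _UNIT_INTERVAL:
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise DomainError(f"parameter {name} must lie in [0, 1]")

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ModelParameters":
        """Build from a mapping; unknown keys are rejected by name, missing
        keys fall back to the published defaults."""
        known = set(cls.field_names())
        for key in d:
            if key not in known:
                raise ConfigurationError(f"unknown parameter key {key!r}")
        vals = {}
        for key, v in d.items():
            if isinstance(v, bool) or not isinstance(v, (int, float)):
                raise ConfigurationError(
                    f"parameter {key!r} must be numeric, got {v!r}")
            vals[key] = float(v)
        return cls(**vals)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name))
                for f in dataclasses.fields(self)}

    def replace(self, **kw: float) -> "ModelParameters":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class SystemState:
    """A point in the nonnegative orthant of the 7-variable system."""

    T: float
    S: float
    C: float
    Fbeta: float
    Fgamma: float
    MI: float
    MII: float

    def __post_init__(self) -> None:
        for name in STATE_VARS:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise DomainError(f"state component {name} is not finite")
            if v < 0:
                raise DomainError(
                    f"state component {name} must be >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_VARS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SystemState":
        y = np.asarray(y, dtype=float)
        if y.shape != (7,):
            raise DomainError(f"state array must have shape (7,), got {y.shape}")
        return cls(*map(float, y))

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in STATE_VARS}


@dataclass(frozen=True)
class DeathRates:
    """Clearance rates of the abstract system (C, x, y, u, v)."""

    muC: float
    mux: float   # TGF-beta
    muy: float   # IFN-gamma
    muu: float   # MHC-I
    muv: float   # MHC-II

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise DomainError(f"death rate {f.name} must be > 0")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.muC, self.mux, self.muy, self.muu, self.muv)


_FORM_FIELDS = ("alpha", "R1", "R2", "fT", "fS", "gT", "gS", "hT", "hS",
                "fC", "gC", "fx", "fy", "fu", "fv", "gv")


@dataclass(frozen=True)
class FunctionalForms:
    """Pluggable bundle of the sixteen interaction functions of the
    abstract system, plus the constant CTL inflow ``N_const``.

    Each entry is a real-valued map, finite and nonnegative on the
    nonnegative orthant (certified numerically by the assumptions module,
    not enforced here).
    """

    alpha: Callable[[float, float], float]   # stem -> tumor differentiation
    R1: Callable[[float], float]             # per-capita tumor growth
    R2: Callable[[float], float]             # per-capita stem growth
    fT: Callable[[float], float]             # TGF-beta kill suppression on T
    fS: Callable[[float], float]             # TGF-beta kill suppression on S
    gT: Callable[[float], float]             # MHC-I kill activation on T
    gS: Callable[[float], float]             # MHC-I kill activation on S
    hT: Callable[[float], float]             # tumor-burden kill saturation
    hS: Callable[[float], float]             # stem-burden kill saturation
    fC: Callable[[float], float]             # CTL recruitment vs (T+S)*MII
    gC: Callable[[float], float]             # TGF-beta recruitment suppression
    fx: Callable[[float], float]             # TGF-beta production vs T+S
    fy: Callable[[float], float]             # IFN-gamma production vs C
    fu: Callable[[float], float]             # MHC-I production vs IFN-gamma
    fv: Callable[[float], float]             # MHC-II suppression vs TGF-beta
    gv: Callable[[float], float]             # MHC-II activation vs IFN-gamma
    N_const: float = 0.0                     # constant CTL inflow (cells/h)

    def __post_init__(self) -> None:
        for name in _FORM_FIELDS:
            fn = getattr(self, name)
            if not callable(fn):
                raise ConfigurationError(
                    f"functional form {name!r} is missing or not callable")
        if not np.isfinite(self.N_const) or self.N_const < 0:
            raise ConfigurationError("N_const must be finite and >= 0")


def kronik_forms(params: ModelParameters) -> FunctionalForms:
    """The builtin bundle reproducing the concrete glioblastoma system
    term for term.

    Notes
    -----
    * The recruitment function ``fC`` is identically zero: the concrete
      system takes CTL inflow to be the constant ``N`` alone.
    * The kill saturation is ``hT(T) = 1/(hT + T)`` as printed in the
      concrete system, which does *not* satisfy the abstract contract
      ``hT(0) = 1``; the assumptions checker flags this deliberately.
    * ``fx`` takes the single argument ``T + S``, so the bundle requires
      ``abetaS == abetaT`` (as in the published parameter set).
    """
    p = params
    if p.abetaS != p.abetaT:
        raise ConfigurationError(
            "kronik_forms requires abetaS == abetaT (fx depends on T+S only)")
    return FunctionalForms(
        alpha=lambda T, S: p.ralpha * (T / p.K1) * (S / p.K2) * (p.K1 - T),
        R1=lambda T: p.r1 * (1.0 - T / p.K1),
        R2=lambda S: p.r2 * (1.0 - S / p.K2),
        fT=lambda x: p.aTbeta + p.eTbeta * (1.0 - p.aTbeta) / (x + p.eTbeta),
        fS=lambda x: p.aSbeta + p.eSbeta * (1.0 - p.aSbeta) / (x + p.eSbeta),
        gT=lambda u: p.aT * u / (u + p.eT),
        gS=lambda u: p.aS * u / (u + p.eS),
        hT=lambda T: 1.0 / (p.hT + T),
        hS=lambda S: 1.0 / (p.hS + S),
        fC=lambda w: 0.0 * w,
        gC=lambda x: np.ones_like(np.asarray(x, dtype=float))[()],
        fx=lambda w: p.gbeta + p.abetaT * w,
        fy=lambda C: p.agammaC * C,
        fu=lambda y: p.gMI + p.aMIgamma * y / (y + p.eMIgamma),
        fv=lambda x: p.aMIIbeta
        + p.eMIIbeta * (1.0 - p.aMIIbeta) / (x + p.eMIIbeta),
        gv=lambda y: p.aMIIgamma * y / (y + p.eMIIgamma),
        N_const=p.N,
    )


def death_rates(params: ModelParameters) -> DeathRates:
    """Clearance-rate bundle of the concrete system."""
    return DeathRates(muC=params.muC, mux=params.mubeta, muy=params.mugamma,
                      muu=params.muMI, muv=params.muMII)


def random_a2_forms(seed_or_rng, N: float | None = None
                    ) -> tuple[FunctionalForms, DeathRates, dict[str, float]]:
    """Draw a random abstract instantiation satisfying the biological
    assumption list (A2), with ``hT(0) = hS(0) = 1``.

    Used by property tests to cross-check closed-form results (cure-state
    eigenvalues, recruitment roots) against numerics on models that are
    *not* the concrete glioblastoma system.  Returns the bundle, its death
    rates, and a dict of the structural constants (``r1``, ``r2``, ``K1``,
    ``K2``, ``ralpha``, saturation scales).
    """
    rng = np.random.default_rng(seed_or_rng) \
        if not isinstance(seed_or_rng, np.random.Generator) else seed_or_rng

    def logu(lo, hi):
        return float(10.0 ** rng.uniform(np.log10(lo), np.log10(hi)))

    r1 = logu(1e-4, 1e-2)
    r2 = logu(1e-2, 0.5)
    K1 = logu(1e6, 1e9)
    K2 = logu(1e5, 1e8)
    ralpha = logu(1e-4, 1e-2)
    aT = logu(0.01, 1.0)
    aS = aT * rng.uniform(0.05, 0.5)   # keeps gS < gT pointwise
    eu = logu(10.0, 1e3)
    aTx = rng.uniform(0.2, 0.9)        # kill-suppression floors
    aSx = rng.uniform(0.2, 0.9)
    ex = logu(1e3, 1e5)
    hsc1 = K1 * logu(0.05, 5.0)   # tied to capacity so hT(T) -> 0 on-scale
    hsc2 = K2 * logu(0.05, 5.0)
    aC = logu(1.0, 1e3)
    ec = logu(1e6, 1e9)
    bC = rng.uniform(0.1, 0.9)
    egc = logu(1e3, 1e5)
    gx = logu(1e3, 1e5)
    ax = logu(1e-7, 1e-4)
    ay = logu(1e-5, 1e-3)
    gu = logu(0.5, 5.0)
    au = logu(0.5, 5.0)
    eu2 = logu(1e4, 1e6)
    ev = logu(1e4, 1e6)
    av = logu(1e2, 1e4)
    egv = logu(1e2, 1e4)
    if N is None:
        N = logu(1e-2, 1e2)

    forms = FunctionalForms(
        alpha=lambda T, S: ralpha * (S / K2) * (T / K1) * (K1 - T),
        R1=lambda T: r1 * (1.0 - T / K1),
        R2=lambda S: r2 * (1.0 - S / K2),
        fT=lambda x: aTx + (1.0 - aTx) * ex / (x + ex),
        fS=lambda x: aSx + (1.0 - aSx) * ex / (x + ex),
        gT=lambda u: aT * u / (u + eu),
        gS=lambda u: aS * u / (u + eu),
        hT=lambda T: hsc1 / (hsc1 + T),
        hS=lambda S: hsc2 / (hsc2 + S),
        fC=lambda w: aC * w / (w + ec),
        gC=lambda x: bC + (1.0 - bC) * egc / (x + egc),
        fx=lambda w: gx + ax * w,
        fy=lambda C: ay * C,
        fu=lambda y: gu + au * y / (y + eu2),
        fv=lambda x: ev / (ev + x),
        gv=lambda y: av * y / (y + egv),
        N_const=float(N),
    )
    mu = DeathRates(muC=logu(1e-3, 0.1), mux=logu(0.5, 10.0),
                    muy=logu(0.01, 1.0), muu=logu(1e-3, 0.1),
                    muv=logu(1e-3, 0.1))
    meta = dict(r1=r1, r2=r2, K1=K1, K2=K2, ralpha=ralpha, gx=gx, ax=ax)
    return forms, mu, meta


# ---------------------------------------------------------------------------
# Right-hand sides
# ---------------------------------------------------------------------------

def _as_state_array(state) -> np.ndarray:
    if isinstance(state, SystemState):
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
        if y.shape != (7,):
            raise DomainError(f"state must have 7 components, got {y.shape}")
    if not np.all(np.isfinite(y)):
        raise DomainError("state contains non-finite components")
    return y


def rhs_gbm_array(y: np.ndarray, p: ModelParameters) -> np.ndarray:
    """Unchecked concrete RHS on a raw array (solver hot path)."""
    T, S, C, Fb, Fg, MI, MII = y
    sup_T = p.aTbeta + p.eTbeta * (1.0 - p.aTbeta) / (Fb + p.eTbeta)
    sup_S = p.aSbeta + p.eSbeta * (1.0 - p.aSbeta) / (Fb + p.eSbeta)
    kill_T = (p.aT * MI / (MI + p.eT)) * sup_T * C * T / (p.hT + T)
    kill_S = (p.aS * MI / (MI + p.eS)) * sup_S * C * S / (p.hS + S)
    alpha = p.ralpha * (T / p.K1) * (S / p.K2) * (p.K1 - T)
    return np.array([
        p.r1 * T * (1.0 - T / p.K1) + alpha - kill_T,
        p.r2 * S * (1.0 - S / p.K2) - alpha - kill_S,
        -p.muC * C + p.N,
        p.gbeta + p.abetaT * T + p.abetaS * S - p.mubeta * Fb,
        p.agammaC * C - p.mugamma * Fg,
        p.gMI + p.aMIgamma * Fg / (Fg + p.eMIgamma) - p.muMI * MI,
        (p.aMIIgamma * Fg / (Fg + p.eMIIgamma))
        * (p.aMIIbeta + p.eMIIbeta * (1.0 - p.aMIIbeta) / (Fb + p.eMIIbeta))
        - p.muMII * MII,
    ])


def eval_rhs_gbm(state, params: ModelParameters) -> np.ndarray:
    """Rates of change of the concrete glioblastoma system (per hour),
    implemented term for term as printed (saturating kill ``T/(hT+T)``,
    TGF-beta suppression ``aTbeta + eTbeta(1-aTbeta)/(Fbeta+eTbeta)``...).
    """
    return rhs_gbm_array(_as_state_array(state), params)


def eval_rhs_abstract(state, forms: FunctionalForms,
                      mu: DeathRates) -> np.ndarray:
    """Rates of change of the abstract system for an arbitrary bundle."""
    y = _as_state_array(state)
    T, S, C, x, yy, u, v = y
    out = np.array([
        forms.alpha(T, S) + forms.R1(T) * T
        - forms.fT(x) * forms.gT(u) * forms.hT(T) * C * T,
        forms.R2(S) * S - forms.alpha(T, S)
        - forms.fS(x) * forms.gS(u) * forms.hS(S) * C * S,
        forms.fC((T + S) * v) * forms.gC(x) - mu.muC * C + forms.N_const,
        forms.fx(T + S) - mu.mux * x,
        forms.fy(C) - mu.muy * yy,
        forms.fu(yy) - mu.muu * u,
        forms.fv(x) * forms.gv(yy) - mu.muv * v,
    ], dtype=float)
    if not np.all(np.isfinite(out)):
        raise DomainError("abstract RHS is non-finite at the given state")
    return out


def tgfb_qss(T: float, S: float, params: ModelParameters | None = None,
             forms: FunctionalForms | None = None,
             mu: DeathRates | None = None) -> float:
    """Quasi-steady-state TGF-beta level ``x* = fx(T+S)/mux`` (fast-cytokine
    reduction)."""
    if params is not None:
        if params.mubeta <= 0:
            raise DomainError("mubeta must be > 0")
        return (params.gbeta + params.abetaT * T + params.abetaS * S) \
            / params.mubeta
    if forms is None or mu is None:
        raise ConfigurationError("provide either params or (forms, mu)")
    return forms.fx(T + S) / mu.mux


#: Order of the reduced (TGF-beta-eliminated) 6-variable state.
REDUCED_VARS = ("T", "S", "C", "Fgamma", "MI", "MII")


def eval_rhs_reduced(state6, params: ModelParameters | None = None,
                     forms: FunctionalForms | None = None,
                     mu: DeathRates | None = None) -> np.ndarray:
    """Rates of the 6-variable fast-TGF-beta reduction.

    TGF-beta is slaved to its quasi-steady state ``x* = fx(T+S)/mux`` and
    CTL inflow is the constant ``N`` (recruitment is dropped, as the
    constant-inflow assumption prescribes).  State order is
    ``(T, S, C, Fgamma, MI, MII)``.
    """
    y6 = np.asarray(state6, dtype=float)
    if y6.shape != (6,):
        raise DomainError(f"reduced state must have 6 components, got {y6.shape}")
    T, S, C, Fg, MI, MII = y6
    xstar = tgfb_qss(T, S, params=params, forms=forms, mu=mu)
    full = np.empty(7)
    full[:] = (T, S, C, xstar, Fg, MI, MII)
    if params is not None:
        r = rhs_gbm_array(full, params)
    else:
        # constant-inflow reduction: recruitment term removed from C'
        r = eval_rhs_abstract(full, forms, mu)
        r[2] = -mu.muC * C + forms.N_const
    return np.concatenate([r[:3], r[4:]])


# ---------------------------------------------------------------------------
# Jacobians and spectra
# ---------------------------------------------------------------------------

def jacobian_gbm(state, params: ModelParameters) -> np.ndarray:
    """Analytic 7x7 Jacobian of the concrete RHS."""
    y = _as_state_array(state)
    p = params
    T, S, C, Fb, Fg, MI, MII = y
    J = np.zeros((7, 7))

    kT = p.aT * MI / (MI + p.eT)
    kS = p.aS * MI / (MI + p.eS)
    dkT = p.aT * p.eT / (MI + p.eT) ** 2
    dkS = p.aS * p.eS / (MI + p.eS) ** 2
    supT = p.aTbeta + p.eTbeta * (1.0 - p.aTbeta) / (Fb + p.eTbeta)
    supS = p.aSbeta + p.eSbeta * (1.0 - p.aSbeta) / (Fb + p.eSbeta)
    dsupT = -p.eTbeta * (1.0 - p.aTbeta) / (Fb + p.eTbeta) ** 2
    dsupS = -p.eSbeta * (1.0 - p.aSbeta) / (Fb + p.eSbeta) ** 2
    satT = T / (p.hT + T)
    satS = S / (p.hS + S)
    dsatT = p.hT / (p.hT + T) ** 2
    dsatS = p.hS / (p.hS + S) ** 2
    dalpha_dT = p.ralpha * (S / (p.K1 * p.K2)) * (p.K1 - 2.0 * T)
    dalpha_dS = p.ralpha * (T / (p.K1 * p.K2)) * (p.K1 - T)

    # T row
    J[0, 0] = p.r1 * (1.0 - 2.0 * T / p.K1) + dalpha_dT - kT * supT * C * dsatT
    J[0, 1] = dalpha_dS
    J[0, 2] = -kT * supT * satT
    J[0, 3] = -kT * C * satT * dsupT
    J[0, 5] = -supT * C * satT * dkT
    # S row
    J[1, 0] = -dalpha_dT
    J[1, 1] = p.r2 * (1.0 - 2.0 * S / p.K2) - dalpha_dS - kS * supS * C * dsatS
    J[1, 2] = -kS * supS * satS
    J[1, 3] = -kS * C * satS * dsupS
    J[1, 5] = -supS * C * satS * dkS
    # C row
    J[2, 2] = -p.muC
    # Fbeta row
    J[3, 0] = p.abetaT
    J[3, 1] = p.abetaS
    J[3, 3] = -p.mubeta
    # Fgamma row
    J[4, 2] = p.agammaC
    J[4, 4] = -p.mugamma
    # MI row
    J[5, 4] = p.aMIgamma * p.eMIgamma / (Fg + p.eMIgamma) ** 2
    J[5, 5] = -p.muMI
    # MII row
    gvv = p.aMIIgamma * Fg / (Fg + p.eMIIgamma)
    fvv = p.aMIIbeta + p.eMIIbeta * (1.0 - p.aMIIbeta) / (Fb + p.eMIIbeta)
    J[6, 3] = gvv * (-p.eMIIbeta * (1.0 - p.aMIIbeta) / (Fb + p.eMIIbeta) ** 2)
    J[6, 4] = fvv * p.aMIIgamma * p.eMIIgamma / (Fg + p.eMIIgamma) ** 2
    J[6, 6] = -p.muMII
    return J


def finite_difference_jacobian(f: Callable[[np.ndarray], np.ndarray],
                               y: np.ndarray, rel_step: float = 1e-6,
                               abs_floor: float = 1e-8) -> np.ndarray:
    """Central-difference Jacobian with per-component relative step."""
    y = np.asarray(y, dtype=float)
    n = y.size
    f0 = np.asarray(f(y), dtype=float)
    J = np.zeros((f0.size, n))
    for j in range(n):
        h = max(rel_step * abs(y[j]), abs_floor)
        yp = y.copy()
        ym = y.copy()
        yp[j] += h
        ym[j] = max(ym[j] - h, 0.0) if y[j] - h < 0 else ym[j] - h
        span = yp[j] - ym[j]
        J[:, j] = (np.asarray(f(yp)) - np.asarray(f(ym))) / span
    if not np.all(np.isfinite(J)):
        raise DomainError("Jacobian has non-finite entries")
    return J


def spectral_label(eigenvalues: np.ndarray,
                   marginal_tol: float = 1e-12) -> str:
    """Stability label from eigenvalue real parts.

    ``marginal`` when the largest real part is within ``marginal_tol``
    times the spectral radius of zero, else ``stable``/``unstable`` by its
    sign.
    """
    lam = np.asarray(eigenvalues, dtype=complex)
    rad = float(np.max(np.abs(lam))) if lam.size else 0.0
    top = float(np.max(lam.real)) if lam.size else 0.0
    if abs(top) <= marginal_tol * max(rad, 1e-300):
        return "marginal"
    return "stable" if top < 0 else "unstable"
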