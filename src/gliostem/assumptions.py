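"""Numerical certification of the model's assumption lists.

Two tiers of assumptions constrain a :class:`~gliostem.model.FunctionalForms`
bundle: a *mathematical* list (A1: linear growth bounds, monotonicity,
boundedness — enough for orthant invariance and dissipativity) and a
*biological* list (A2: logistic growth with fixed carrying capacities,
kill suppression decreasing from 1 to a positive floor, MHC activation
saturating, linear cytokine production, constant treatment).

The checker is a **falsifier, not a prover**: every item is tested by
finite sampling on log-spaced grids (default 512 points per axis over
``[0, 1e3 x scale]``), limits are probed at ``1e6 x scale``, and
"bounded above" means the value at ``1e6 x scale`` is within 1% of the
value at ``1e5 x scale``.  Verdicts are therefore grid-relative; a
``fail`` always carries at least one concrete witness point at which the
violated inequality can be re-evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError
from .model import DeathRates, FunctionalForms, ModelParameters

__all__ = ["AssumptionCheck", "AssumptionReport", "check_A1", "check_A2",
           "check_A3"]

_MONO_TOL = 1e-9       # relative slack for monotonicity comparisons
_LIMIT_TOL = 1e-3      # relative tolerance for limit values
_BOUND_TOL = 1e-2      # 1%: "bounded" = flat between 1e5x and 1e6x scale


@dataclass(frozen=True)
class AssumptionCheck:
    """Verdict for one assumption item."""

    id: str                       # e.g. "A2.5"
    description: str
    status: str                   # pass / fail / not-applicable
    witnesses: tuple = ()         # points violating the item (when fail)

    def __post_init__(self) -> None:
        if self.status == "fail" and not self.witnesses:
            raise ValueError("a fail verdict requires a witness point")


@dataclass(frozen=True)
class AssumptionReport:
    """Collection of per-item verdicts plus the grid description."""

    checks: tuple[AssumptionCheck, ...]
    grid: str

    @property
    def failed(self) -> tuple[AssumptionCheck, ...]:
        return tuple(c for c in self.checks if c.status == "fail")

    @property
    def ok(self) -> bool:
        return not self.failed

    def __getitem__(self, item_id: str) -> AssumptionCheck:
        for c in self.checks:
            if c.id == item_id:
                return c
        raise KeyError(item_id)

    def as_table(self) -> str:
        lines = [f"{'id':<6} {'status':<16} description",
                 "-" * 72]
        for c in self.checks:
            lines.append(f"{c.id:<6} {c.status:<16} {c.description}")
        lines.append(f"[grid: {self.grid}]")
        return "\n".join(lines)


def _grid(scale: float, n: int) -> np.ndarray:
    """Log-spaced grid on [0, 1e3*scale] with a zero node."""
    g = np.geomspace(scale * 1e-6, scale * 1e3, n - 1)
    return np.concatenate([[0.0], g])


def _eval(fn, grid) -> np.ndarray:
    try:
        vals = np.array([float(fn(g)) for g in np.atleast_1d(grid)])
    except Exception as exc:  # noqa: BLE001 - surfaced as a domain failure
        raise DomainError(f"form evaluation failed: {exc}") from exc
    return vals


def _finite_nonneg(fn, grid):
    vals = _eval(fn, grid)
    bad = ~np.isfinite(vals) | (vals < 0)
    if np.any(bad):
        i = int(np.argmax(bad))
        return False, ((float(grid[i]), float(vals[i])),), vals
    return True, (), vals


def _monotone(vals: np.ndarray, grid: np.ndarray, increasing: bool):
    """Nondecreasing/nonincreasing along the grid, with relative slack."""
    scale = np.maximum(np.abs(vals[:-1]), np.abs(vals[1:])) + 1e-300
    diff = np.diff(vals)
    viol = diff < -_MONO_TOL * scale if increasing \
        else diff > _MONO_TOL * scale
    if np.any(viol):
        i = int(np.argmax(viol))
        return False, ((float(grid[i]), float(grid[i + 1])),)
    return True, ()


def _bounded_above(fn, scale: float):
    v5, v6 = float(fn(1e5 * scale)), float(fn(1e6 * scale))
    ref = max(abs(v5), abs(v6), 1e-300)
    if abs(v6 - v5) > _BOUND_TOL * ref:
        return False, ((1e6 * scale, v6),)
    return True, ()


def _at_most_linear(fn, scale: float):
    """|f(z)|/(1+z) stays flat between 1e5x and 1e6x scale."""
    z5, z6 = 1e5 * scale, 1e6 * scale
    q5 = abs(float(fn(z5))) / (1.0 + z5)
    q6 = abs(float(fn(z6))) / (1.0 + z6)
    ref = max(q5, q6, 1e-300)
    if q6 - q5 > _BOUND_TOL * ref:
        return False, ((z6, float(fn(z6))),)
    return True, ()


def _scales(params: ModelParameters | None) -> dict[str, float]:
    if params is None:
        params = ModelParameters()
    p = params
    x_sc = max(p.gbeta / p.mubeta, 1.0)
    C_sc = max(p.N / p.muC, 1e6)
    y_sc = max(p.agammaC * C_sc / p.mugamma, 1.0)
    u_sc = max((p.gMI + p.aMIgamma) / p.muMI, 1.0)
    v_sc = max(p.aMIIgamma / p.muMII, 1.0)
    return {"T": p.K1, "S": p.K2, "C": C_sc, "x": x_sc, "y": y_sc,
            "u": u_sc, "v": v_sc, "w": (p.K1 + p.K2) * v_sc}


def check_A1(forms: FunctionalForms, params: ModelParameters | None = None,
             n_grid: int = 512) -> AssumptionReport:
    """Certify the mathematical assumption list (A1) by finite sampling."""
    if n_grid < 3:
        raise DomainError("grid size must be >= 3")
    sc = _scales(params)
    gT_ = _grid(sc["T"], n_grid)
    gS_ = _grid(sc["S"], n_grid)
    gx = _grid(sc["x"], n_grid)
    gy = _grid(sc["y"], n_grid)
    gu = _grid(sc["u"], n_grid)
    gw = _grid(sc["w"], n_grid)
    gC = _grid(sc["C"], n_grid)
    checks: list[AssumptionCheck] = []

    def add(id_, desc, ok, wit=()):
        checks.append(AssumptionCheck(
            id=id_, description=desc,
            status="pass" if ok else "fail",
            witnesses=tuple(wit) if not ok else ()))

    # A1.1 R1, R2 at most linear
    ok1, w1 = _at_most_linear(forms.R1, sc["T"])
    ok2, w2 = _at_most_linear(forms.R2, sc["S"])
    add("A1.1", "R1(T) and R2(S) grow at most linearly", ok1 and ok2,
        w1 + w2)

    # A1.2 alpha increasing (both arguments)
    wit = []
    ok = True
    for Sfix in (sc["S"] * 1e-3, sc["S"]):
        vals = np.array([forms.alpha(t, Sfix) for t in gT_])
        o, w = _monotone(vals, gT_, increasing=True)
        ok &= o
        wit += [(t, Sfix) for t in (w[0] if w else ())]
    for Tfix in (sc["T"] * 1e-3, sc["T"] / 2.0):
        vals = np.array([forms.alpha(Tfix, s) for s in gS_])
        o, w = _monotone(vals, gS_, increasing=True)
        ok &= o
        wit += [(Tfix, s) for s in (w[0] if w else ())]
    add("A1.2", "alpha(T,S) is increasing in T and S", ok, wit[:4])

    # A1.3 fT, fS decreasing & bounded below; gT, gS increasing & bounded above
    ok = True
    wit = []
    for fn, g in ((forms.fT, gx), (forms.fS, gx)):
        vals = _eval(fn, g)
        o, w = _monotone(vals, g, increasing=False)
        ok &= o and bool(np.all(vals >= 0))
        wit += list(w)
    for fn in (forms.gT, forms.gS):
        vals = _eval(fn, gu)
        o, w = _monotone(vals, gu, increasing=True)
        ob, wb = _bounded_above(fn, sc["u"])
        ok &= o and ob
        wit += list(w) + list(wb)
    add("A1.3", "fT,fS decreasing bounded below; gT,gS increasing bounded "
        "above", ok, wit)

    # A1.4 hT, hS decreasing & bounded below (by 0: nonnegative)
    ok = True
    wit = []
    for fn, g in ((forms.hT, gT_), (forms.hS, gS_)):
        okn, wn, vals = _finite_nonneg(fn, g)
        o, w = _monotone(vals, g, increasing=False)
        ok &= okn and o
        wit += list(wn) + list(w)
    add("A1.4", "hT and hS decreasing and bounded below", ok, wit)

    # A1.5 fC increasing bounded above; gC decreasing bounded below
    vfC = _eval(forms.fC, gw)
    o1, w1 = _monotone(vfC, gw, increasing=True)
    ob, wb = _bounded_above(forms.fC, sc["w"])
    vgC = _eval(forms.gC, gx)
    o2, w2 = _monotone(vgC, gx, increasing=False)
    add("A1.5", "fC increasing bounded above; gC decreasing bounded below",
        o1 and ob and o2 and bool(np.all(vgC >= 0)), w1 + wb + w2)

    # A1.6 N nonnegative and bounded
    add("A1.6", "treatment inflow nonnegative and bounded",
        np.isfinite(forms.N_const) and forms.N_const >= 0,
        ((forms.N_const,),))

    # A1.7 fx, fy increasing
    o1, w1 = _monotone(_eval(forms.fx, gw), gw, increasing=True)
    o2, w2 = _monotone(_eval(forms.fy, gC), gC, increasing=True)
    add("A1.7", "fx(T+S) and fy(C) increasing", o1 and o2, w1 + w2)

    # A1.8 fu increasing bounded above
    o, w = _monotone(_eval(forms.fu, gy), gy, increasing=True)
    ob, wb = _bounded_above(forms.fu, sc["y"])
    add("A1.8", "fu increasing and bounded above", o and ob, w + wb)

    # A1.9 gv increasing bounded above; fv decreasing bounded below
    o1, w1 = _monotone(_eval(forms.gv, gy), gy, increasing=True)
    ob, wb = _bounded_above(forms.gv, sc["y"])
    vfv = _eval(forms.fv, gx)
    o2, w2 = _monotone(vfv, gx, increasing=False)
    add("A1.9", "gv increasing bounded above; fv decreasing bounded below",
        o1 and ob and o2 and bool(np.all(vfv >= 0)), w1 + wb + w2)

    return AssumptionReport(
        checks=tuple(checks),
        grid=f"log-spaced, {n_grid} pts/axis, [0, 1e3 x scale]")


def check_A2(forms: FunctionalForms, params: ModelParameters | None = None,
             n_grid: int = 512) -> AssumptionReport:
    """Certify the biological assumption list (A2) by finite sampling.

    Carrying capacities and structural constants come from ``params``
    (published defaults when omitted).  Limits are probed at
    ``1e6 x scale``.
    """
    if n_grid < 3:
        raise DomainError("grid size must be >= 3")
    p = params if params is not None else ModelParameters()
    sc = _scales(p)
    gx = _grid(sc["x"], n_grid)
    gu = _grid(sc["u"], n_grid)
    gy = _grid(sc["y"], n_grid)
    gw = _grid(sc["w"], n_grid)
    checks: list[AssumptionCheck] = []

    def add(id_, desc, ok, wit=(), status=None):
        checks.append(AssumptionCheck(
            id=id_, description=desc,
            status=status or ("pass" if ok else "fail"),
            witnesses=() if (ok or status) else tuple(wit)))

    def close(a, b, tol=_LIMIT_TOL):
        return abs(a - b) <= tol * max(abs(a), abs(b), 1e-300)

    # A2.1 logistic structure of R1, R2
    gT_lin = np.linspace(0.0, p.K1, n_grid)
    gS_lin = np.linspace(0.0, p.K2, n_grid)
    v1 = _eval(forms.R1, gT_lin)
    v2 = _eval(forms.R2, gS_lin)
    o1, w1 = _monotone(v1, gT_lin, increasing=False)
    o2, w2 = _monotone(v2, gS_lin, increasing=False)
    ok = o1 and o2 and abs(v1[-1]) <= 1e-9 * abs(v1[0]) \
        and abs(v2[-1]) <= 1e-9 * abs(v2[0]) and v1[0] > 0 and v2[0] > 0
    add("A2.1", "R1, R2 decreasing with R(K)=0 and R(0)>0", ok,
        w1 + w2 + ((p.K1, float(v1[-1])), (p.K2, float(v2[-1]))))

    # A2.2 product form of alpha
    wit = []
    ok = True
    for T, S in ((p.K1 / 3, p.K2 / 2), (p.K1 / 2, p.K2), (p.K1 / 5, p.K2 / 7)):
        lhs = forms.alpha(T, S)
        rhs = forms.alpha(T, p.K2) * (S / p.K2)   # linear in S
        if not close(lhs, rhs, 1e-9):
            ok = False
            wit.append((T, S))
    for S in (p.K2 / 2, p.K2):
        if abs(forms.alpha(0.0, S)) > 1e-12 or \
                abs(forms.alpha(p.K1, S)) > 1e-12 * p.ralpha * p.K1:
            ok = False
            wit.append((0.0, S))
    add("A2.2", "alpha(T,S) = ralpha (S/K2)(T/K1)(K1-T) product form", ok, wit)

    # A2.3 fT, fS decreasing from 1 to a positive limit
    ok = True
    wit = []
    for fn in (forms.fT, forms.fS):
        f0 = float(fn(0.0))
        flim = float(fn(1e6 * sc["x"]))
        o, w = _monotone(_eval(fn, gx), gx, increasing=False)
        if not (o and close(f0, 1.0) and flim > 0):
            ok = False
            wit += list(w) + [(0.0, f0), (1e6 * sc["x"], flim)]
    add("A2.3", "fT, fS decrease from 1 to a positive floor", ok, wit)

    # A2.4 gT, gS increasing from 0 to a positive limit
    ok = True
    wit = []
    for fn in (forms.gT, forms.gS):
        g0 = float(fn(0.0))
        glim = float(fn(1e6 * sc["u"]))
        o, w = _monotone(_eval(fn, gu), gu, increasing=True)
        if not (o and abs(g0) <= 1e-12 and glim > 0):
            ok = False
            wit += list(w) + [(0.0, g0)]
    add("A2.4", "gT, gS increase from 0 to a positive limit", ok, wit)

    # A2.5 gS < gT pointwise for u > 0
    upos = gu[gu > 0]
    diff = _eval(forms.gT, upos) - _eval(forms.gS, upos)
    okk = bool(np.all(diff > 0))
    wit = () if okk else ((float(upos[int(np.argmin(diff))]),),)
    add("A2.5", "gS(u) < gT(u) for u > 0 (CTLs less efficient on stem cells)",
        okk, wit)

    # A2.6 hT, hS decreasing from 1 to 0
    ok = True
    wit = []
    for fn, scl in ((forms.hT, sc["T"]), (forms.hS, sc["S"])):
        h0 = float(fn(0.0))
        hlim = float(fn(1e6 * scl))
        o, w = _monotone(_eval(fn, _grid(scl, n_grid)), _grid(scl, n_grid),
                         increasing=False)
        if not (o and close(h0, 1.0) and abs(hlim) <= _LIMIT_TOL):
            ok = False
            wit += list(w) + [(0.0, h0)]
    add("A2.6", "hT, hS decrease from 1 to 0", ok, wit)

    # A2.7 fC increasing from 0, fC'(0) > 0, fC' -> 0
    vfC = _eval(forms.fC, gw)
    if np.all(vfC == 0.0):
        add("A2.7", "fC increasing from 0 with positive initial slope "
            "(vacuous: recruitment identically zero)", True,
            status="not-applicable")
    else:
        h = sc["w"] * 1e-9
        slope0 = (float(forms.fC(h)) - float(forms.fC(0.0))) / h
        slope_inf = (float(forms.fC(1e6 * sc["w"] + h))
                     - float(forms.fC(1e6 * sc["w"]))) / h
        o, w = _monotone(vfC, gw, increasing=True)
        okk = o and abs(float(forms.fC(0.0))) <= 1e-12 and slope0 > 0 \
            and abs(slope_inf) <= _LIMIT_TOL * max(slope0, 1e-300)
        add("A2.7", "fC increasing from 0, fC'(0)>0, fC' -> 0", okk,
            w + ((0.0, slope0),))

    # A2.8 gC decreasing from 1 to a positive floor
    vgC = _eval(forms.gC, gx)
    o, w = _monotone(vgC, gx, increasing=False)
    okk = o and close(float(forms.gC(0.0)), 1.0) \
        and float(forms.gC(1e6 * sc["x"])) > 0
    add("A2.8", "gC decreasing from 1 to a positive floor", okk,
        w + ((0.0, float(forms.gC(0.0))),))

    # A2.9 fx affine with positive intercept/slope; fy linear through 0
    w_pts = np.array([0.0, sc["w"] / 2, sc["w"], 2 * sc["w"]])
    vfx = _eval(forms.fx, w_pts)
    second = vfx[2] - 2 * vfx[1] + vfx[0]
    okx = abs(second) <= 1e-9 * max(abs(vfx[2]), 1e-300) and vfx[0] > 0 \
        and vfx[1] >= vfx[0]
    C_pts = np.array([sc["C"] / 2, sc["C"], 2 * sc["C"]])
    vfy = _eval(forms.fy, C_pts)
    oky = abs(float(forms.fy(0.0))) <= 1e-12 \
        and close(vfy[1] / C_pts[1], vfy[0] / C_pts[0], 1e-9) \
        and close(vfy[2] / C_pts[2], vfy[0] / C_pts[0], 1e-9)
    add("A2.9", "fx = gx + ax (T+S) affine; fy = ay C linear", okx and oky,
        ((sc["w"], float(second)), (0.0, float(forms.fy(0.0)))))

    # A2.10 fu(0) > 0 with a finite saturated limit
    fu0 = float(forms.fu(0.0))
    o, w = _monotone(_eval(forms.fu, gy), gy, increasing=True)
    ob, wb = _bounded_above(forms.fu, sc["y"])
    add("A2.10", "fu(0)=gu>0, increasing to gu+au", fu0 > 0 and o and ob,
        ((0.0, fu0),) + w + wb)

    # A2.11 fv(0)=1 decreasing to 0
    fv0 = float(forms.fv(0.0))
    fvlim = float(forms.fv(1e6 * sc["x"]))
    o, w = _monotone(_eval(forms.fv, gx), gx, increasing=False)
    add("A2.11", "fv(0)=1 and fv decreasing to 0",
        o and close(fv0, 1.0) and abs(fvlim) <= _LIMIT_TOL,
        w + ((0.0, fv0), (1e6 * sc["x"], fvlim)))

    # A2.12 gv(0)=0 increasing and saturating with vanishing slope
    gv0 = float(forms.gv(0.0))
    o, w = _monotone(_eval(forms.gv, gy), gy, increasing=True)
    ob, wb = _bounded_above(forms.gv, sc["y"])
    h = sc["y"] * 1e-9
    slope0 = (float(forms.gv(h)) - gv0) / h
    slope_inf = (float(forms.gv(1e6 * sc["y"] + h))
                 - float(forms.gv(1e6 * sc["y"]))) / h
    okk = abs(gv0) <= 1e-12 and o and ob and slope0 > 0 \
        and abs(slope_inf) <= _LIMIT_TOL * max(slope0, 1e-300)
    add("A2.12", "gv(0)=0, increasing to a limit with slope -> 0", okk,
        ((0.0, gv0),) + w + wb)

    # A2.13 constant treatment
    add("A2.13", "treatment inflow constant in time",
        np.isfinite(forms.N_const), ((forms.N_const,),))

    return AssumptionReport(
        checks=tuple(checks),
        grid=f"log-spaced, {n_grid} pts/axis, [0, 1e3 x scale], "
             f"limits at 1e6 x scale")


def check_A3(forms: FunctionalForms, mu: DeathRates,
             timescale_ratio: float = 10.0) -> AssumptionReport:
    """Check the reduction assumptions: fast TGF-beta (its clearance rate
    dominates every other clearance rate by ``timescale_ratio``) and
    constant CTL inflow (structural: ``N_const`` is a number)."""
    others = (mu.muC, mu.muy, mu.muu, mu.muv)
    fast = mu.mux >= timescale_ratio * max(others)
    checks = (
        AssumptionCheck(
            id="A3.1",
            description=f"TGF-beta clearance at least {timescale_ratio:g}x "
                        "faster than every other clearance",
            status="pass" if fast else "fail",
            witnesses=() if fast else ((mu.mux, max(others)),)),
        AssumptionCheck(
            id="A3.2", description="CTL inflow constant in time",
            status="pass" if np.isfinite(forms.N_const) else "fail",
            witnesses=() if np.isfinite(forms.N_const)
            else ((forms.N_const,),)),
    )
    return AssumptionReport(checks=checks, grid="structural")
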