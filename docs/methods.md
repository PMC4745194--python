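# Methods

## Model

The state is (T, S, C, Fβ, Fγ, MI, MII): differentiated tumor cells, cancer
stem cells, alloreactive CTLs, TGF-β, IFN-γ, and MHC class I/II receptor
densities per tumor cell.  Time is in hours, populations in cells, cytokines
in pg, receptor densities in receptors/cell.  Growth of both cancer
compartments is logistic with distinct carrying capacities (K1 = 1e8,
K2 = 1e7 cells); stem cells divert divisions into the tumor pool through
α(T,S) = rα(T/K1)(S/K2)(K1−T), which vanishes when either pool is empty and
when the tumor is at capacity.  CTL killing of each compartment is the
product of an MHC-I activation factor a·MI/(MI+e), a TGF-β suppression
factor f(Fβ) decreasing from 1 to a floor aβ, the CTL count, and a
burden-saturation 1/(h+T).  CTLs are infused at the constant rate N and die
at rate μC; in this instantiation recruitment from the bloodstream is folded
into the constant inflow (the constant-inflow simplification), so
C' = −μC·C + N exactly.  Cytokine and receptor kinetics are linear
production/decay with Michaelis–Menten activation terms.

Two code paths evaluate the right-hand side: the concrete system
(`eval_rhs_gbm`, hand-written term for term, with an analytic Jacobian) and
the abstract system (`eval_rhs_abstract`) in which all sixteen interaction
functions are pluggable (`FunctionalForms`).  `kronik_forms(params)` builds
the bundle that reproduces the concrete system; tests verify agreement to
1e-12 relative on random states.  The abstract `fx` takes the single
argument T+S, so the bundle requires aβS = aβT (true of the published
parameter set, which ties them); the concrete path keeps the two
coefficients separate.

### Assumption lists and where the concrete model departs from them

The analysis rests on three lists: (A1) mathematical (monotonicity,
boundedness, at-most-linear growth — enough for orthant invariance and
dissipativity), (A2) biological (logistic structure, kill suppression
decreasing from 1, saturating activation, linear cytokine production,
constant treatment), (A3) reduction (TGF-β fast, CTL inflow constant).  The
`assumptions` module certifies them **numerically**: log-spaced grids
(default 512 points per axis over [0, 1e3×scale]), limits probed at
1e6×scale with tolerance 1e-3, "bounded above" meaning the value at
1e6×scale is within 1% of the value at 1e5×scale, and monotonicity with
1e-9 relative slack.  This is a falsifier, not a prover: a pass is
grid-relative; a fail always carries a witness point.

The published concrete instantiation genuinely violates three items, and the
checker reports them rather than papering over:

- **A2.6**: the printed kill saturation is 1/(hT+T), whose value at zero is
  1/hT = 2e-9, not 1.  The two normalisations differ by the constant hT and
  cannot both hold; the concrete model is authoritative for simulation, the
  abstract contract for the checker.  Both behaviours are exposed, neither
  is "corrected".
- **A2.11**: the MHC-II suppression factor tends to aMIIβ = 0.012, not 0.
- **A1.2**: α above is not monotone in T past K1/2 — no product-form
  coupling of this shape can be, so every A2-compliant bundle fails this
  one item (the tests pin this down).
- **A2.7** is reported not-applicable for the concrete bundle because
  recruitment is identically zero under the constant-inflow simplification.

## Equilibria

**Cure state** (T = S = 0): C* = N/μC, Fβ* = gβ/μβ, Fγ* = aγC·C*/μγ, and MI*,
MII* from the steady state of their own equations — e.g.
MI* = [gMI + aMIγFγ*/(Fγ*+eMIγ)]/μMI, which is 100 receptors/cell untreated.
Residual contract: the RHS max-norm at a returned equilibrium is ≤ 1e-10 ×
the state scale.

**Recurrence states** are roots of L_N(S) = R2(S) − G2(N)·f̄S(S)/(hS+S) on
(0, K2], found by a 10⁴-interval sign scan plus Brent bisection; a root
where L_N falls through zero is stable, the reverse crossing unstable, and a
touch without sign change is labelled marginal and excluded from the parity
rule (the analysis assumes transversal crossings).  Boundary roots at K2 are
classified from the left side.

**Coexistence states** are simultaneous zeros of the reduced per-capita
rates M1, M2 on (0, K1] × (0, K2].  A 512×512 sign scan selects cells where
both rates span zero (grid nodes that are exact simultaneous zeros — the
(K1, K2) corner of the untreated system — are taken directly); candidates
are polished by a hybrid Newton solve in capacity-scaled coordinates and
kept when max(|M1|, |M2|) ≤ 1e-8.  Stability is read from the 2×2 Jacobian
of (T·M1, S·M2); the odd/even crossing-parity classification along the two
nullcline sections through each point is reported alongside.

**CTL recruitment balance** (for bundles with non-trivial recruitment): the
unique positive root of the strictly decreasing H(C), bracketed by doubling
from [0, 1] (cap 1e30) and solved by Brent's method.

## Threshold calculus and the two modes

G1(N) = gT(·)·C*(N) is the tumor-side kill pressure at the treated steady
state, G2 the stem-side one.  The steady MHC-I drive is computed through
the full chain Fγ*(N) = aγC·N/(μγμC) → X(N) = gMI + aMIγFγ*/(Fγ*+eMIγ).
Two modes are exposed:

- **mode "paper"** (default, the acceptance surface): the MHC-I argument of
  the kill activation is the *production rate* X(N) itself, and the
  stem-side amplification maximand is R2(S)·S·(hS+S)/f̄S(K1,S).  This is the
  only reading that reproduces every printed number of the worked example
  (N_min,T = .00245, N_min,S = 2.07889, ℵ_T = 3.60322e17, ℵ_S = 1.4866e15,
  N_thr,T = 3.10199e14, N_cure = 1.08783e15), verified by independent
  recomputation here.
- **mode "consistent"**: the kill activation uses the MHC-I *steady state*
  MI* = X/μMI — the coefficient the simulated dynamics actually see — and
  the stem-side maximand drops the extra factor of S (the literal
  definition, symmetric with the tumor side).  Its thresholds are
  substantially smaller (N_cure ≈ 2.9e13) and are the ones relevant to the
  simulated model.

In both modes H1(T,S) = f̄T(T,S)/(hT+T) and H2 = f̄S(T,S)/(hS+S) — the
per-capita kill shape implied by the saturating kill terms — with T fixed at
K1 during the stem-side maximization (the worst case, since f̄S decreases in
T; this choice matches the printed value).  The N_min inversions follow the
printed formulas, which evaluate the saturation at its unit normalisation
(not 1/h); as a consequence the thresholds are *sufficient* doses, not tight
ones for the simulated model — the recurrence submodel's pair
(N_min ≈ 2.45, N_thr ≈ 4.3e8) brackets the same gap.  The u*(N) chain uses
the full composition u* = fu(fy(N/μC)/μy)/μu throughout (one section of the
source derivation abbreviates this as fu(N)/μu; the full chain is what the
steady state requires).

Numerics: monotone inversion by bracket doubling from [0, 1] plus Brent's
method at 1e-12 relative tolerance (error below the target range or bracket
overflow at 1e30 raises); amplification maxima by a 1e5-point dense grid
with bounded golden-section refinement around the argmax (relative tolerance
1e-10), evaluating the interval endpoints so boundary maxima (the tumor-side
maximand peaks exactly at T = K1) are exact.

## Stability certificates

- Cure spectrum: eigenvalues of the analytic Jacobian at the cure state.
  At the cure state the Jacobian is block-triangular, so the closed form
  {−μC, −μx, −μy, −μu, −μv, r2 − C*·fS·gS·hS(0), r1 − C*·fT·gT·hT(0)} is
  exact; tests verify closed form vs finite-difference numerics to 1e-8
  relative on 50 random A2-compliant bundles.  Stability labels use the
  tolerance policy |Re λ| < 1e-12 × spectral radius ⇒ marginal.
- Decay certificates a1, a2 follow the printed bounds exactly, including
  the rα·K1²/4 term whose per-capita analogue would be rα·K1/4; the
  dimensional status of that term is ambiguous in the source and it is kept
  as printed.  On that scale a1, a2 are not themselves per-capita rates for
  the concrete model: the certified decay rate is h(K)·f(x_max)·a (the
  docstring states this), and the simulation test asserts exactly that
  rate, starting with the immune cascade at its treated steady level — the
  regime in which the certificate is derived.
- Dissipativity: with b1 = r1, a1 = r1K1 (valid since r1T(1−T/K1) ≤
  r1K1 − r1T is (T−K1)² ≥ 0), likewise for S, the state sum W obeys
  dW/dt ≤ A − δW with δ = min{r1, r2, μC, μβ, μγ, μMI, μMII} = 1e-3/h and
  A the aggregate inflow; the supremum bounds use the basal TGF-β
  production plus tumor-proportional terms at capacity, and the CTL ceiling
  max(N/μC, C(0)) (pass C0 when bounding a specific trajectory).  Tests
  assert W(t) ≤ max(W(0), A/δ)(1+1e-6) along all scenarios and 20 perturbed
  parameter sets.
- Global cure: grid certificate L1+rαK1 < 0 and L2 < 0 on
  [0, K1]×[0, K2] (default 256×256; tests also run 512×512), monotone in N.

## Simulation

`solve_ivp` with LSODA (stiff-capable) and the analytic Jacobian; relative
tolerance 1e-10; absolute tolerance 1e-40 for T and S and 1e-12 for the
other components.  The tiny cell-compartment tolerance is load-bearing: in
the recurrence regime S falls to ~1e-9 cells before regrowing, and T
traverses values far below one cell — an extinction cutoff or a loose
absolute tolerance would destroy the regrowth branch.  Populations below
one cell therefore keep evolving continuously; the one-cell threshold lives
only in `classify_outcome`.  Sampling is a short linear ramp to 1 h then
geometric spacing (≥ 1000 samples), resolving both the fast kill transient
and slow regrowth.  Solver-level negative excursions are bounded by the
tolerances (tests assert ≥ −1e-10 × component scale) and are not clipped.

`classify_outcome` labels the horizon state: cure (T, S < 1 cell),
recurrence (T < 1 ≤ S), coexistence (both ≥ 1), and undecided when (T, S)
still change by more than 10% over the last 10% of the horizon.  The
relative change is floored at one cell — |Δ|/max(|a|, |b|, 1) — because
sub-cell populations can change by many orders of magnitude (T ~ 1e-200
regrowing at ~0.007/h) without any biological meaning.  Labels are
horizon-relative by construction: in the recurrence scenario T also regrows
on a much longer timescale than the 5,000 h horizon.

### Scenarios

The three bundled studies use the published initial state (T, S, C, Fβ, Fγ,
MI, MII)(0) = (70, 30, 250, 50, 50, 50, 50) with: fig1 N = 0; fig2 N = 1 and
C(0) = 2.5e10; fig3 N = 1.08783e15 with T(0) = 7e5, S(0) = 3e5.  The source
states no integration horizons; the defaults 10,000 / 5,000 / 1,000 h are
this package's choices, long enough for each study's classification to be
stationary under the undecided test while keeping each run well under a
minute.  The 20 perturbed fixture sets multiply every independent
rate-valued parameter by a log-uniform factor in [0.5, 2] (tied rows — aS =
0.1·aT, aβS = aβT and the estimated duplicates — follow their parents),
emulating parameter uncertainty around the published set; they are used for
property tests (dissipativity, orthant invariance), not for inference.

What the defaults do not emulate: measurement noise, inter-patient
variability beyond rate scaling, time-varying or pulsed dosing, spatial
structure, delays, or stochastic extinction at low copy number.  Passing
tests show the deterministic model and its analysis are implemented
correctly and self-consistently, not that the model predicts clinical
outcomes; in particular continuous sub-cell populations are a modelling
convention, and real recurrence from ~1e-9 cells is a stochastic event this
framework cannot represent.

## Known limitations

- The cure-dose thresholds are sufficient, not necessary: simulated cures
  occur at doses far below N_cure (fig2 eliminates T at N = 1).
- Mode "paper" reproduces the published worked example but mixes the MHC-I
  production rate into the kill activation; mode "consistent" is the
  dynamics-faithful variant.  Choose deliberately.
- The coexistence search is a grid method: equilibria whose sign structure
  is finer than the 512×512 grid (or tangential intersections) can be
  missed; the parity classification assumes the nullclines cross the axes
  transversally.
- The assumptions checker samples finitely and cannot prove monotonicity or
  limits; its A2.7 slope tests use finite differences with no
  source-prescribed tolerance.
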