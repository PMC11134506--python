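# Methods

## Scope and assumptions

One protein with a single binding site; 1:1 stoichiometry; no
cooperativity; at most one competitive inhibitor; temperature, pH and
ionic strength implicitly constant (they enter only through the rate
and equilibrium constants supplied by the user). All computations are
deterministic forward calculations — no noise model and no fitting of
real experimental data. Concentrations are kept in nM end to end
(association rate constants are converted from M⁻¹s⁻¹ at the interface
by 1e-9); this scaling keeps the competitive-equilibrium cubic away
from the round-off pathologies that occur when the same coefficients
are formed in molar units.

## Saturation and the apparent Kd

The saturation curve is generated parametrically: `[PL]` is stepped
uniformly over `[0, [P]_total)` and the free/total ligand follow from
`Kd = ([P]t − [PL])·[L]free/[PL]`. Of the `n_points` grid points
(default 1000) only the first `shown_points` (default 970) are emitted,
because `[L]total` diverges as occupancy approaches 1; the full grid is
available with `shown_points=None`. The apparent Kd is analytic,
`Kd + [P]t/2`, and the titration-regime check compares
`1 + [P]t/(2Kd)` against a threshold of 1.05 (strictly below passes;
the threshold is the conventional 5% tolerance on a Kd estimate).

## Single-pair kinetics

The rate law `dx/dt = kon(Pt−x)(Lt−x) − koff·x` factors through the
roots `x1 < x2` of `x² − (Pt+Lt+Kd)x + Pt·Lt = 0`. The smaller root is
computed as `Pt·Lt/x2` (Vieta) to avoid cancellation. The general
solution from initial complex `x0` is

    x(t) = (x1 − x2·Q·e^(−γt)) / (1 − Q·e^(−γt)),
    Q = (x1−x0)/(x2−x0),  γ = kon(x2−x1),

covering association (`x0 < x1`) and relaxation downward after dilution
(`x0 > x1`) in one formula; its exact inverse supplies all
time-to-fraction quantities (t50, t99) analytically rather than by grid
search. The `x0 > x1` branch is not a textbook form, so the test suite
validates it against adaptive ODE integration (LSODA, rtol 1e-10).
When `x2 − x1 < 1e-9` nM the closed form loses precision and the
implementation falls back to numerical integration; with the supported
parameter ranges this branch is essentially unreachable (the root gap
is bounded below by Kd) but it guards degenerate limits.

Association time courses are emitted by stepping `[PL]` (1000 points,
990 shown by default) and inverting for t, which concentrates samples
where the curve bends; dissociation without rebinding is the pure
exponential `x0·e^(−koff·t)`.

## The simulated kinetic experiment

The fitting module emulates the standard association assay: fixed
`[P]0 = 100` nM, a chosen `[L]0`, six samples including t = 0, the last
sample at 99% of the second-order equilibrium complex. Two protocol
choices required a decision because prose descriptions of "evenly
separated measurements" are ambiguous:

- **Sample placement.** Samples are evenly spaced in `[PL]` (fractions
  0, 0.198, …, 0.99 of the equilibrium), consistent with curves that
  are generated by stepping concentration; times follow from the exact
  inverse. Even-in-time sampling is available (`sampling="time"`).
- **Fit model.** The default fit holds the plateau fixed at the
  end-point measurement itself and adjusts kobs alone
  (`model="anchored"`). This mirrors the bench shortcut of treating the
  last measurement of a run terminated at apparent equilibrium as the
  plateau, and it reproduces the canonical bias landmarks of this
  experiment design (kobs ratio 1.044 at 275 nM, minimum 0.999 at
  800 nM, 1.013 at 5000 nM; koff ratio 0.729 and kon ratio 1.018 at
  A = 4900 nM). A conventional two-parameter fit (amplitude free,
  `model="free"`) is provided; it yields systematically lower kobs
  (e.g. 1.020 at 275 nM) because the free amplitude absorbs part of
  the depletion bias.

Least squares uses Levenberg–Marquardt (`scipy.optimize.curve_fit`,
xtol 1e-10, ≤10,000 evaluations, unweighted residuals), seeded at the
theoretical `kobs = kon[L]0 + koff` when the generating rates are
known, else at `ln 2` over the mid-sample time. Rate-constant recovery
solves the line through `(A, kobs_fit)` and `(A+N, kobs_fit)` with
spacing `N = 100` nM by default. The bias scan covers
`[L]0 = 25…5000` nM in 25 nM steps and reports, per ratio, the
contiguous window around the closest approach to 1 where the ratio
stays within 1.000 ± 0.050. One caveat: the left edge of the published
two-point recovery curves (koff ratio 1.931, kon ratio 0.634 at
A = 25 nM) is not reproduced by any sampling/fit variant we examined
that also matches the other landmarks; our protocol gives 1.990 and
0.569 there. The discrepancy is confined to the strongly
ligand-depleted pair (25, 125) nM and does not affect the accurate
windows by more than one grid step.

## Competitive equilibrium

Mass balance reduces the five-species equilibrium to a cubic in free
protein, solved by the trigonometric closed form. Two numerical
safeguards: the arccos argument is clipped to [−1, 1], and the root is
polished with four Newton steps on the equivalent monotone balance
`p(1 + Lt/(Kd+p) + It/(Ki+p)) = Pt` — the trigonometric expression
cancels catastrophically when the free protein is many orders of
magnitude below the dominant coefficients (tiny protein against tight,
concentrated competitors), and the polish restores full double
precision (max relative deviation from a bracketed brute-force solve:
~1e-10 over wide random sweeps). The solver is vectorized over any
broadcastable combination of totals and constants.

## Competition kinetics

The analytical association model is the classical pseudo-first-order
double exponential (fast/slow rates from `KA = kon_L[L]0 + koff_L`,
`KB = kon_I[I]0 + koff_I`); it requires zero initial complexes and
<10% depletion of both ligand and inhibitor, and degrades gracefully —
the tests assert <1% agreement with the full simulation inside that
regime and growing disagreement outside.

The unrestricted simulator is explicit forward Euler on the mass-action
system: per step, the four on/off subprocess increments are evaluated
from the current state and all five species are updated simultaneously
(the assumption that within a small Δt each subprocess is unaffected by
the others *is* forward Euler). Stiffness is handled by splitting the
run into two phases: phase 1 ends at the smaller of the two binary
99%-equilibrium times (ligand side and inhibitor side, both analytic),
the run ends at 10× the larger, and each phase is divided into
`steps_per_phase` equal steps — 200,000 for association, 400,000 for
dissociation by default. Dissociation runs start from the dilution
state: pre-mix species scaled by `r/(r+1)`, inhibitor by `1/(r+1)`,
`[PI] = 0`, clock starting at mixing. The final state is compared with
the exact cubic equilibrium; a deviation of `[PL]` beyond 0.1% sets
`converged = False` (surfaced as a CLI warning advising more steps).
Halving Δt at the defaults moves the final concentrations by well under
0.01%. Trajectories are decimated to ≤2000 rows for output; any
negative concentration beyond −1e-12 nM aborts with an instability
error. For the dissociation phase-1 time we use the post-dilution free
protein and diluted inhibitor as the binary association pair; this only
sets the step size, and the 0.1% equilibrium check is insensitive to
the choice.

## Inhibition curves and Ki back-calculation

The dose grid is uniform on `[0, 100·A]` with `A = Ki(1 + [L]0/Kd)`
(the Cheng–Prusoff pre-estimate) and 20,001 points by default; the grid
resolution directly bounds the apparent-IC50 accuracy, and the
Ki-recovery residual shrinks roughly in proportion as the grid is
refined — it stems from the argmin estimate of the 50% point, not from
arithmetic precision. The apparent IC50 is the grid dose whose `[PL]`
is closest to half the blank control (smallest index on ties); the IC50
is the free inhibitor at that grid point; a grid that does not bracket
the 50% point raises a range error rather than returning the nearest
dose. Because the grid scales with Ki, even a practically inert
inhibitor is eventually titrated within its own grid; flatness of the
curve for weak inhibitors should be judged within a physically dosable
range. In dissociation mode the protein and ligand totals are scaled by
`r/(r+1)` and the grid holds post-mixing inhibitor totals, with the
blank control equilibrated at the same dilution.

Ki estimators: Cheng–Prusoff divides the apparent IC50 by
`1 + [L]0/Kd`; the exact relation propagates
`pl50 = pl_control/2` through mass balance
(`l50 = [L]0 − pl50`, `p50 = Kd·pl50/l50`, `pi50 = [P]0 − p50 − pl50`,
`i50 = IC50' − pi50`, `Ki = p50·i50/pi50`); Lin–Riggs is the same chain
with `i50` approximated by the apparent IC50 itself, implemented this
way deliberately so that its validity condition (`[I]0 ≫ [P]0`) is the
only difference from the exact relation.

## HTS sensitivity

For each requested baseline occupancy the protein total is derived
analytically (`Pt = pl0 + Kd·pl0/(Lt − pl0)`), guaranteeing that the
inhibitor-free equilibrium reproduces the baseline exactly; the
surviving fraction `[PL]eq/[PL]0` is then a single vectorized cubic
solve per condition. Defaults: Kd 100 nM, 10 nM ligand, 10 µM dose,
occupancies 0.1–0.9, Ki log-spaced 1 nM–100 µM (61 points). The grids
are choices of this package; only their ranges are canonical.

## Verification strategy

Every closed form is checked against an independent route: quadratic
roots against `numpy.roots`, time courses against LSODA integration of
the raw ODEs at rtol 1e-10, the competitive cubic against bracketed
root finding (brentq) on the monotone mass balance, IC50 estimates
against bisection on the exact 50% condition, and the simulator against
both the cubic equilibrium and the ODE oracle. Property-based tests
(hypothesis, derandomized) sweep the webpage-advertised parameter
ranges. What passing these tests shows is internal consistency of the
ideal-experiment model at stated precision; none of it speaks to
instrument noise, baseline drift, non-1:1 binding, or other features of
real data that the model deliberately excludes.

## Known limitations

- No noise model, no fitting of measured data, no multi-site or
  allosteric mechanisms, at most one inhibitor.
- The anchored kobs fit reproduces the canonical bias landmarks except
  the two published values at the most ligand-depleted two-point pair
  (A = 25 nM), as noted above.
- Forward Euler is first order; accuracy rests on the two-phase step
  budget, and pathological rate/concentration combinations outside the
  recommended ranges may need `steps_per_phase` raised.
- The dose-grid argmin makes apparent-IC50 (and hence back-calculated
  Ki) resolution-limited; refine `n_grid` when tighter than ~0.05 nM
  recovery is needed.
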