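# Methods

## The experimental system being modeled

The analysis targets isolated rat left-ventricular papillary muscle held
at its optimal length in an oxygen-free bath at 29 °C for 3 h, with
mechanics recorded every 30 min (anoxia times 0–180 min) followed by a
90 min re-oxygenation phase (recovery times r30–r90).  At each time
point the preparation yields: an afterloaded tension–velocity curve
(8–10 loads from zero to the isometric tension, in mN/mm² and Lo/s), an
independently measured unloaded shortening velocity Vmax (zero-load
clamp), the crossbridge sliding velocity v₀ (µm/s) and the myosin
content (nmol/g).  Only cohort summaries (mean ± SD, n = 20) of these
quantities are publicly available; they ship with the package as TSV
tables and anchor both the fixture analysis mode and the synthetic
generator.

## Hill mechanics

The tension–velocity relation is the rectangular hyperbola
(T + a)(V + b) = (To + a)·b with positive asymptote parameters a
(tension axis) and b (velocity axis) and curvature G = To/a = Vmax/b.
Fitting is nonlinear least squares on tension residuals of
T(V) = (To + a)·b/(V + b) − a, with To fixed at the measured isometric
point by default (the isometric contraction measures To directly; a
free-To variant is exposed via `fix_to=False`).  Starting values follow
the classical heuristic a₀ = To/4, b₀ = Vmax/4 and can be overridden.
Shortening velocities are positive; the lengthening limb and
series-elastic corrections are out of scope.  Estimates pinned at the
positivity bound (≤ 1e-8) are reported as fit failures naming the
muscle and time point, as are non-converged solves.

The curvature is the fragile quantity: it places the tension asymptote
−a outside the data, and when G < 1 (late anoxia) modest tension noise
moves a substantially.  This drives the choice of the synthetic noise
default below.

## Two-state crossbridge energetics

The 1957 sliding-filament scheme with attachment rate peak f1 and
detachment peaks g1 (head tilt ≤ h) and g2 (tilt > h) closes against
the Hill fit through

    G = f1/g1,   g1 = 2(w/e)·b/(h·G),   g2 = 2·Vmax/h,

with molecular constants h = 10 nm (working stroke), l = 28.6 nm
(actin site spacing, satisfying l ≫ h), e = 1e-19 J per ATP and
w/e = 0.75 (work fraction of one crossbridge).  Muscle velocities enter
as filament sliding speeds per half-sarcomere; the conversion Lo/s →
nm/s uses a 1.0 µm half-sarcomere, applied exactly once in
`derive_cb_params`.  That default reproduces the tabulated g2 column
from the tabulated Vmax column within 2 %, which is the validation the
choice rests on.  Derived observables:

* unitary force po = (w/l)·f1/(f1+g1), in pN, bounded by
  w/l ≈ 2.622 pN;
* catalytic constant kcat = (h/2l)·f1·g1/(f1+g1);
* crossbridge number per mm², N = To/po;
* stroke time ts = h/v₀ when v₀ is available;
* myosin ATPase = kcat × myosin content.

The energy-liberation rate and isotonic tension are

    E(V) = N·e·(h/2l)·(f1/(f1+g1))·{ g1 + f1·(V/Φ)(1 − e^(−Φ/V)) }
    P(V) = N·(w/l)·(f1/(f1+g1))·{ 1 − (V/Φ)(1 − e^(−Φ/V))
                                     ·(1 + ½((f1+g1)/g2)²(V/Φ)) }

with Φ = (f1+g1)·h/2.  The (V/Φ)(1 − e^(−Φ/V)) factor is evaluated
analytically at V = 0 (it tends to 0), avoiding the 0/0; P(0) = N·po
and E(0) = N·e·(h/2l)·f1g1/(f1+g1) hold exactly.  The quadratic
detachment correction uses ((f1+g1)/g2)² — the form consistent with the
g2 = 2Vmax/h closure (circulating transcriptions of the tension
equation sometimes garble this factor).

Efficiency η(V) = P(V)·V/E(V) is independent of N and of joint (e, w)
rescaling at fixed w/e.  Its maximum is located on a 2048-point
log-spaced grid of V/Φ ∈ [1e-3, V_root/Φ], where V_root is the zero of
P found by bracketing and Brent's method, then refined with a bounded
scalar minimizer (relative tolerance 1e-6).  With the control-time
cohort-mean rates (f1 = 314, g1 = 199, g2 = 753 s⁻¹) the maximum is
0.297 at V/Φ ≈ 0.49, inside the tabulated 28 ± 2 %.

v₀ and myosin content are treated strictly as measured inputs: the
stroke time that would generate v₀, and the geometry factor linking the
areal crossbridge count N (mm⁻²) to a mass-specific myosin content
(nmol/g), are not reconstructible from the available summaries.

## Entropy-production dynamics and the bifurcation

The thermodynamic force is myosin content / T (T = 302.15 K, the 29 °C
bath; configurable, and every downstream landmark — argmax times, zero
crossing, Ψ* — is invariant to the choice because T only rescales the
EPR).  The flow is v₀.  The EPR is their elementwise product
y(t) = v₀·MC/T, carried in the pseudo-units of its factors; no
dimensional claim is made for y itself.

The analysis (all regressions on cohort-mean series, matching how the
summaries are published; a per-muscle mode is a straightforward loop
over the same functions):

1. **Cubic time fit.**  Ordinary least squares of y on {1, t, t², t³},
   t in minutes; r² reported; the derivative polynomial is analytic.
   On the reference tables: intercept 0.2376, r² = 0.964.
2. **Zero crossing.**  Smallest real root of y′(t) in the fitted
   domain (74.9 min on the reference tables); absence of a sign change
   raises an analysis error carrying the endpoint derivatives.
3. **Phase curve.**  Zero-intercept least squares
   y = c1·y′ + c2·y′² + c3·y′³, with y′ the analytic derivative
   evaluated at the observation times (a finite-difference variant
   would simply substitute a different y′ series).  A free-intercept
   refit is always computed alongside as a diagnostic.  On data where
   y stays far from 0 while y′ crosses 0 — the reference tables are
   such data — the zero-intercept convention fits poorly (its r² can
   be strongly negative) and the intercept diagnostic absorbs the
   offset; both fits and both r² values are reported and neither is
   privileged.
4. **Control-parameter map.**  OLS line y′ = α + β·po; its zero
   −α/β is the unitary force at which dEPR/dt changes sign (1.348 pN
   on the reference tables).
5. **Fixed point.**  The fitted cubic gives y as a function of y′;
   near y′ = 0 its local inverse is the scalar field y′ = f(y), so
   y* = curve(0) and λ = 1/curve′(0).  Because λ is a fitted quantity
   and never exactly zero, "non-hyperbolic" means |λ| < 0.05 × max|f′|
   over the observed y′ range (f′ evaluated parametrically on a
   2001-point grid; where curve′ vanishes inside the range, max|f′| is
   large and the criterion is generous by construction — on the
   reference pipeline λ = 0.0225 against a tolerance of 0.27).  A
   fixed point with |λ| below tolerance is labelled half-stable when f
   keeps one sign on both sides of y* (the saddle-node normal form)
   and non-hyperbolic otherwise; a locally invertible cubic always
   yields the latter, so the half-stable label effectively requires
   the tangency geometry.  `classify_scalar_field` applies the same
   classification to any user-supplied f (root by sign-change scan +
   Brent, λ by central difference), and reproduces the analytic (λ,
   class) of linear and quadratic normal forms to 1e-9.
6. **Bifurcation branch.**  The pairs (po(t), y(t)) traversed in time
   order form the branch y = f(Ψ).  The turning point is the first
   sign change of successive Δy (ties: first in time order); Ψ* and t*
   are the po and time at that point (1.4 pN at 60 min on the
   reference tables).  A monotone branch returns a report with
   `detected = False` rather than an error.

## Synthetic cohorts

The generator emulates the study design: `n_muscles` = 20, anoxia times
{0, …, 180} min, recovery times {30, 60, 90} min, 9 afterloads per
curve at equal tension fractions 0 … 1 of To (the true spacing protocol
is not published; equal fractions of the isometric tension is the
natural afterload ladder).  Per-parameter trajectory means default to
the reference-table column means, including the recovery rows — so full
reversibility of Vmax, rates, v₀ and po, and the partial (~80 %)
reversibility of myosin content, are inherited from the tables rather
than imposed.  The hyperbola shape parameters G and b are back-derived
from the tabulated f1, g1 (G = f1/g1, b = g1·h·G/(2·w/e)); the
tabulated Vmax column is carried as a separate "measured" trajectory,
deliberately preserving the mean-of-ratios vs ratio-of-means mismatch
(G·b ≈ 3.3 Lo/s vs Vmax = 3.8 Lo/s at control) that per-muscle
averaging produces in the source summaries.

Biological variability is log-normal with coefficient of variation 0.3
(the published SDs are 30–45 % of their means; log-normal draws keep
every parameter positive up to cv ≈ 0.4, where Gaussian draws would
not).  Repeated measures on the same muscle are correlated through a
single muscle-level log-normal multiplier carrying half the
log-variance (`between_muscle_fraction = 0.5`); the true correlation
structure and the biological/instrumental error split are unknowable
from the published summaries, so both are documented defaults, not
claims.

Measurement noise is additive Gaussian on tension with SD 0.25 mN/mm²
(~0.5 % of the control isometric tension).  This is transducer-level
precision, chosen to match the source's report that every muscle's T–V
relation was accurately hyperbolic (R² ≈ 0.999 at this level); it is
also the regime in which the curvature-limited chain G → g1 is
identifiable to the few-percent level at cohort size 20.  Velocities
are synthesized exactly on the drawn hyperbola (the afterload is a
clamped, precisely known force; residual velocity noise is absorbed
into the biological cv).  What the generator does **not** emulate: raw
force/length waveforms, stimulation artifacts, drift within a time
point, non-log-normal outliers, and any muscle death during the
protocol.  Passing recovery tests therefore demonstrate estimator
correctness and pipeline identifiability under the stated statistical
model — not robustness to every failure mode of real preparations.

Determinism: one `numpy.random.Generator` seeded from the spec drives
every draw; identical specs give byte-identical CSV/JSON output.

## Problem sizes and numerical choices

The default test suite runs the reference-table analyses (7 time
points), single-curve fits, and cohort simulations of 3–20 muscles; the
distribution-level recovery check uses 50 seeded 20-muscle cohorts
(10 000 Hill fits, ~1 min).  These sizes were chosen to estimate the
relevant medians and detection rates tightly while keeping the suite
fast to iterate on.  Key tolerances: Hill solver xtol/ftol 1e-14 on
bounded trust-region least squares; efficiency maximum to 1e-6
relative; polynomial roots by companion-matrix eigenvalues (imaginary
parts < 1e-9 accepted as real); fixed-point roots by Brent to near
machine precision.

## Known limitations

* The phase-curve step inherits the conceptual weakness of regressing
  y on y′ when the observed trajectory loops in the (y, y′) plane: the
  single-valued cubic cannot represent both time branches, which is
  why the attracting-then-repelling character of the fixed point is
  visible in the branch diagram but not in the inverted phase field.
* The zero-intercept convention for the phase cubic follows the
  published analysis route; on the packaged tables the free-intercept
  diagnostic fits far better, and users drawing dynamical conclusions
  should inspect both.
* Between-condition significance testing (the paired contrasts marked
  in the reference tables) requires per-animal data that were never
  published; the markers are carried as data but no statistics are
  reproduced.
* Two-dimensional dynamics (limit cycles) and formal entropy balances
  from chemical affinities are out of scope.
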