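# myothermo

Crossbridge mechanics and non-equilibrium thermodynamics of anoxic
cardiac papillary muscle.

When an isolated left-ventricular papillary muscle is deprived of
oxygen for three hours, its contractile machinery degrades in a
structured way: the force–velocity relation flattens, the myosin
detachment kinetics accelerate, and the average force of a single
crossbridge falls.  Treated as an open thermodynamic system — with the
myosin content over the bath temperature as generalized force, the
crossbridge sliding velocity v₀ as generalized flow, and their product
as the entropy production rate (EPR) — the muscle passes through a
thermodynamic bifurcation at roughly one hour of anoxia: the EPR stops
rising and turns over at a non-hyperbolic fixed point of a
one-dimensional dynamics whose control parameter is the unitary
crossbridge force.

`myothermo` implements that entire analysis chain as a tested Python
library for muscle physiologists and biophysicists:

1. **Hill mechanics** — fit the hyperbolic tension–velocity relation
   `(T + a)(V + b) = (To + a)·b` to afterloaded contraction data;
   curvature `G = To/a = Vmax/b`.
2. **Two-state crossbridge energetics** — from `(G, b, Vmax)` derive
   the attachment/detachment rates
   `g1 = 2(w/e)b/(hG)`, `f1 = G·g1`, `g2 = 2Vmax/h`, the unitary force
   `po = (w/l)·f1/(f1+g1)`, catalytic constant
   `kcat = (h/2l)·f1g1/(f1+g1)`, the energy-rate and tension curves
   `E(V)`, `P(V)`, and the contractile efficiency `η(V) = P·V/E` with
   its maximum (bounded by `w/e = 0.75`).
3. **EPR dynamics** — build `y(t) = v₀·MC/T`, fit a cubic in time,
   regress `y` on `y′` (zero-intercept cubic) and `y′` on `po` (a
   line), classify the fixed point of `y′ = f(y)` by its slope
   `λ = f′(y*)`, and locate the turning point of the bifurcation
   branch `y = f(Ψ)`, `Ψ = po`.
4. **Synthetic cohorts** — seeded 20-muscle cohorts whose per-time
   parameter means track the packaged reference tables, with
   log-normal biological variability and ground-truth sidecars for
   end-to-end parameter-recovery testing.

## Worked example

```bash
python examples/03_bifurcation_analysis.py
```

```
EPR peaks at 60 min; flow peaks at 120 min
EPR(t) cubic: 0.238 + 2.63e-03 t + -2.12e-05 t^2 + 3.21e-08 t^3   (r2 = 0.964)
dEPR/dt crosses zero at 74.9 min
fixed point: lambda = 0.0225 -> non_hyperbolic
bifurcation: t* = 60 min, psi* = 1.40 pN; po-map root = 1.348 pN
```

Reading the output: the cohort-mean EPR rises from 0.235 at control,
peaks at 60 min of anoxia and falls thereafter, while the flow (v₀)
keeps rising until 120 min — the hallmark of a system moving
far from equilibrium.  The derivative of the fitted cubic changes sign
inside the 60–90 min window; the slope of the phase relation at the
fixed point is indistinguishable from zero (non-hyperbolic), and the
branch `y(po)` turns around at Ψ* ≈ 1.4 pN (the regression route gives
1.35 pN): once the unitary crossbridge force has fallen that far, the
muscle switches to a new thermodynamic branch.

The other examples cover single-curve Hill fitting
(`01_hill_fit.py`), the molecular energetics of the control state —
`po = 1.605 pN`, `kcat = 21.3 s⁻¹`, maximum efficiency 29.7 %
(`02_crossbridge_energetics.py`) — and cohort simulation with
parameter recovery, sub-2 % median error on `(f1, g1, g2, po)`
(`04_synthetic_cohort.py`).

A thin CLI wraps the same functions:

```bash
myothermo run --fixtures --report out/
myothermo simulate --seed 1 --out cohort/
myothermo fit cohort/tv_points.csv --aux cohort/muscle_series.csv --out fits.csv
```

## Layout

```
src/myothermo/      hill, huxley, thermo, synthetic, pipeline, cli
src/myothermo/data/ reference cohort tables (TSV)
examples/           narrative scripts, one per capability
tests/              pytest suite (unit, property, end-to-end)
docs/methods.md     model assumptions, parameters, design choices
```
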