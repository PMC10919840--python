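"""Entropy-production dynamics and bifurcation analysis.

The anoxic muscle is treated as an open thermodynamic system whose
generalized force is the myosin content divided by the absolute
temperature (nmol·g⁻¹·K⁻¹), whose generalized flow is the crossbridge
sliding velocity v0 (µm/s), and whose entropy production rate (EPR) is
their product:

    y(t) = EPR(t) = v0(t) · myosin_content(t) / T

The analysis proceeds in four steps:

1. fit a cubic polynomial y(t) to the EPR time course and take its
   analytic derivative y′(t);
2. regress y on y′ (zero-intercept cubic), giving a one-dimensional
   differential relation y = c1·y′ + c2·y′² + c3·y′³;
3. regress y′ on the unitary crossbridge force po (a line y′ = α + β·po),
   which recasts po as the control parameter Ψ of the dynamics — the
   zero −α/β is the force at which dEPR/dt changes sign;
4. classify the fixed point of y′ = f(y) (root, slope λ = f′(y*),
   attracting / repelling / non-hyperbolic / half-stable) and locate the
   turning point of the bifurcation branch y = f(Ψ).

Units are the pseudo-units of the source quantities; no dimensional
claim is made for the EPR product itself, and every result that matters
(argmax time, zero crossing, Ψ*) is invariant to its overall scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import AnalysisError, FitFailureError, InvalidInputError


# --------------------------------------------------------------------------
# thermodynamic series

@dataclass(frozen=True)
class ThermoSeries:
    """Time-indexed thermodynamic force, flow and EPR of a cohort."""

    times: np.ndarray          # min
    force: np.ndarray          # myosin content / T, nmol g^-1 K^-1
    flow: np.ndarray           # v0, um/s
    epr: np.ndarray            # flow * force

    @property
    def epr_argmax_time(self) -> float:
        """Protocol time (min) at which the observed EPR peaks."""
        return float(self.times[int(np.argmax(self.epr))])

    @property
    def flow_argmax_time(self) -> float:
        """Protocol time (min) at which the flow (v0) peaks."""
        return float(self.times[int(np.argmax(self.flow))])


def build_thermo_series(times: Sequence[float], v0: Sequence[float],
                        myosin_content: Sequence[float],
                        temperature_K: float = 302.15) -> ThermoSeries:
    """Assemble force/flow/EPR series from cohort-mean v0 and myosin content.

    EPR is computed elementwise as v0 × myosin_content / T.
    """
    t = np.asarray(times, dtype=float)
    flow = np.asarray(v0, dtype=float)
    mc = np.asarray(myosin_content, dtype=float)
    if not (len(t) == len(flow) == len(mc)):
        raise InvalidInputError(
            f"misaligned series: len(times)={len(t)}, len(v0)={len(flow)}, "
            f"len(myosin)={len(mc)}")
    if temperature_K <= 0:
        raise InvalidInputError("temperature_K must be positive")
    if np.any(flow < 0) or np.any(mc < 0):
        raise InvalidInputError("flow and myosin content must be non-negative")
    force = mc / temperature_K
    return ThermoSeries(times=t, force=force, flow=flow, epr=flow * force)


# --------------------------------------------------------------------------
# polynomial fit of the EPR time course

@dataclass(frozen=True)
class PolyFit:
    """Polynomial y(t) with ascending coefficients and its derivative."""

    coeffs: np.ndarray         # ascending degree
    degree: int
    r2: float
    domain: tuple[float, float]

    def __call__(self, t) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(t, dtype=float),
                                                self.coeffs)

    @property
    def derivative_coeffs(self) -> np.ndarray:
        """Ascending coefficients of dy/dt (analytic)."""
        return np.polynomial.polynomial.polyder(self.coeffs)

    def derivative(self, t) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(t, dtype=float),
                                                self.derivative_coeffs)


def fit_time_polynomial(series: ThermoSeries, degree: int = 3) -> PolyFit:
    """Ordinary least squares polynomial fit of EPR against time (min)."""
    t, y = series.times, series.epr
    if len(t) < degree + 2:
        raise InvalidInputError(
            f"need at least degree+2 = {degree + 2} time points, got {len(t)}")
    X = np.vander(t, degree + 1, increasing=True)
    if np.linalg.matrix_rank(X) < degree + 1:
        raise FitFailureError("rank-deficient design matrix for the "
                              "time-polynomial fit (duplicate times?)")
    coeffs, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coeffs
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return PolyFit(coeffs=coeffs, degree=degree, r2=r2,
                   domain=(float(t.min()), float(t.max())))


def zero_crossing(pf: PolyFit) -> float:
    """Smallest root of dy/dt = 0 inside the fitted time domain.

    Raises :class:`AnalysisError` with the derivative's endpoint values
    when the derivative does not change sign over the domain.
    """
    lo, hi = pf.domain
    d_lo, d_hi = float(pf.derivative(lo)), float(pf.derivative(hi))
    roots = np.polynomial.polynomial.polyroots(pf.derivative_coeffs)
    real = sorted(float(r.real) for r in roots
                  if abs(r.imag) < 1e-9 and lo - 1e-9 <= r.real <= hi + 1e-9)
    if not real:
        raise AnalysisError(
            f"dy/dt has no zero on [{lo}, {hi}] min "
            f"(endpoints: y'({lo}) = {d_lo:.3g}, y'({hi}) = {d_hi:.3g})")
    return float(np.clip(real[0], lo, hi))


# --------------------------------------------------------------------------
# phase-plane regressions

@dataclass(frozen=True)
class PhaseModel:
    """Fitted phase relations of the one-dimensional dynamics.

    ``cubic_coeffs`` are (c1, c2, c3) of the zero-intercept regression
    y = c1·y′ + c2·y′² + c3·y′³; ``intercept_diagnostic`` holds the
    four coefficients (c0..c3) of the always-reported refit with a free
    intercept.  ``po_map`` is (α, β) of the line y′ = α + β·po with zero
    psi_root = −α/β.
    """

    cubic_coeffs: tuple[float, float, float]
    r2_phase: float
    po_map: tuple[float, float]
    r2_map: float
    psi_root: float
    intercept_diagnostic: tuple[float, float, float, float] | None = None
    r2_intercept_diagnostic: float | None = None

    def curve(self, y_prime) -> np.ndarray:
        """y as a function of y′ under the zero-intercept cubic."""
        yp = np.asarray(y_prime, dtype=float)
        c1, c2, c3 = self.cubic_coeffs
        return c1 * yp + c2 * yp ** 2 + c3 * yp ** 3

    def curve_slope(self, y_prime) -> np.ndarray:
        """dy/dy′ of the fitted cubic."""
        yp = np.asarray(y_prime, dtype=float)
        c1, c2, c3 = self.cubic_coeffs
        return c1 + 2 * c2 * yp + 3 * c3 * yp ** 2


def _r2(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot if ss_tot > 0 else 1.0


def fit_phase_curve(y: Sequence[float], y_prime: Sequence[float],
                    degree: int = 3
                    ) -> tuple[np.ndarray, float, np.ndarray, float]:
    """Zero-intercept polynomial regression of y on y′.

    Returns ``(coeffs, r2, coeffs_with_intercept, r2_with_intercept)``:
    the zero-intercept coefficients (ascending powers of y′, starting at
    the linear term) and, as a diagnostic, the same regression with a
    free intercept (coefficients starting at the constant term).
    """
    yv = np.asarray(y, dtype=float)
    yp = np.asarray(y_prime, dtype=float)
    if len(yv) != len(yp):
        raise InvalidInputError("y and y_prime must have equal length")
    if len(yv) < degree + 1:
        raise InvalidInputError(
            f"need at least {degree + 1} points for a degree-{degree} "
            f"zero-intercept fit, got {len(yv)}")
    X = np.column_stack([yp ** k for k in range(1, degree + 1)])
    if np.linalg.matrix_rank(X) < degree:
        raise FitFailureError("rank-deficient design for the phase-curve fit")
    coeffs, *_ = np.linalg.lstsq(X, yv, rcond=None)
    r2 = _r2(yv, X @ coeffs)
    Xi = np.column_stack([yp ** k for k in range(0, degree + 1)])
    coeffs_i, *_ = np.linalg.lstsq(Xi, yv, rcond=None)
    r2_i = _r2(yv, Xi @ coeffs_i)
    return coeffs, r2, coeffs_i, r2_i


def fit_parameter_map(po: Sequence[float], y_prime: Sequence[float]
                      ) -> tuple[float, float, float, float]:
    """OLS line y′ = α + β·po and its zero psi_root = −α/β.

    Returns ``(alpha, beta, psi_root, r2)``.
    """
    p = np.asarray(po, dtype=float)
    yp = np.asarray(y_prime, dtype=float)
    if len(p) != len(yp):
        raise InvalidInputError("po and y_prime must have equal length")
    if len(p) < 3:
        raise InvalidInputError("need at least 3 points for the po map")
    if np.ptp(p) == 0:
        raise InvalidInputError("po is constant: the linear map is undefined")
    X = np.column_stack([np.ones_like(p), p])
    (alpha, beta), *_ = np.linalg.lstsq(X, yp, rcond=None)
    r2 = _r2(yp, alpha + beta * p)
    return float(alpha), float(beta), float(-alpha / beta), r2


def build_phase_model(y: Sequence[float], y_prime: Sequence[float],
                      po: Sequence[float]) -> PhaseModel:
    """Fit both phase relations and assemble a :class:`PhaseModel`."""
    coeffs, r2, coeffs_i, r2_i = fit_phase_curve(y, y_prime)
    alpha, beta, psi_root, r2_map = fit_parameter_map(po, y_prime)
    return PhaseModel(cubic_coeffs=tuple(float(v) for v in coeffs),
                      r2_phase=r2, po_map=(alpha, beta), r2_map=r2_map,
                      psi_root=psi_root,
                      intercept_diagnostic=tuple(float(v) for v in coeffs_i),
                      r2_intercept_diagnostic=r2_i)


# --------------------------------------------------------------------------
# fixed-point classification

@dataclass(frozen=True)
class FixedPoint:
    """Fixed point y* of y′ = f(y) with slope λ = f′(y*).

    ``klass`` is one of ``attracting`` (λ < 0), ``repelling`` (λ > 0),
    ``non_hyperbolic`` (|λ| below tolerance, f changes sign through y*)
    or ``half_stable`` (|λ| below tolerance, f keeps its sign on both
    sides — the saddle-node normal form).
    """

    y_star: float
    lam: float
    klass: str
    tolerance: float

    @property
    def is_non_hyperbolic(self) -> bool:
        return self.klass in ("non_hyperbolic", "half_stable")


def classify_scalar_field(f: Callable[[float], float],
                          y_range: tuple[float, float],
                          rel_tolerance: float = 0.05,
                          n_grid: int = 2001) -> FixedPoint:
    """Classify the fixed point of the autonomous scalar ODE y′ = f(y).

    The root of f is located by a sign-change scan over ``y_range``
    (falling back to the grid minimum of |f| when f touches zero without
    crossing, as in the saddle-node normal form).  λ is a central
    difference of f at the root; the non-hyperbolicity tolerance is
    ``rel_tolerance`` × max|f′| over the range, since a fitted λ is
    never exactly zero.
    """
    lo, hi = float(y_range[0]), float(y_range[1])
    if not hi > lo:
        raise InvalidInputError("y_range must be a non-degenerate interval")
    ys = np.linspace(lo, hi, n_grid)
    fv = np.array([float(f(y)) for y in ys])

    sign = np.sign(fv)
    crossings = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if len(crossings) > 0:
        from scipy.optimize import brentq
        i = crossings[0]
        y_star = float(brentq(f, ys[i], ys[i + 1], xtol=1e-15 * max(1, abs(hi))))
    elif np.any(fv == 0):
        y_star = float(ys[int(np.argmin(np.abs(fv)))])
    else:
        i = int(np.argmin(np.abs(fv)))
        # tangency root (f touches 0): refine by minimizing |f|
        from scipy.optimize import minimize_scalar
        lo_b, hi_b = ys[max(i - 1, 0)], ys[min(i + 1, n_grid - 1)]
        res = minimize_scalar(lambda y: abs(float(f(y))), bounds=(lo_b, hi_b),
                              method="bounded", options={"xatol": 1e-14})
        scale = float(np.max(np.abs(fv)))
        if abs(float(f(res.x))) > 1e-9 * max(scale, 1e-30):
            raise AnalysisError(
                f"no root of the phase field in [{lo:g}, {hi:g}] "
                f"(min |f| = {abs(float(f(res.x))):.3g})")
        y_star = float(res.x)

    h = max(abs(y_star), hi - lo) * 1e-6
    lam = (float(f(y_star + h)) - float(f(y_star - h))) / (2 * h)
    fp = np.gradient(fv, ys)
    tol = rel_tolerance * float(np.max(np.abs(fp)))

    if abs(lam) < tol:
        delta = (hi - lo) * 1e-3
        s_lo = np.sign(float(f(y_star - delta)))
        s_hi = np.sign(float(f(y_star + delta)))
        klass = "half_stable" if s_lo == s_hi and s_lo != 0 else "non_hyperbolic"
    else:
        klass = "attracting" if lam < 0 else "repelling"
    return FixedPoint(y_star=y_star, lam=float(lam), klass=klass,
                      tolerance=float(tol))


def classify_fixed_point(phase: PhaseModel,
                         y_prime_range: tuple[float, float],
                         rel_tolerance: float = 0.05,
                         n_grid: int = 2001) -> FixedPoint:
    """Classify the fixed point of the fitted phase relation.

    The fitted cubic gives y as a function of y′; its local inverse near
    y′ = 0 is the phase field y′ = f(y).  The fixed point (f = 0) is
    therefore y* = curve(0) with λ = 1/curve_slope(0), and the
    non-hyperbolicity tolerance is ``rel_tolerance`` × max|f′| evaluated
    parametrically over the observed y′ range (f′(y) = 1/g′(y′) along
    the curve).  ``y_prime_range`` must bracket 0 — i.e. the observed
    dEPR/dt must change sign — otherwise the fixed point was not
    traversed and an :class:`AnalysisError` is raised.
    """
    lo, hi = float(min(y_prime_range)), float(max(y_prime_range))
    if not (lo <= 0.0 <= hi):
        raise AnalysisError(
            f"observed y' range [{lo:.3g}, {hi:.3g}] does not bracket 0: "
            "no fixed point in the observed window")
    slope0 = float(phase.curve_slope(0.0))
    if slope0 == 0:
        raise AnalysisError("phase curve has zero slope at y' = 0; the "
                            "local inverse is undefined")
    y_star = float(phase.curve(0.0))
    lam = 1.0 / slope0

    yp = np.linspace(lo, hi, n_grid)
    g_slope = phase.curve_slope(yp)
    g_slope = g_slope[np.abs(g_slope) > 0]
    tol = rel_tolerance * float(np.max(1.0 / np.abs(g_slope)))

    if abs(lam) < tol:
        # sign of f on both sides of y*: parametrize by y' near 0, where
        # the curve is locally monotone (slope0 != 0)
        klass = "non_hyperbolic"
        delta = (hi - lo) * 1e-3
        # f has the sign of y'; the side of y* reached is sign(curve(y')-y*)
        side_lo = np.sign(float(phase.curve(-delta)) - y_star)
        side_hi = np.sign(float(phase.curve(+delta)) - y_star)
        if side_lo == side_hi and side_lo != 0:
            klass = "half_stable"
    else:
        klass = "attracting" if lam < 0 else "repelling"
    return FixedPoint(y_star=y_star, lam=float(lam), klass=klass,
                      tolerance=float(tol))


# --------------------------------------------------------------------------
# bifurcation diagram

@dataclass(frozen=True)
class BifurcationReport:
    """Turning point of the bifurcation branch y = f(Ψ), Ψ = po."""

    detected: bool
    psi_star: float | None          # pN
    t_star: float | None            # min
    zero_crossing_min: float | None
    branch: list[tuple[float, float]] = field(default_factory=list)
    message: str = ""


def bifurcation_diagram(times: Sequence[float], po: Sequence[float],
                        y: Sequence[float],
                        zero_crossing_min: float | None = None
                        ) -> BifurcationReport:
    """Locate the turning point of the branch (po(t), y(t)).

    The branch is traversed in time order; the bifurcation is flagged at
    the first sign change of successive Δy (the time point where y
    attains its local maximum), with Ψ* the unitary force at that
    point.  A strictly monotone branch yields ``detected=False`` with
    the message "no bifurcation detected".
    """
    t = np.asarray(times, dtype=float)
    p = np.asarray(po, dtype=float)
    yv = np.asarray(y, dtype=float)
    if not (len(t) == len(p) == len(yv)):
        raise InvalidInputError("times, po and y must be aligned")
    order = np.argsort(t)
    t, p, yv = t[order], p[order], yv[order]
    branch = [(float(pi), float(yi)) for pi, yi in zip(p, yv)]

    dy = np.diff(yv)
    signs = np.sign(dy)
    turn = None
    for i in range(1, len(signs)):
        if signs[i] != 0 and signs[i - 1] != 0 and signs[i] != signs[i - 1]:
            turn = i
            break
    if turn is None:
        return BifurcationReport(detected=False, psi_star=None, t_star=None,
                                 zero_crossing_min=zero_crossing_min,
                                 branch=branch,
                                 message="no bifurcation detected")
    return BifurcationReport(detected=True, psi_star=float(p[turn]),
                             t_star=float(t[turn]),
                             zero_crossing_min=zero_crossing_min,
                             branch=branch,
                             message=f"turning point at t = {t[turn]:g} min")


# --------------------------------------------------------------------------
# orchestration

@dataclass(frozen=True)
class ThermoReport:
    """Full thermodynamic analysis of one cohort time course."""

    series: ThermoSeries
    polyfit: PolyFit
    phase: PhaseModel
    fixed_point: FixedPoint
    bifurcation: BifurcationReport
    temperature_K: float

    def to_dict(self) -> dict:
        return {
            "temperature_K": self.temperature_K,
            "series": {
                "times_min": self.series.times.tolist(),
                "force": self.series.force.tolist(),
                "flow_um_s": self.series.flow.tolist(),
                "epr": self.series.epr.tolist(),
                "epr_argmax_min": self.series.epr_argmax_time,
                "flow_argmax_min": self.series.flow_argmax_time,
            },
            "epr_polynomial": {
                "coeffs_ascending": self.polyfit.coeffs.tolist(),
                "degree": self.polyfit.degree,
                "r2": self.polyfit.r2,
                "domain_min": list(self.polyfit.domain),
            },
            "phase_model": {
                "cubic_coeffs": list(self.phase.cubic_coeffs),
                "r2_phase": self.phase.r2_phase,
                "intercept_diagnostic": list(self.phase.intercept_diagnostic)
                if self.phase.intercept_diagnostic else None,
                "r2_intercept_diagnostic": self.phase.r2_intercept_diagnostic,
                "po_map_alpha_beta": list(self.phase.po_map),
                "r2_map": self.phase.r2_map,
                "psi_root_pN": self.phase.psi_root,
            },
            "fixed_point": {
                "y_star": self.fixed_point.y_star,
                "lambda": self.fixed_point.lam,
                "class": self.fixed_point.klass,
                "tolerance": self.fixed_point.tolerance,
            },
            "bifurcation": {
                "detected": self.bifurcation.detected,
                "psi_star_pN": self.bifurcation.psi_star,
                "t_star_min": self.bifurcation.t_star,
                "zero_crossing_min": self.bifurcation.zero_crossing_min,
                "branch_po_y": self.bifurcation.branch,
                "message": self.bifurcation.message,
            },
        }


def analyze_thermodynamics(times: Sequence[float], v0: Sequence[float],
                           myosin_content: Sequence[float],
                           po: Sequence[float],
                           temperature_K: float = 302.15,
                           degree: int = 3) -> ThermoReport:
    """Run the full EPR → phase model → bifurcation analysis.

    ``v0``, ``myosin_content`` and ``po`` are cohort-mean series aligned
    with ``times``.  The y′ values entering the phase regressions are
    the analytic derivative of the fitted time cubic evaluated at the
    observation times.
    """
    series = build_thermo_series(times, v0, myosin_content, temperature_K)
    pf = fit_time_polynomial(series, degree=degree)
    y_prime = pf.derivative(series.times)
    phase = build_phase_model(series.epr, y_prime, po)
    fp = classify_fixed_point(
        phase, (float(np.min(y_prime)), float(np.max(y_prime))))
    try:
        zc = zero_crossing(pf)
    except AnalysisError:
        zc = None
    bif = bifurcation_diagram(series.times, po, series.epr,
                              zero_crossing_min=zc)
    return ThermoReport(series=series, polyfit=pf, phase=phase,
                        fixed_point=fp, bifurcation=bif,
                        temperature_K=temperature_K)
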