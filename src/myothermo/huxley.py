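"""Two-state crossbridge energetics (sliding-filament formalism).

The 1957 two-state scheme describes cycling myosin heads with a peak
attachment rate ``f1`` and peak detachment rates ``g1`` (head tilt up to
the step size h) and ``g2`` (tilt beyond h).  The muscle-level Hill fit
determines the rates through

    G  = f1 / g1                  (curvature)
    g1 = 2 (w/e) b / (h G)        (b in nm/s per half-sarcomere)
    g2 = 2 Vmax / h               (Vmax in nm/s per half-sarcomere)

and the molecular observables follow:

    kcat = (h / 2l) · f1 g1 / (f1 + g1)        catalytic turnover, s⁻¹
    po   = (w / l) · f1 / (f1 + g1)            unitary force, pN

The total energy-liberation rate E(V) and isotonic tension P(V) are

    E(V) = N e (h/2l) (f1/(f1+g1)) { g1 + f1 (V/Φ)(1 − e^{−Φ/V}) }
    P(V) = N (w/l) (f1/(f1+g1)) { 1 − (V/Φ)(1 − e^{−Φ/V})
                                     (1 + ½ ((f1+g1)/g2)² (V/Φ)) }

with Φ = (f1 + g1) h / 2 and N the number of cycling crossbridges.
Contractile efficiency is the ratio of mechanical work rate P·V to E;
its maximum over velocity is independent of N and bounded by w/e.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .constants import DEFAULT_CONSTANTS, CrossbridgeConstants
from .errors import AnalysisError, InvalidInputError
from .hill import HillFit


@dataclass(frozen=True)
class CrossbridgeParams:
    """Derived molecular parameters of one muscle at one time point."""

    f1: float                      # s^-1
    g1: float                      # s^-1
    g2: float                      # s^-1
    phi: float                     # nm/s, (f1+g1)h/2
    po: float                      # pN
    kcat: float                    # s^-1
    n_cb: float                    # crossbridges per mm^2
    myosin_content: float | None   # nmol/g (measured input)
    v0: float | None               # um/s (measured input)
    ts: float | None               # s, stroke time h/v0
    max_efficiency: float | None   # dimensionless fraction

    def __post_init__(self) -> None:
        if min(self.f1, self.g1, self.g2) <= 0:
            raise InvalidInputError("rate constants must be positive")

    @property
    def atpase(self) -> float | None:
        """Myosin ATPase activity = kcat × myosin content, nmol·g⁻¹·s⁻¹."""
        if self.myosin_content is None:
            return None
        return self.kcat * self.myosin_content


def rate_constants(g: float, b_nm_s: float, vmax_nm_s: float,
                   c: CrossbridgeConstants = DEFAULT_CONSTANTS
                   ) -> tuple[float, float, float]:
    """Attachment/detachment rates (f1, g1, g2) from the Hill fit.

    Parameters are the Hill curvature ``g`` and the velocity asymptote
    ``b`` and unloaded velocity ``vmax`` already converted to nm/s per
    half-sarcomere.
    """
    if min(g, b_nm_s, vmax_nm_s) <= 0:
        raise InvalidInputError(
            f"curvature and velocities must be positive, got "
            f"g={g}, b={b_nm_s}, vmax={vmax_nm_s}")
    g1 = 2.0 * c.w_over_e * b_nm_s / (c.h * g)
    f1 = g * g1
    g2 = 2.0 * vmax_nm_s / c.h
    return f1, g1, g2


def unitary_force(f1: float, g1: float,
                  c: CrossbridgeConstants = DEFAULT_CONSTANTS) -> float:
    """Unitary crossbridge force po = (w/l)·f1/(f1+g1), in pN."""
    if f1 <= 0 or g1 <= 0:
        raise InvalidInputError("f1 and g1 must be positive")
    return c.w_over_l_pN * f1 / (f1 + g1)


def catalytic_constant(f1: float, g1: float,
                       c: CrossbridgeConstants = DEFAULT_CONSTANTS) -> float:
    """Catalytic turnover kcat = (h/2l)·f1·g1/(f1+g1), in s⁻¹."""
    if f1 <= 0 or g1 <= 0:
        raise InvalidInputError("f1 and g1 must be positive")
    return (c.h / (2.0 * c.l)) * f1 * g1 / (f1 + g1)


def _phi(f1: float, g1: float, c: CrossbridgeConstants) -> float:
    return (f1 + g1) * c.h / 2.0


def _velocity_factor(v: np.ndarray, phi: float) -> np.ndarray:
    """(V/Φ)(1 − e^{−Φ/V}), with the analytic limit 0 at V = 0."""
    v = np.atleast_1d(np.asarray(v, dtype=float))
    out = np.zeros_like(v)
    pos = v > 0
    x = v[pos] / phi
    out[pos] = x * (1.0 - np.exp(-1.0 / x))
    return out


def energy_rate(v_nm_s, f1: float, g1: float, n_cb: float,
                c: CrossbridgeConstants = DEFAULT_CONSTANTS) -> np.ndarray:
    """Total energy-liberation rate E(V) in J/s for N crossbridges.

    Strictly increasing in velocity, from N·e·(h/2l)·f1g1/(f1+g1) at
    V = 0 to the plateau N·e·(h/2l)·f1 as V → ∞.
    """
    scalar = np.isscalar(v_nm_s) or np.ndim(v_nm_s) == 0
    v = np.atleast_1d(np.asarray(v_nm_s, dtype=float))
    if np.any(v < 0):
        raise InvalidInputError("velocity must be non-negative")
    phi = _phi(f1, g1, c)
    bracket = g1 + f1 * _velocity_factor(v, phi)
    res = n_cb * c.e * (c.h / (2.0 * c.l)) * (f1 / (f1 + g1)) * bracket
    return float(res[0]) if scalar else res


def tension_curve(v_nm_s, f1: float, g1: float, g2: float, n_cb: float,
                  c: CrossbridgeConstants = DEFAULT_CONSTANTS) -> np.ndarray:
    """Isotonic tension P(V) in mN/mm² for ``n_cb`` crossbridges per mm².

    P(0) = n_cb·po exactly and P decreases monotonically with velocity;
    values go negative past the unloaded velocity (callers clip for
    reporting).
    """
    scalar = np.isscalar(v_nm_s) or np.ndim(v_nm_s) == 0
    v = np.atleast_1d(np.asarray(v_nm_s, dtype=float))
    if np.any(v < 0):
        raise InvalidInputError("velocity must be non-negative")
    phi = _phi(f1, g1, c)
    braces = 1.0 - _velocity_factor(v, phi) * (
        1.0 + 0.5 * ((f1 + g1) / g2) ** 2 * (v / phi))
    po_N = c.w_over_l_pN * 1e-12 * f1 / (f1 + g1)   # N per crossbridge
    res = n_cb * po_N * braces * 1e3                # N/mm^2 -> mN/mm^2
    return float(res[0]) if scalar else res


@dataclass(frozen=True)
class EfficiencyResult:
    """Efficiency curve η(V) = P·V/E and its maximum."""

    v_grid: np.ndarray          # nm/s
    efficiency: np.ndarray
    v_opt: float                # nm/s
    max_efficiency: float
    v_root: float               # nm/s, unloaded velocity where P = 0


def efficiency_analysis(f1: float, g1: float, g2: float,
                        c: CrossbridgeConstants = DEFAULT_CONSTANTS,
                        n_grid: int = 2048) -> EfficiencyResult:
    """Contractile efficiency P(V)·V/E(V) over velocity and its maximum.

    Efficiency is independent of the crossbridge number N (it cancels),
    so the analysis is run at N = 1.  The maximum is located on a
    log-spaced grid of V/Φ ∈ [1e-3, V_root/Φ] and refined with a bounded
    scalar minimizer (relative tolerance 1e-6); ``v_root`` is the zero
    of P found by bracketing.
    """
    if min(f1, g1, g2) <= 0:
        raise InvalidInputError("rate constants must be positive")
    phi = _phi(f1, g1, c)

    def p_of_v(v):
        return tension_curve(v, f1, g1, g2, 1.0, c)

    # bracket the unloaded velocity: P(0+) > 0, P decreasing
    hi = phi
    for _ in range(60):
        if p_of_v(hi) < 0:
            break
        hi *= 2.0
    else:
        raise AnalysisError("tension curve has no positive root: "
                            "cannot bound the efficiency search interval")
    v_root = brentq(p_of_v, phi * 1e-12, hi, xtol=1e-12 * phi)

    v = np.geomspace(1e-3 * phi, v_root, n_grid)
    e = energy_rate(v, f1, g1, 1.0, c)
    # P [mN/mm^2 at N=1] * V [nm/s]: common factors cancel in the ratio,
    # restore SI so eta is the true dimensionless work fraction
    eta = (p_of_v(v) * 1e-3) * (v * 1e-9) / e
    i = int(np.argmax(eta))
    lo_b = v[max(i - 1, 0)]
    hi_b = v[min(i + 1, n_grid - 1)]

    def neg_eta(x):
        return -(p_of_v(x) * 1e-3) * (x * 1e-9) / energy_rate(x, f1, g1, 1.0, c)

    ref = minimize_scalar(neg_eta, bounds=(lo_b, hi_b), method="bounded",
                          options={"xatol": 1e-6 * phi})
    v_opt, max_eff = float(ref.x), float(-ref.fun)
    if max_eff < eta[i]:                       # keep the better of grid/refine
        v_opt, max_eff = float(v[i]), float(eta[i])
    return EfficiencyResult(v_grid=v, efficiency=eta, v_opt=v_opt,
                            max_efficiency=max_eff, v_root=float(v_root))


def derive_cb_params(hf: HillFit, v0: float | None = None,
                     myosin_content: float | None = None,
                     c: CrossbridgeConstants = DEFAULT_CONSTANTS, *,
                     vmax_measured: float | None = None,
                     compute_efficiency: bool = True) -> CrossbridgeParams:
    """Assemble the full molecular parameter set from one Hill fit.

    Velocities are converted from Lo/s to nm/s per half-sarcomere once,
    here.  ``vmax_measured`` (zero-load clamp, Lo/s) takes precedence
    over the fitted zero-tension velocity for the g2 closure, mirroring
    the experimental protocol.  The crossbridge number per mm² is the
    ratio of isometric tension to unitary force, N = To/po.  The sliding
    velocity ``v0`` (µm/s) and myosin content (nmol/g) are measured
    inputs passed through; the stroke time ts = h/v0 when v0 is given.
    """
    vmax_lo_s = vmax_measured if vmax_measured is not None else hf.vmax
    b_nm = c.lo_per_s_to_nm_per_s(hf.b)
    vmax_nm = c.lo_per_s_to_nm_per_s(vmax_lo_s)
    f1, g1, g2 = rate_constants(hf.g, b_nm, vmax_nm, c)
    po = unitary_force(f1, g1, c)
    kcat = catalytic_constant(f1, g1, c)
    n_cb = (hf.to * 1e-3) / (po * 1e-12)        # (N/mm^2) / N
    ts = c.h / (v0 * 1e3) if v0 else None       # um/s -> nm/s
    max_eff = (efficiency_analysis(f1, g1, g2, c).max_efficiency
               if compute_efficiency else None)
    return CrossbridgeParams(
        f1=f1, g1=g1, g2=g2, phi=_phi(f1, g1, c), po=po, kcat=kcat,
        n_cb=n_cb, myosin_content=myosin_content, v0=v0, ts=ts,
        max_efficiency=max_eff)
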