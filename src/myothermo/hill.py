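"""Hill force–velocity mechanics.

An afterloaded tension–velocity (T–V) curve of cardiac papillary muscle
is hyperbolic and is summarised by Hill's relation

    (T + a)(V + b) = (To + a) b

where ``To`` is the peak isometric tension and ``-a`` (tension axis) and
``-b`` (velocity axis) are the asymptotes.  The dimensionless curvature

    G = To / a = Vmax / b

links the muscle-level fit to the crossbridge rate constants, and the
fitted zero-tension velocity Vmax = b·G is the curve's intercept with the
velocity axis.  Shortening velocities are positive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitFailureError, InvalidInputError

ANOXIA_TIMES = (0, 30, 60, 90, 120, 150, 180)
RECOVERY_TIMES = (30, 60, 90)

#: CSV column names of the afterload-point table.
TV_CSV_COLUMNS = ("muscle_id", "phase", "time_min",
                  "tension_mN_mm2", "velocity_Lo_s", "lo_mm")


@dataclass(frozen=True)
class TVPoint:
    """One afterloaded contraction: tension (mN/mm²), velocity (Lo/s)."""

    tension: float
    velocity: float

    def __post_init__(self) -> None:
        if self.tension < 0 or self.velocity < 0:
            raise InvalidInputError(
                f"tension and velocity must be non-negative, got "
                f"({self.tension}, {self.velocity})")


@dataclass
class TVDataset:
    """Afterloaded T–V points of one muscle at one protocol time.

    ``points`` must hold at least 5 afterload levels spanning zero load
    to the isometric contraction, exactly one of which is the isometric
    point (velocity 0).  ``vmax_measured`` is the independently measured
    unloaded shortening velocity (zero-load clamp), if available.
    """

    muscle_id: str
    phase: str
    time_min: int
    points: list[TVPoint] = field(default_factory=list)
    vmax_measured: float | None = None
    lo_mm: float | None = None

    def __post_init__(self) -> None:
        if self.phase not in ("anoxia", "recovery"):
            raise InvalidInputError(f"unknown phase {self.phase!r}")
        allowed = ANOXIA_TIMES if self.phase == "anoxia" else RECOVERY_TIMES
        if self.time_min not in allowed:
            raise InvalidInputError(
                f"time {self.time_min} min not in protocol times {allowed} "
                f"for phase {self.phase!r}")
        if len(self.points) < 5:
            raise InvalidInputError(
                f"{self.label}: need >= 5 afterload points, "
                f"got {len(self.points)}")
        n_iso = sum(1 for p in self.points if p.velocity == 0)
        if n_iso != 1:
            raise InvalidInputError(
                f"{self.label}: expected exactly one isometric point "
                f"(velocity 0), found {n_iso}")

    @property
    def label(self) -> str:
        return f"{self.muscle_id}/{self.phase}@{self.time_min}min"

    @property
    def isometric_tension(self) -> float:
        """Tension of the (unique) zero-velocity point, mN/mm²."""
        return next(p.tension for p in self.points if p.velocity == 0)

    def tensions(self) -> np.ndarray:
        return np.array([p.tension for p in self.points])

    def velocities(self) -> np.ndarray:
        return np.array([p.velocity for p in self.points])


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill hyperbola of one T–V dataset.

    ``vmax`` is the fitted curve's zero-tension velocity b·To/a; the
    independently measured unloaded velocity lives on the dataset.
    """

    a: float
    b: float
    to: float
    vmax: float
    g: float
    r2: float

    def tension_at(self, velocity: float | np.ndarray) -> np.ndarray:
        """Tension predicted by the fitted hyperbola at ``velocity``."""
        v = np.asarray(velocity, dtype=float)
        return (self.to + self.a) * self.b / (v + self.b) - self.a


def hill_tension(velocity: np.ndarray, a: float, b: float,
                 to: float) -> np.ndarray:
    """T(V) = (To + a)·b/(V + b) − a, the hyperbola solved for tension."""
    v = np.asarray(velocity, dtype=float)
    return (to + a) * b / (v + b) - a


def hill_velocity(tension: np.ndarray, a: float, b: float,
                  to: float) -> np.ndarray:
    """V(T) = b·(To − T)/(T + a), the hyperbola solved for velocity."""
    t = np.asarray(tension, dtype=float)
    return b * (to - t) / (t + a)


def fit_hill(dataset: TVDataset, *, fix_to: bool = True,
             a0: float | None = None, b0: float | None = None) -> HillFit:
    """Fit the Hill hyperbola to an afterloaded T–V dataset.

    Nonlinear least squares on tension residuals of
    T(V) = (To + a)·b/(V + b) − a.  By default ``To`` is fixed to the
    measured isometric point's tension and only the asymptotes (a, b)
    are free; with ``fix_to=False`` all three parameters are estimated.

    Starting values default to the classical heuristic a₀ = To/4 and
    b₀ = Vmax/4 (measured Vmax when available, else the largest observed
    velocity).

    Returns
    -------
    HillFit
        With curvature g = To/a and fitted zero-tension velocity
        vmax = b·g, and r² computed on tension residuals.

    Raises
    ------
    InvalidInputError
        Fewer than 5 points (raised on dataset construction).
    FitFailureError
        Non-convergence or a non-positive asymptote estimate; the
        message names the muscle and time point.
    """
    t_obs = dataset.tensions()
    v_obs = dataset.velocities()
    to_meas = dataset.isometric_tension

    vref = dataset.vmax_measured if dataset.vmax_measured else float(v_obs.max())
    a_init = a0 if a0 is not None else max(to_meas / 4.0, 1e-6)
    b_init = b0 if b0 is not None else max(vref / 4.0, 1e-6)

    if fix_to:
        def resid(theta):
            return hill_tension(v_obs, theta[0], theta[1], to_meas) - t_obs
        x0 = [a_init, b_init]
    else:
        def resid(theta):
            return hill_tension(v_obs, theta[0], theta[1], theta[2]) - t_obs
        x0 = [a_init, b_init, to_meas]

    sol = least_squares(resid, x0, bounds=(1e-12, np.inf),
                        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise FitFailureError(
            f"Hill fit did not converge for {dataset.label}: {sol.message}")
    a_hat, b_hat = float(sol.x[0]), float(sol.x[1])
    to_hat = to_meas if fix_to else float(sol.x[2])
    # estimates pinned at the positivity bound signal a non-hyperbolic set
    if a_hat <= 1e-8 or b_hat <= 1e-8 or to_hat <= 1e-8:
        raise FitFailureError(
            f"Hill fit for {dataset.label} produced non-positive "
            f"estimates a={a_hat:.3g}, b={b_hat:.3g}, To={to_hat:.3g}")

    t_hat = hill_tension(v_obs, a_hat, b_hat, to_hat)
    ss_res = float(np.sum((t_obs - t_hat) ** 2))
    ss_tot = float(np.sum((t_obs - t_obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    g = to_hat / a_hat
    return HillFit(a=a_hat, b=b_hat, to=to_hat, vmax=b_hat * g, g=g, r2=r2)


def fit_cohort(datasets: Iterable[TVDataset], **kwargs) -> pd.DataFrame:
    """Fit every dataset; one row of HillFit fields per muscle × time."""
    rows = []
    for ds in datasets:
        hf = fit_hill(ds, **kwargs)
        rows.append({"muscle_id": ds.muscle_id, "phase": ds.phase,
                     "time_min": ds.time_min, "a": hf.a, "b": hf.b,
                     "to": hf.to, "vmax_fitted": hf.vmax, "g": hf.g,
                     "r2": hf.r2, "vmax_measured": ds.vmax_measured})
    return pd.DataFrame(rows)


def datasets_from_frame(points: pd.DataFrame,
                        aux: pd.DataFrame | None = None) -> list[TVDataset]:
    """Group a long afterload-point table into TVDataset objects.

    ``points`` follows :data:`TV_CSV_COLUMNS`.  ``aux``, if given, is a
    per-muscle × time table with a ``vmax_Lo_s`` column attached as the
    measured unloaded velocity.
    """
    missing = set(TV_CSV_COLUMNS) - set(points.columns)
    if missing:
        raise InvalidInputError(f"input table lacks columns {sorted(missing)}")
    vmax_lookup: dict[tuple, float] = {}
    if aux is not None and "vmax_Lo_s" in aux.columns:
        for _, r in aux.iterrows():
            vmax_lookup[(str(r["muscle_id"]), r["phase"],
                         int(r["time_min"]))] = float(r["vmax_Lo_s"])
    out = []
    for (mid, phase, t), grp in points.groupby(
            ["muscle_id", "phase", "time_min"], sort=True):
        pts = [TVPoint(float(r.tension_mN_mm2), float(r.velocity_Lo_s))
               for r in grp.itertuples()]
        lo = float(grp["lo_mm"].iloc[0]) if grp["lo_mm"].notna().any() else None
        out.append(TVDataset(
            muscle_id=str(mid), phase=str(phase), time_min=int(t),
            points=pts, lo_mm=lo,
            vmax_measured=vmax_lookup.get((str(mid), str(phase), int(t)))))
    return out


def read_tv_csv(points_path, aux_path=None) -> list[TVDataset]:
    """Read afterload points (and optional per-muscle aux table) from CSV."""
    points = pd.read_csv(points_path)
    aux = pd.read_csv(aux_path) if aux_path is not None else None
    return datasets_from_frame(points, aux)


def sample_hyperbola(a: float, b: float, to: float, n_points: int = 9,
                     fractions: Sequence[float] | None = None) -> TVDataset:
    """Noise-free T–V points on an exact Hill hyperbola (test helper).

    Tensions sit at equal fractions 0 … 1 of ``To`` unless ``fractions``
    is given; velocities follow from the hyperbola.
    """
    fr = np.linspace(0, 1, n_points) if fractions is None else np.asarray(fractions)
    t = fr * to
    v = hill_velocity(t, a, b, to)
    pts = [TVPoint(float(ti), float(max(vi, 0.0))) for ti, vi in zip(t, v)]
    return TVDataset(muscle_id="synthetic", phase="anoxia", time_min=0,
                     points=pts, vmax_measured=b * to / a)
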