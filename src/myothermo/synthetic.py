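"""Seeded synthetic cohorts of afterloaded papillary-muscle experiments.

The generator emulates the study design: a cohort of muscles (default
20), each followed through seven anoxia time points (0–180 min, every
30 min) and three oxygen-recovery points (r30–r90), with 8–10 afterload
contractions per time point.  Per-parameter trajectory means default to
the packaged reference-cohort tables; muscle- and time-level biological
variability is log-normal (positivity is guaranteed at coefficients of
variation up to ~0.4, matching the published SD/mean ratios), with a
single muscle-level random effect providing within-muscle correlation
across time points.  Measurement noise is additive Gaussian on tension.

Because the hyperbola parameters (To, G, b) are drawn explicitly and
the afterload points are synthesized exactly on the resulting Hill
curve, every generated cohort carries a ground-truth record of both the
drawn muscle-level parameters and the forward-derived crossbridge
parameters (f1, g1, g2, po, kcat), enabling end-to-end parameter
recovery tests with no external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, CrossbridgeConstants
from .errors import InvalidInputError
from .hill import (ANOXIA_TIMES, RECOVERY_TIMES, TV_CSV_COLUMNS, TVDataset,
                   TVPoint, hill_velocity)
from .huxley import catalytic_constant, rate_constants, unitary_force
from .tables import load_reference_cohort

#: trajectory parameters drawn per muscle × time
TRAJECTORY_PARAMS = ("to", "g", "b", "vmax", "v0", "myosin_content")


@dataclass
class CohortSpec:
    """Design of a synthetic cohort.

    ``trajectory`` maps each of :data:`TRAJECTORY_PARAMS` to a mean
    curve over the concatenated (anoxia, recovery) time points; ``cv``
    is the per-parameter biological coefficient of variation (a scalar
    applies to all), split between a muscle-level random effect and
    independent per-time variation by ``between_muscle_fraction`` (the
    fraction of log-variance shared within a muscle).
    """

    n_muscles: int = 20
    times: tuple[int, ...] = ANOXIA_TIMES
    recovery_times: tuple[int, ...] = RECOVERY_TIMES
    trajectory: dict[str, np.ndarray] = field(default_factory=dict)
    cv: float | dict[str, float] = 0.3
    between_muscle_fraction: float = 0.5
    noise_sd_tension: float = 0.25
    seed: int = 0
    n_afterloads: int = 9
    lo_mm: float = 5.0

    def validate(self) -> None:
        problems = []
        if self.n_muscles < 3:
            problems.append(f"n_muscles={self.n_muscles} (need >= 3)")
        if self.n_afterloads < 5:
            problems.append(f"n_afterloads={self.n_afterloads} (need >= 5)")
        if self.noise_sd_tension < 0:
            problems.append("noise_sd_tension < 0")
        if not 0 <= self.between_muscle_fraction <= 1:
            problems.append("between_muscle_fraction outside [0, 1]")
        n_rows = len(self.times) + len(self.recovery_times)
        for p in TRAJECTORY_PARAMS:
            if p not in self.trajectory:
                problems.append(f"trajectory missing {p!r}")
                continue
            arr = np.asarray(self.trajectory[p], dtype=float)
            if len(arr) != n_rows:
                problems.append(f"trajectory[{p!r}] has {len(arr)} values, "
                                f"expected {n_rows}")
            elif np.any(arr <= 0):
                problems.append(f"trajectory[{p!r}] must be positive")
            if self.cv_for(p) < 0:
                problems.append(f"cv[{p!r}] < 0")
        if problems:
            raise InvalidInputError(
                "invalid cohort spec: " + "; ".join(problems))

    def cv_for(self, param: str) -> float:
        if isinstance(self.cv, dict):
            return float(self.cv.get(param, 0.0))
        return float(self.cv)

    @property
    def schedule(self) -> list[tuple[str, int]]:
        """(phase, time) rows in protocol order, anoxia then recovery."""
        return ([("anoxia", t) for t in self.times]
                + [("recovery", t) for t in self.recovery_times])


def default_cohort_spec(seed: int = 0, *, cv: float | dict[str, float] = 0.3,
                        n_muscles: int = 20,
                        noise_sd_tension: float = 0.25,
                        c: CrossbridgeConstants = DEFAULT_CONSTANTS
                        ) -> CohortSpec:
    """Cohort spec whose trajectory means track the reference tables.

    To, Vmax, v0 and myosin content come straight from the tabulated
    column means.  The hyperbola shape parameters G and b, which the
    tables do not list, are back-derived from the tabulated rate
    constants (G = f1/g1; b = g1·h·G/(2·w/e) per half-sarcomere), so
    forward-derived ground-truth rate constants coincide with the
    tabulated means.  Vmax is carried as a separate measured trajectory
    (the tabulated column), preserving the published mean-of-ratios vs
    ratio-of-means discrepancy (Vmax ≠ G·b on the means).
    """
    ref = load_reference_cohort(phase=None)
    g_traj = ref["f1_mean"] / ref["g1_mean"]
    b_nm = ref["g1_mean"] * c.h * g_traj / (2.0 * c.w_over_e)
    trajectory = {
        "to": ref["tension_mean"].to_numpy(float),
        "g": g_traj.to_numpy(float),
        "b": (b_nm / (c.half_sarcomere_um * 1e3)).to_numpy(float),  # Lo/s
        "vmax": ref["vmax_mean"].to_numpy(float),
        "v0": ref["v0_mean"].to_numpy(float),
        "myosin_content": ref["myosin_content_mean"].to_numpy(float),
    }
    return CohortSpec(n_muscles=n_muscles, trajectory=trajectory, cv=cv,
                      noise_sd_tension=noise_sd_tension, seed=seed)


@dataclass
class SyntheticCohort:
    """Generated cohort: T–V datasets, per-muscle series, ground truth."""

    spec: CohortSpec
    datasets: list[TVDataset]
    aux: pd.DataFrame           # muscle_id, phase, time_min, v0, MC, vmax
    ground_truth: pd.DataFrame  # drawn + forward-derived parameters

    def points_frame(self) -> pd.DataFrame:
        """Long afterload-point table in the pipeline's CSV schema."""
        rows = []
        for ds in self.datasets:
            for p in ds.points:
                rows.append((ds.muscle_id, ds.phase, ds.time_min,
                             p.tension, p.velocity, ds.lo_mm))
        return pd.DataFrame(rows, columns=TV_CSV_COLUMNS)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write points CSV, aux CSV and ground-truth JSON sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "points": outdir / "tv_points.csv",
            "aux": outdir / "muscle_series.csv",
            "ground_truth": outdir / "ground_truth.json",
        }
        self.points_frame().to_csv(paths["points"], index=False)
        self.aux.to_csv(paths["aux"], index=False)
        gt = {
            "spec": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                     for k, v in asdict(self.spec).items()
                     if k != "trajectory"},
            "trajectory": {k: np.asarray(v).tolist()
                           for k, v in self.spec.trajectory.items()},
            "records": self.ground_truth.to_dict(orient="records"),
        }
        paths["ground_truth"].write_text(json.dumps(gt, indent=1))
        return paths


def _lognormal_factors(rng: np.random.Generator, sigma: float,
                       size) -> np.ndarray:
    """Unit-mean log-normal multipliers with log-SD ``sigma``."""
    if sigma == 0:
        return 1.0 if size is None else np.ones(size)
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


def generate_cohort(spec: CohortSpec,
                    c: CrossbridgeConstants = DEFAULT_CONSTANTS
                    ) -> SyntheticCohort:
    """Draw a seeded synthetic cohort.

    Per muscle and time point, (To, G, b, Vmax, v0, myosin content) are
    drawn log-normally around the trajectory means with the spec's CV —
    a muscle-level multiplier shared across time points supplies the
    within-muscle correlation — after which ``n_afterloads`` T–V points
    are synthesized exactly on the Hill hyperbola at equal tension
    fractions 0 … 1 of To and Gaussian tension noise is added (the
    zero-velocity isometric point keeps a velocity of exactly 0, and
    noisy tensions are clipped at 0).  Identical seeds give identical
    cohorts.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    schedule = spec.schedule
    n_rows = len(schedule)

    # per-parameter log-SDs, split muscle-level vs time-level
    sig = {p: np.sqrt(np.log1p(spec.cv_for(p) ** 2)) for p in TRAJECTORY_PARAMS}
    frac = spec.between_muscle_fraction

    datasets: list[TVDataset] = []
    aux_rows, gt_rows = [], []
    fractions = np.linspace(0.0, 1.0, spec.n_afterloads)

    for m in range(spec.n_muscles):
        mid = f"m{m + 1:02d}"
        muscle_eff = {p: _lognormal_factors(rng, sig[p] * np.sqrt(frac), None)
                      for p in TRAJECTORY_PARAMS}
        for row, (phase, t) in enumerate(schedule):
            drawn = {}
            for p in TRAJECTORY_PARAMS:
                mean = float(np.asarray(spec.trajectory[p], dtype=float)[row])
                eps = _lognormal_factors(rng, sig[p] * np.sqrt(1 - frac), None)
                drawn[p] = mean * float(muscle_eff[p]) * float(eps)

            to, g, b = drawn["to"], drawn["g"], drawn["b"]
            a = to / g
            tensions = fractions * to
            velocities = hill_velocity(tensions, a, b, to)
            if spec.noise_sd_tension > 0:
                tensions = tensions + rng.normal(
                    0.0, spec.noise_sd_tension, size=spec.n_afterloads)
                tensions = np.clip(tensions, 0.0, None)
            # the isometric contraction is the zero-velocity point
            velocities[-1] = 0.0
            points = [TVPoint(float(ti), float(max(vi, 0.0)))
                      for ti, vi in zip(tensions, velocities)]
            datasets.append(TVDataset(
                muscle_id=mid, phase=phase, time_min=t, points=points,
                vmax_measured=drawn["vmax"], lo_mm=spec.lo_mm))
            aux_rows.append((mid, phase, t, drawn["v0"],
                             drawn["myosin_content"], drawn["vmax"]))

            f1, g1, g2 = rate_constants(
                g, c.lo_per_s_to_nm_per_s(b),
                c.lo_per_s_to_nm_per_s(drawn["vmax"]), c)
            gt_rows.append({
                "muscle_id": mid, "phase": phase, "time_min": t,
                "to": to, "g": g, "b": b, "vmax": drawn["vmax"],
                "v0": drawn["v0"], "myosin_content": drawn["myosin_content"],
                "f1": f1, "g1": g1, "g2": g2,
                "po": unitary_force(f1, g1, c),
                "kcat": catalytic_constant(f1, g1, c),
            })

    aux = pd.DataFrame(aux_rows, columns=[
        "muscle_id", "phase", "time_min", "v0_um_s",
        "myosin_content_nmol_g", "vmax_Lo_s"])
    return SyntheticCohort(spec=spec, datasets=datasets, aux=aux,
                           ground_truth=pd.DataFrame(gt_rows))
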