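"""End-to-end orchestration: input → Hill fits → crossbridge parameters
→ cohort summary → thermodynamic/bifurcation report.

Three input modes are supported, exactly one per run:

* ``input_csv`` (+ ``aux_csv``) — measured afterload points and the
  per-muscle (v0, myosin content, Vmax) series;
* ``synthetic`` — a seeded :class:`~myothermo.synthetic.CohortSpec`;
* ``fixtures`` — the packaged reference-cohort summary tables, in which
  case the per-muscle stages are skipped and the thermodynamic analysis
  runs directly on the published cohort means.

Cohort summaries report mean ± SD of the per-muscle derived quantities
(the published tables average per-muscle ratios, so e.g. the summary's
mean Vmax need not equal the mean G × mean b; the report carries both
routes).  Every fitted coefficient and resolved configuration default is
recorded in the report bundle, and a MANIFEST lists completed stages so
partial output of a failed run remains interpretable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import hill, synthetic
from .constants import DEFAULT_CONSTANTS, CrossbridgeConstants
from .errors import InvalidInputError
from .huxley import derive_cb_params
from .tables import load_reference_cohort
from .thermo import ThermoReport, analyze_thermodynamics

log = logging.getLogger("myothermo")

#: cohort-summary columns mirroring the published tables
SUMMARY_COLUMNS = ("vmax", "to", "f1", "g1", "g2", "myosin_content", "v0",
                   "max_efficiency_pct", "po")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    input_csv: str | None = None
    aux_csv: str | None = None
    synthetic: synthetic.CohortSpec | None = None
    fixtures: bool = False
    constants: CrossbridgeConstants = field(default_factory=lambda: DEFAULT_CONSTANTS)
    fix_to: bool = True
    seed: int = 0
    outdir: str | None = None
    make_plots: bool = False

    def __post_init__(self) -> None:
        sources = [self.input_csv is not None, self.synthetic is not None,
                   bool(self.fixtures)]
        if sum(sources) != 1:
            raise InvalidInputError(
                "exactly one input source required: input_csv, synthetic "
                "spec, or fixtures")

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "input_csv": self.input_csv, "aux_csv": self.aux_csv,
            "fixtures": self.fixtures, "fix_to": self.fix_to,
            "seed": self.seed, "outdir": self.outdir,
            "make_plots": self.make_plots,
            "constants": {k: getattr(self.constants, k) for k in
                          ("h", "l", "e", "w_over_e", "half_sarcomere_um",
                           "temperature_K")},
        }
        if self.synthetic is not None:
            d["synthetic"] = {
                "n_muscles": self.synthetic.n_muscles,
                "cv": self.synthetic.cv,
                "noise_sd_tension": self.synthetic.noise_sd_tension,
                "n_afterloads": self.synthetic.n_afterloads,
                "seed": self.synthetic.seed,
            }
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Build a config from a YAML file.

        Recognized keys: ``input_csv``, ``aux_csv``, ``fixtures``,
        ``synthetic: {n_muscles, cv, noise_sd_tension, seed}``,
        ``constants: {h, l, e, w_over_e, half_sarcomere_um,
        temperature_K}``, ``fix_to``, ``seed``, ``outdir``,
        ``make_plots``.
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        const = CrossbridgeConstants(**raw.pop("constants", {}))
        spec = None
        if "synthetic" in raw:
            syn = raw.pop("synthetic") or {}
            spec = synthetic.default_cohort_spec(
                seed=syn.get("seed", raw.get("seed", 0)),
                cv=syn.get("cv", 0.3),
                n_muscles=syn.get("n_muscles", 20),
                noise_sd_tension=syn.get("noise_sd_tension", 0.25),
                c=const)
        return cls(constants=const, synthetic=spec, **raw)


@dataclass
class PipelineResult:
    """Bundle returned by :func:`run_pipeline`."""

    config: dict[str, Any]
    hill_fits: pd.DataFrame | None
    cb_params: pd.DataFrame | None
    cohort_summary: pd.DataFrame
    thermo: ThermoReport
    stages_completed: list[str]
    output_paths: dict[str, str] = field(default_factory=dict)

    def report_dict(self) -> dict[str, Any]:
        return {"config": self.config,
                "stages_completed": self.stages_completed,
                "thermo": self.thermo.to_dict()}

    def report_hash(self) -> str:
        """Stable digest of the report content (determinism checks).

        The output directory is excluded so identical analyses written
        to different locations hash identically."""
        d = self.report_dict()
        d["config"] = {k: v for k, v in d["config"].items() if k != "outdir"}
        payload = json.dumps(d, sort_keys=True)
        if self.cohort_summary is not None:
            payload += self.cohort_summary.to_csv(index=False)
        return hashlib.sha256(payload.encode()).hexdigest()


def derive_cohort_params(hill_fits: pd.DataFrame, aux: pd.DataFrame,
                         c: CrossbridgeConstants = DEFAULT_CONSTANTS, *,
                         compute_efficiency: bool = True) -> pd.DataFrame:
    """Crossbridge parameters for every fitted muscle × time point."""
    merged = hill_fits.merge(aux, on=["muscle_id", "phase", "time_min"],
                             how="left", validate="1:1")
    rows = []
    for r in merged.itertuples():
        hf = hill.HillFit(a=r.a, b=r.b, to=r.to, vmax=r.vmax_fitted,
                          g=r.g, r2=r.r2)
        vmax_meas = getattr(r, "vmax_Lo_s", None)
        if vmax_meas is None or pd.isna(vmax_meas):
            vmax_meas = r.vmax_measured if not pd.isna(r.vmax_measured) else None
        v0 = getattr(r, "v0_um_s", None)
        mc = getattr(r, "myosin_content_nmol_g", None)
        cb = derive_cb_params(
            hf, v0=None if v0 is None or pd.isna(v0) else float(v0),
            myosin_content=None if mc is None or pd.isna(mc) else float(mc),
            c=c, vmax_measured=vmax_meas,
            compute_efficiency=compute_efficiency)
        rows.append({
            "muscle_id": r.muscle_id, "phase": r.phase,
            "time_min": r.time_min,
            "vmax": vmax_meas if vmax_meas is not None else hf.vmax,
            "to": hf.to, "f1": cb.f1, "g1": cb.g1, "g2": cb.g2,
            "phi": cb.phi, "po": cb.po, "kcat": cb.kcat, "n_cb": cb.n_cb,
            "myosin_content": cb.myosin_content, "v0": cb.v0,
            "atpase": cb.atpase,
            "max_efficiency_pct": (100 * cb.max_efficiency
                                   if cb.max_efficiency is not None else None),
        })
    return pd.DataFrame(rows)


def summarize_cohort(cb_params: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD per phase × time of the derived per-muscle quantities."""
    out = []
    for (phase, t), grp in cb_params.groupby(["phase", "time_min"], sort=True):
        row: dict[str, Any] = {"phase": phase, "time_min": t,
                               "n": len(grp)}
        for col in SUMMARY_COLUMNS:
            if col in grp and grp[col].notna().any():
                row[f"{col}_mean"] = float(grp[col].mean())
                row[f"{col}_sd"] = float(grp[col].std(ddof=1))
        out.append(row)
    df = pd.DataFrame(out)
    order = df["phase"].map({"anoxia": 0, "recovery": 1})
    return (df.assign(_o=order).sort_values(["_o", "time_min"])
            .drop(columns="_o").reset_index(drop=True))


def _fixture_summary() -> pd.DataFrame:
    """Reference-table means recast in the cohort-summary schema."""
    ref = load_reference_cohort(phase=None)
    return pd.DataFrame({
        "phase": ref["phase"], "time_min": ref["time_min"], "n": 20,
        "vmax_mean": ref["vmax_mean"], "vmax_sd": ref["vmax_sd"],
        "to_mean": ref["tension_mean"], "to_sd": ref["tension_sd"],
        "f1_mean": ref["f1_mean"], "f1_sd": ref["f1_sd"],
        "g1_mean": ref["g1_mean"], "g1_sd": ref["g1_sd"],
        "g2_mean": ref["g2_mean"], "g2_sd": ref["g2_sd"],
        "myosin_content_mean": ref["myosin_content_mean"],
        "myosin_content_sd": ref["myosin_content_sd"],
        "v0_mean": ref["v0_mean"], "v0_sd": ref["v0_sd"],
        "max_efficiency_pct_mean": ref["max_efficiency_pct_mean"],
        "max_efficiency_pct_sd": ref["max_efficiency_pct_sd"],
        "po_mean": ref["cb_force_mean"], "po_sd": ref["cb_force_sd"],
    })


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full pipeline for one configuration.

    Writes (when ``cfg.outdir`` is set) ``hill_fits.csv``,
    ``cb_params.csv``, ``cohort_summary.csv``, ``thermo_report.json``,
    optional figure files, and ``MANIFEST.json``; on a stage failure the
    MANIFEST still lists the completed stages before the error is
    re-raised.
    """
    stages: list[str] = []
    paths: dict[str, str] = {}
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def _manifest():
        if outdir:
            (outdir / "MANIFEST.json").write_text(json.dumps(
                {"stages_completed": stages, "outputs": paths,
                 "config": cfg.config_dict}, indent=1, default=str))

    cfg.config_dict = cfg.to_dict()  # resolved config, recorded everywhere
    try:
        hill_fits = cb_params = None
        if cfg.fixtures:
            summary = _fixture_summary()
            stages.append("fixtures")
        else:
            if cfg.synthetic is not None:
                cohort = synthetic.generate_cohort(cfg.synthetic,
                                                   cfg.constants)
                datasets, aux = cohort.datasets, cohort.aux
                if outdir:
                    for k, p in cohort.write(outdir / "synthetic").items():
                        paths[f"synthetic_{k}"] = str(p)
                stages.append("simulate")
            else:
                if not Path(cfg.input_csv).exists():
                    raise InvalidInputError(
                        f"input file not found: {cfg.input_csv}")
                datasets = hill.read_tv_csv(cfg.input_csv, cfg.aux_csv)
                aux = (pd.read_csv(cfg.aux_csv)
                       if cfg.aux_csv else pd.DataFrame(
                           columns=["muscle_id", "phase", "time_min"]))
                stages.append("load")
            hill_fits = hill.fit_cohort(datasets, fix_to=cfg.fix_to)
            log.info("fitted %d Hill curves", len(hill_fits))
            stages.append("fit")
            cb_params = derive_cohort_params(hill_fits, aux, cfg.constants)
            stages.append("crossbridge")
            summary = summarize_cohort(cb_params)
        stages.append("summary")

        anox = summary[summary["phase"] == "anoxia"]
        thermo = analyze_thermodynamics(
            times=anox["time_min"].to_numpy(float),
            v0=anox["v0_mean"].to_numpy(float),
            myosin_content=anox["myosin_content_mean"].to_numpy(float),
            po=anox["po_mean"].to_numpy(float),
            temperature_K=cfg.constants.temperature_K)
        stages.append("thermo")

        if outdir:
            if hill_fits is not None:
                hill_fits.to_csv(outdir / "hill_fits.csv", index=False)
                paths["hill_fits"] = str(outdir / "hill_fits.csv")
            if cb_params is not None:
                cb_params.to_csv(outdir / "cb_params.csv", index=False)
                paths["cb_params"] = str(outdir / "cb_params.csv")
            summary.to_csv(outdir / "cohort_summary.csv", index=False)
            paths["cohort_summary"] = str(outdir / "cohort_summary.csv")
            report = {"config": cfg.config_dict,
                      "stages_completed": stages + ["report"],
                      "thermo": thermo.to_dict()}
            (outdir / "thermo_report.json").write_text(
                json.dumps(report, indent=1))
            paths["thermo_report"] = str(outdir / "thermo_report.json")
            if cfg.make_plots:
                from . import plots
                paths.update({k: str(v) for k, v in
                              plots.render_all(thermo, outdir).items()})
                stages.append("plots")
        stages.append("report")
        return PipelineResult(config=cfg.config_dict, hill_fits=hill_fits,
                              cb_params=cb_params, cohort_summary=summary,
                              thermo=thermo, stages_completed=stages,
                              output_paths=paths)
    finally:
        _manifest()
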