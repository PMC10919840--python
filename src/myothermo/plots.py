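"""Diagnostic figures for the thermodynamic report.

Three panels mirror the analysis: the force/flow/EPR time courses, the
phase plane (dEPR/dt against EPR with the fitted relation), and the
bifurcation branch (EPR against the unitary force Ψ = po).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .thermo import ThermoReport


def _mpl():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_time_series(report: ThermoReport, path: str | Path) -> Path:
    plt = _mpl()
    s = report.series
    fig, axes = plt.subplots(3, 1, figsize=(5, 8), sharex=True)
    axes[0].plot(s.times, s.force, "o-")
    axes[0].set_ylabel("force\n(nmol g$^{-1}$ K$^{-1}$)")
    axes[1].plot(s.times, s.flow, "o-")
    axes[1].set_ylabel("flow $v_0$ (µm/s)")
    axes[2].plot(s.times, s.epr, "o", label="observed")
    tt = np.linspace(*report.polyfit.domain, 200)
    axes[2].plot(tt, report.polyfit(tt), "-",
                 label=f"cubic fit (r²={report.polyfit.r2:.2f})")
    axes[2].set_ylabel("EPR")
    axes[2].set_xlabel("anoxia time (min)")
    axes[2].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_phase_diagram(report: ThermoReport, path: str | Path) -> Path:
    plt = _mpl()
    s = report.series
    yp = report.polyfit.derivative(s.times)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(s.epr, yp, "o", label="observed times")
    grid = np.linspace(yp.min(), yp.max(), 200)
    ax.plot(report.phase.curve(grid), grid, "-", lw=1,
            label=f"cubic (r²={report.phase.r2_phase:.2f})")
    ax.axhline(0, color="k", lw=0.5)
    fp = report.fixed_point
    ax.plot([fp.y_star], [0], "rs",
            label=f"fixed point ({fp.klass}, λ={fp.lam:.3g})")
    ax.set_xlabel("y = EPR")
    ax.set_ylabel("y′ = dEPR/dt (min$^{-1}$)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_bifurcation_diagram(report: ThermoReport, path: str | Path) -> Path:
    plt = _mpl()
    b = report.bifurcation
    po, y = zip(*b.branch)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(po, y, "o-")
    if b.detected:
        ax.plot([b.psi_star], [max(y)], "r^", ms=10,
                label=f"Ψ* = {b.psi_star:.2f} pN at t* = {b.t_star:.0f} min")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("Ψ = po (pN)")
    ax.set_ylabel("y = EPR")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def render_all(report: ThermoReport, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return {
        "fig_time_series": plot_time_series(report, outdir / "time_series.png"),
        "fig_phase": plot_phase_diagram(report, outdir / "phase_diagram.png"),
        "fig_bifurcation": plot_bifurcation_diagram(
            report, outdir / "bifurcation_diagram.png"),
    }
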