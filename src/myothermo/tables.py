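"""Packaged reference cohort tables.

The published study reports only cohort summaries (mean ± SD over 20
papillary muscles) of the mechanical and energetic indices at each time
point of a 3 h anoxia protocol (0–180 min, every 30 min) and a 90 min
oxygen-recovery phase (r30–r90).  Those summary tables ship with the
package as TSV fixtures and drive both the fixture analysis mode and the
default synthetic-cohort trajectories.

Columns
-------
``table1_mechanics.tsv``
    vmax (Lo/s), isometric tension (mN/mm²), crossbridge attachment rate
    f1 and detachment rates g1, g2 (s⁻¹): mean and SD per phase × time.
``table2_energetics.tsv``
    myosin content (nmol/g), crossbridge sliding velocity v0 (µm/s),
    maximum contractile efficiency (%), unitary crossbridge force (pN).
``significance_markers.tsv``
    the published paired-contrast markers, carried for reference only —
    per-animal data are not published, so the underlying statistics are
    not reproducible and are out of scope here.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA_PKG = "myothermo.data"


def _read(name: str) -> pd.DataFrame:
    with resources.files(_DATA_PKG).joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_mechanics_table() -> pd.DataFrame:
    """Cohort mean ± SD of Vmax, tension and rate constants."""
    return _read("table1_mechanics.tsv")


def load_energetics_table() -> pd.DataFrame:
    """Cohort mean ± SD of myosin content, v0, efficiency and po."""
    return _read("table2_energetics.tsv")


def load_significance_markers() -> pd.DataFrame:
    """Published paired-contrast markers (reference only)."""
    return _read("significance_markers.tsv")


def load_reference_cohort(phase: str | None = "anoxia") -> pd.DataFrame:
    """Merged mechanics + energetics means/SDs.

    Parameters
    ----------
    phase
        ``"anoxia"`` (default), ``"recovery"`` or ``None`` for both.
    """
    df = load_mechanics_table().merge(
        load_energetics_table(), on=["phase", "time_min"], validate="1:1")
    if phase is not None:
        df = df[df["phase"] == phase].reset_index(drop=True)
    return df
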