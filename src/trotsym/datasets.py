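"""Bundled reference tables from the limb-by-limb re-shoeing study.

Small plain-text tables shipped with the package: the study-population
roster, baseline movement-symmetry summaries per exercise condition, the
left/right intervention difference centers used by the pooling worked
example, and the published mixed-model estimated marginal means used to
parameterise realistic synthetic studies.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_PKG = "trotsym.data"


def _read(name: str) -> pd.DataFrame:
    with resources.files(_PKG).joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_horses() -> pd.DataFrame:
    """Study-population roster (id, sex, breed, age, shoeing history)."""
    return _read("horses.csv")


def load_baseline_symmetry() -> pd.DataFrame:
    """Baseline per-condition movement symmetry summaries (mm)."""
    return _read("baseline_symmetry.csv")


def load_side_difference_centers() -> pd.DataFrame:
    """Published left-minus-right intervention difference centers (mm).

    The ``normal`` flag records whether the left/right differences were
    normally distributed; the pooling center is the mean where normal (and
    available) and the median otherwise.
    """
    return _read("side_difference_centers.csv")


def load_reshoeing_emm() -> pd.DataFrame:
    """Published mixed-model EMMs with 95% CIs per difference variable (mm)."""
    return _read("reshoeing_emm.csv")


def pooling_centers() -> dict:
    """Variable -> center (mm) for the pooling-threshold worked example."""
    tab = load_side_difference_centers()
    centers = {}
    for row in tab.itertuples(index=False):
        use_mean = bool(row.normal) and pd.notna(row.mean_diff_mm)
        centers[row.variable] = (
            float(row.mean_diff_mm) if use_mean else float(row.median_diff_mm)
        )
    return centers


def median_age_years() -> float:
    """Median age of the study horses."""
    return float(load_horses()["age_years"].median())


def mean_withers_rom_mm() -> float:
    """Mean of the hard- and soft-surface median withers ROM at baseline.

    This is the reference value used to convert percentage-of-ROM withers
    asymmetry guidelines into millimetres.
    """
    tab = load_baseline_symmetry()
    sel = tab[
        (tab["variable"] == "WROM")
        & (tab["condition"].isin(["hard_straight", "soft_straight"]))
    ]
    return float(sel["median"].mean())
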