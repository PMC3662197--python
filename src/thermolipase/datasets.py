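"""Packaged reference tables.

``table1``: the 101-strain dual-mode screening table (halo scores at 24/48 h
on Rhodamine-olive-oil agar; liquid-culture activities in nkat/mL at 48/72 h,
"ND" marking non-detections).  ``table2``: fitted two-step deactivation
parameters (alpha1, k1, k2 with standard errors) for the nine selected
lipases at 70-100 degC, plus the published activation energies for context.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .screening import ScreeningRecord, read_screening_csv

__all__ = ["load_table1", "load_table1_frame", "load_table2", "load_table2_ea"]


def _data_path(name: str):
    return resources.files("thermolipase.data").joinpath(name)


def load_table1() -> list[ScreeningRecord]:
    """The screening table as ScreeningRecord objects."""
    with resources.as_file(_data_path("table1.csv")) as path:
        return read_screening_csv(path)


def load_table1_frame() -> pd.DataFrame:
    """The raw screening table as a DataFrame (strings, "ND" sentinels)."""
    with resources.as_file(_data_path("table1.csv")) as path:
        return pd.read_csv(path, dtype=str)


def load_table2() -> pd.DataFrame:
    """Tidy deactivation-parameter table: one row per enzyme-temperature with
    columns alpha1, alpha1_se, k1, k1_se, k2, k2_se (k in 1/min)."""
    with resources.as_file(_data_path("table2.csv")) as path:
        return pd.read_csv(path)


def load_table2_ea() -> pd.DataFrame:
    """Published activation energies (kJ/mol) per enzyme for k1 and k2.

    Reference context only: they were regressed from unrounded per-replicate
    rate constants, so OLS on the rounded table means does not reproduce
    them.
    """
    with resources.as_file(_data_path("table2_ea.csv")) as path:
        return pd.read_csv(path)
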