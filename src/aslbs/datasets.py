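"""Packaged per-volunteer cohort tables (study fixtures).

Small CSVs shipped with the package: whole-brain tissue T1 values, paired
relative-CBF measurements under the fixed and the individually adapted
suppression timing, and the two readers' 3-point image-quality ratings.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_volunteer_t1", "load_volunteer_rcbf", "load_reader_ratings"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("aslbs.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_volunteer_t1() -> pd.DataFrame:
    """Per-volunteer whole-brain mean T1 (ms): gm_t1, wm_t1, csf_t1."""
    return _read("volunteer_t1.csv")


def load_volunteer_rcbf() -> pd.DataFrame:
    """Paired per-volunteer rCBF (a.u.): rcbf_regular, rcbf_adaptive."""
    return _read("volunteer_rcbf.csv")


def load_reader_ratings() -> pd.DataFrame:
    """Long-form reader ratings: case, reader, category, rating in {-1,0,1}."""
    return _read("reader_ratings.csv")
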