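"""Packaged reference tables for the Hegi-cave femur study.

Two small published tables ship with the package so the cohort-level
statistics can be reproduced without any download:

* 68.3 % highest-probability calibrated radiocarbon intervals for the
  fifteen adult male femurs excavated from Hegi cave (Nakatsu, Oita, Japan),
  used to split the specimens into Initial/Early and Late Jomon groups;
* the lateral-curvature type counts of the modern Japanese and the two
  Jomon cohorts (primary lateral / primary medial / S lateral-medial /
  S medial-lateral).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["hegi_radiocarbon", "lateral_curvature_counts"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("femora.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def hegi_radiocarbon() -> pd.DataFrame:
    """Calibrated 68.3 % age intervals, one row per interval.

    Columns: ``specimen_id``, ``period_label``, ``c14_age_bp``,
    ``c14_err_bp``, ``cal_bp_from`` (older bound), ``cal_bp_to`` (younger
    bound), ``probability_pct``.
    """
    df = _read("hegi_radiocarbon_cal68.csv")
    df["specimen_id"] = df["specimen_id"].astype(str)
    return df


def lateral_curvature_counts() -> pd.DataFrame:
    """Published cohort x lateral-pattern contingency table (counts)."""
    return _read("lateral_curvature_counts.csv").set_index("cohort")
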