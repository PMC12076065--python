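"""Local adaptation: regression of family breeding values on elevation of
origin of the seed parents."""

from __future__ import annotations

import pandas as pd
from scipy import stats

__all__ = ["bv_vs_elevation", "elevation_regressions"]


def bv_vs_elevation(records: pd.DataFrame, trait, elevation_col="elevation"):
    """Ordinary least squares of parent breeding values on elevation (m).

    ``records`` has one row per parent with its BV columns and elevation of
    origin.  Returns a dict with slope, intercept, r2, p (slope test) and n.
    Requires at least 3 parents and non-constant elevation.
    """
    d = records[[trait, elevation_col]].dropna()
    if len(d) < 3:
        raise ValueError("need at least 3 parents with BV and elevation")
    if d[elevation_col].std() == 0:
        raise ValueError("elevation has zero variance")
    fit = stats.linregress(d[elevation_col], d[trait])
    return {
        "trait": trait,
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue**2),
        "p": float(fit.pvalue),
        "n": int(len(d)),
    }


def elevation_regressions(records: pd.DataFrame, traits, elevation_col="elevation"):
    """bv_vs_elevation over several traits as a tidy DataFrame."""
    return pd.DataFrame([bv_vs_elevation(records, t, elevation_col) for t in traits])
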