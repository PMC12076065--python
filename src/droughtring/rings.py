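"""Basal area increment and drought-response indices.

Implements the Lloret-style short-term indices (resistance, resilience), the
long-term decline index, the resilience grouping, and the neighbourhood
competition index used to adjust for stand structure in the progeny trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import RingSeries

__all__ = [
    "BAISeries",
    "DroughtEvent",
    "bai",
    "resistance",
    "resilience",
    "decline",
    "resilience_groups",
    "competition_index",
    "drought_indices_table",
    "detect_drought_years",
]

log = logging.getLogger(__name__)

DECLINE_MAX_WINDOW = (1997, 2001)
DECLINE_LAST_WINDOW = (2012, 2016)
RESILIENCE_THRESHOLD = 0.8


@dataclass
class BAISeries:
    """Annual basal area increment (mm^2/yr) with cumulative radius (mm)."""

    tree_id: str
    first_year: int
    bai: np.ndarray
    radius: np.ndarray

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.bai))

    def window_mean(self, start: int, end: int):
        """Mean BAI over calendar years [start, end]; None if incomplete."""
        years = self.years
        sel = (years >= start) & (years <= end)
        if sel.sum() != end - start + 1:
            return None
        return float(self.bai[sel].mean())


@dataclass
class DroughtEvent:
    """A drought event year with its 4-year pre and post windows."""

    event_year: int
    window: int = 4

    @property
    def pre_window(self):
        return (self.event_year - self.window, self.event_year - 1)

    @property
    def post_window(self):
        return (self.event_year + 1, self.event_year + self.window)


def bai(series: RingSeries) -> BAISeries:
    """Basal area increment from ring widths, assuming a circular stem.

    BAI_t = pi (r_t^2 - r_{t-1}^2) with r_t the cumulative radius (r_0 = 0),
    so the BAI total equals the final basal area pi r^2 exactly.
    """
    if series.first_year is None:
        raise ValueError("series must be dated (first_year set)")
    r = np.cumsum(series.widths)
    r_prev = np.concatenate([[0.0], r[:-1]])
    return BAISeries(
        tree_id=series.tree_id,
        first_year=series.first_year,
        bai=np.pi * (r**2 - r_prev**2),
        radius=r,
    )


def resistance(bai_series: BAISeries, event) -> float | None:
    """BAI in the event year over mean BAI of the 4 preceding years."""
    event = event if isinstance(event, DroughtEvent) else DroughtEvent(int(event))
    pre = bai_series.window_mean(*event.pre_window)
    ev = bai_series.window_mean(event.event_year, event.event_year)
    if pre is None or ev is None or pre == 0:
        log.info("resistance %s %s: incomplete window", bai_series.tree_id, event.event_year)
        return None
    return ev / pre


def resilience(bai_series: BAISeries, event) -> float | None:
    """Mean BAI of the 4 years after the event over the 4 years before."""
    event = event if isinstance(event, DroughtEvent) else DroughtEvent(int(event))
    pre = bai_series.window_mean(*event.pre_window)
    post = bai_series.window_mean(*event.post_window)
    if pre is None or post is None or pre == 0:
        log.info("resilience %s %s: incomplete window", bai_series.tree_id, event.event_year)
        return None
    return post / pre


def decline(
    bai_series: BAISeries,
    max_window=DECLINE_MAX_WINDOW,
    last_window=DECLINE_LAST_WINDOW,
) -> float | None:
    """Long-term decline: mean BAI of the maximum-growth window over the
    final window.

    Values near 1 indicate trees that maintained their growth; values > 1
    indicate a long-term growth reduction.  Both windows must be fully
    covered by the dated series, otherwise the index is missing.
    """
    num = bai_series.window_mean(*max_window)
    den = bai_series.window_mean(*last_window)
    if num is None or den is None or den == 0:
        return None
    return num / den


def resilience_groups(res_a, res_b, threshold=RESILIENCE_THRESHOLD):
    """Classify trees by resilience to two events ('high' = strictly above
    the threshold in that event); missing values are unclassified."""
    if res_a is None or res_b is None or np.isnan(res_a) or np.isnan(res_b):
        return None
    a = "high" if res_a > threshold else "low"
    b = "high" if res_b > threshold else "low"
    return f"{a}-{b}"


def competition_index(layout, dbh_map, focal_id, radius=7.1):
    """Size-distance competition index around a focal tree.

    CI = sum_i (d_i / d) * arctan(d_i / dist_i) over alive neighbours within
    ``radius`` m (the closest two rows and columns at 2.5 m spacing), with
    DBH in cm and distance in m, as in the source formulation.  Note the
    mixed units are deliberate: d_i/dist_i feeds arctan without conversion.
    """
    lay = layout.set_index("tree_id") if "tree_id" in layout.columns else layout
    if focal_id not in lay.index:
        raise KeyError(f"focal tree {focal_id!r} not in layout")
    row = lay.loc[focal_id]
    if not bool(row["alive"]):
        raise ValueError(f"focal tree {focal_id!r} is dead")
    d = float(dbh_map[focal_id]) if focal_id in dbh_map else np.nan
    if not d > 0:
        raise ValueError(f"focal tree {focal_id!r} needs a positive DBH")
    site = row["site"]
    x0, y0 = float(row["x_m"]), float(row["y_m"])
    nb = lay[(lay["site"] == site) & lay["alive"]]
    dx = nb["x_m"].to_numpy() - x0
    dy = nb["y_m"].to_numpy() - y0
    dist = np.hypot(dx, dy)
    ci = 0.0
    for tid, dist_i in zip(nb.index, dist):
        if tid == focal_id:
            if dist_i == 0:
                continue
        if dist_i == 0:
            raise ValueError(f"zero distance between {focal_id!r} and {tid!r}")
        if dist_i > radius:
            continue
        di = dbh_map.get(tid)
        if di is None or not di > 0:
            continue
        ci += (di / d) * np.arctan(di / dist_i)
    return ci


def competition_indices(layout, dbh_map, focal_ids=None, radius=7.1):
    """Vectorized ``competition_index`` over many focal trees.

    Returns a Series indexed by tree_id (alive focal trees with DBH only).
    """
    from scipy.spatial import cKDTree

    lay = layout.reset_index(drop=True)
    out = {}
    for _, g in lay.groupby("site"):
        alive = g[g["alive"]]
        ids = alive["tree_id"].to_numpy()
        xy = alive[["x_m", "y_m"]].to_numpy()
        dbh = np.array([dbh_map.get(t, np.nan) for t in ids])
        tree = cKDTree(xy)
        focal_mask = np.ones(len(ids), dtype=bool)
        if focal_ids is not None:
            fset = set(focal_ids)
            focal_mask = np.array([t in fset for t in ids])
        for i in np.where(focal_mask)[0]:
            d = dbh[i]
            if not d > 0:
                continue
            nb = tree.query_ball_point(xy[i], r=radius)
            nb = [j for j in nb if j != i]
            if not nb:
                out[ids[i]] = 0.0
                continue
            dist = np.hypot(*(xy[nb] - xy[i]).T)
            di = dbh[nb]
            ok = np.isfinite(di) & (di > 0) & (dist > 0)
            out[ids[i]] = float(((di[ok] / d) * np.arctan(di[ok] / dist[ok])).sum())
    return pd.Series(out, name="competition")


def detect_drought_years(climate, threshold=0.0):
    """Years whose annual climate moisture index falls below ``threshold``.

    Provided as a diagnostic; the analysis pipeline takes its event years
    from configuration, since event selection also weighs the growth record.
    """
    ann = climate.annual
    return sorted(ann.loc[ann["cmi"] < threshold, "year"].astype(int).tolist())


def drought_indices_table(series_dict, drought_years=(2002, 2010), threshold=RESILIENCE_THRESHOLD):
    """Tidy per-tree index table for a set of dated ring series.

    Columns: tree_id, resistance_<year>, resilience_<year>, decline,
    resilience_group.
    """
    events = [DroughtEvent(int(y)) for y in drought_years]
    rows = []
    for tid, s in series_dict.items():
        b = bai(s)
        rec = {"tree_id": tid}
        res_vals = []
        for ev in events:
            rec[f"resistance_{ev.event_year}"] = resistance(b, ev)
            rv = resilience(b, ev)
            rec[f"resilience_{ev.event_year}"] = rv
            res_vals.append(rv)
        rec["decline"] = decline(b)
        if len(res_vals) >= 2:
            rec["resilience_group"] = resilience_groups(res_vals[0], res_vals[1], threshold)
        rows.append(rec)
    df = pd.DataFrame(rows)
    return df.astype({c: float for c in df.columns if c not in ("tree_id", "resilience_group")})
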