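"""Ring detection and quality control for wood-density profiles.

X-ray style density profiles sampled at a fixed radial step (0.0254 mm) show
an earlywood plateau rising to a latewood maximum within each ring, followed
by a sharp density drop at the transition to the next ring's earlywood.  Ring
boundaries are placed at those drops; widths follow from boundary spacing.
A simplified master-chronology segment-correlation check stands in for full
cross-dating software.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .types import DensityProfile, RingSeries

__all__ = [
    "detect_ring_boundaries",
    "date_series",
    "core_qc",
    "crossdate_check",
    "mean_core_density",
]

log = logging.getLogger(__name__)

SAMPLING_YEAR = 2017  # cores collected in June; the partial ring is excluded
OUTERMOST_RING_YEAR = SAMPLING_YEAR - 1


def detect_ring_boundaries(profile: DensityProfile, drop_fraction=0.5, min_width_mm=0.2):
    """Detect ring boundaries at sharp latewood-to-earlywood density drops.

    A boundary is a negative density step larger than ``drop_fraction`` times
    the profile's earlywood/latewood contrast (estimated as the 10th-90th
    percentile spread).  Candidate boundaries closer than ``min_width_mm``
    are merged, keeping the steepest drop.  Returns an undated RingSeries
    (first_year None); if no boundary is found the series is empty and
    globally flagged.
    """
    step = profile.step
    min_samples = int(round(2 * min_width_mm / step))
    if profile.n_samples < min_samples:
        raise ValueError("profile too short for the requested minimum ring width")
    d = profile.density
    contrast = np.percentile(d, 90) - np.percentile(d, 10)
    diffs = np.diff(d)
    if contrast <= 0:
        return RingSeries(profile.tree_id, None, np.array([]), np.array([], dtype=bool))
    thr = drop_fraction * contrast
    cand = np.where(diffs < -thr)[0]  # boundary between samples i and i+1
    if cand.size == 0:
        return RingSeries(profile.tree_id, None, np.array([]), np.array([], dtype=bool))
    min_sep = max(1, int(round(min_width_mm / step)))
    # greedy: keep the steepest drop within each min-separation cluster
    order = cand[np.argsort(diffs[cand])]  # most negative first
    kept = []
    for i in order:
        if all(abs(i - j) >= min_sep for j in kept):
            kept.append(i)
    kept = sorted(kept)
    edges = [0] + [i + 1 for i in kept] + [profile.n_samples]
    widths = np.diff(edges) * step
    series = RingSeries(profile.tree_id, None, widths)
    return series


def ring_contrast_scores(profile: DensityProfile, series: RingSeries):
    """Per-ring boundary clarity: the smaller adjacent boundary drop divided
    by the profile's overall earlywood/latewood contrast (ends score 1)."""
    d = profile.density
    contrast = np.percentile(d, 90) - np.percentile(d, 10)
    if contrast <= 0 or series.n_rings == 0:
        return np.zeros(series.n_rings)
    edges = np.round(np.cumsum(series.widths[:-1]) / profile.step).astype(int)
    diffs = np.diff(d)
    drops = np.array([max(0.0, -diffs[e - 1]) / contrast for e in edges]) if len(edges) else np.array([])
    scores = np.empty(series.n_rings)
    for i in range(series.n_rings):
        left = drops[i - 1] if i - 1 >= 0 and i - 1 < len(drops) else 1.0
        right = drops[i] if i < len(drops) else 1.0
        scores[i] = min(left, right)
    return scores


def date_series(series: RingSeries, outermost_year=OUTERMOST_RING_YEAR) -> RingSeries:
    """Anchor an undated series at the bark side (outermost ring year)."""
    return RingSeries(
        tree_id=series.tree_id,
        first_year=int(outermost_year) - series.n_rings + 1,
        widths=series.widths,
        qc_flags=series.qc_flags,
    )


def core_qc(series_dict, contrast_scores, threshold):
    """Discard trees whose earlywood/latewood contrast is too unclear to
    yield a complete dated series.

    contrast_scores: tree_id -> per-ring contrast score array.  A tree is
    discarded when any ring's score falls below ``threshold`` (an unclear
    section breaks the dating chain).  Returns (flags, discard_fraction)
    where flags maps tree_id -> accepted bool.
    """
    flags = {}
    for tid, series in series_dict.items():
        scores = np.asarray(contrast_scores[tid], dtype=float)
        if len(scores) != series.n_rings:
            raise ValueError(f"{tid}: one contrast score per ring required")
        flags[tid] = bool((scores >= threshold).all()) if len(scores) else False
    n = len(flags)
    frac = (sum(not ok for ok in flags.values()) / n) if n else 0.0
    return flags, frac


def _detrend(widths):
    """First difference of log widths: a parameter-free high-pass filter."""
    return np.diff(np.log(np.asarray(widths, dtype=float)))


def crossdate_check(series_dict, segment_length=10, min_corr=0.4):
    """Flag series segments that do not track the master chronology.

    Each series is detrended (first-differenced log widths) and correlated
    against the mean of all other detrended series (leave-one-out master)
    over sliding half-overlapping segments of ``segment_length`` years.
    Segments with Pearson correlation below ``min_corr`` are flagged,
    catching dating errors such as a one-year shift.

    Returns a DataFrame: tree_id, start_year, end_year, correlation, flagged.
    Series shorter than the segment length are skipped with a warning.
    """
    dated = {t: s for t, s in series_dict.items() if s.first_year is not None}
    if len(dated) < 5:
        raise ValueError("need at least 5 dated series for cross-dating")
    det = {}
    for tid, s in dated.items():
        if s.n_rings < segment_length:
            warnings.warn(f"series {tid} shorter than segment length; skipped")
            continue
        det[tid] = pd.Series(_detrend(s.widths), index=s.years[1:])
    wide = pd.DataFrame(det)
    totals = wide.sum(axis=1)
    counts = wide.notna().sum(axis=1)
    rows = []
    for tid in det:
        ser = wide[tid]
        master = (totals - ser.fillna(0.0)) / (counts - ser.notna().astype(int)).replace(0, np.nan)
        years = ser.dropna().index.to_numpy()
        step = max(1, segment_length // 2)
        starts = list(range(0, max(1, len(years) - segment_length + 1), step))
        if starts and starts[-1] + segment_length < len(years):
            starts.append(len(years) - segment_length)
        for st in starts:
            yrs = years[st : st + segment_length]
            a = ser.loc[yrs].to_numpy()
            b = master.loc[yrs].to_numpy()
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(a[ok], b[ok])[0, 1])
            rows.append((tid, int(yrs[0]), int(yrs[-1]), r, not (r >= min_corr)))
    return pd.DataFrame(rows, columns=["tree_id", "start_year", "end_year", "correlation", "flagged"])


def mean_core_density(profile: DensityProfile) -> float:
    """Whole-core average wood density (kg/m3)."""
    if profile.n_samples == 0:
        raise ValueError("empty density profile")
    return float(np.mean(profile.density))
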