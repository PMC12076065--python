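"""Readers, writers and run configuration.

Ring series travel as Tucson (RWL) decadal text — the dendrochronology
community's interchange format (values in 0.01 mm, series closed by a 999
terminator) — or as tidy long CSV; layouts, traits, pedigrees, genotypes and
climate are plain CSV; the simulation truth record is JSON; configuration is
YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import DensityProfile, RingSeries

__all__ = [
    "read_rwl",
    "write_rwl",
    "ring_series_to_frame",
    "frame_to_ring_series",
    "read_density_profiles",
    "RunConfig",
]

_TERMINATORS = {999, -9999}


def write_rwl(series_dict, path):
    """Write dated ring series in Tucson decadal format (0.01 mm units).

    Series ids are limited to 8 characters by the format; longer ids that
    would collide after truncation are replaced by sequential core codes.
    Returns the id -> written-code mapping.
    """
    short = {}
    used = set()
    for k, tid in enumerate(series_dict):
        sid = str(tid)[:8]
        if sid in used:
            sid = f"C{k:07d}"
        used.add(sid)
        short[tid] = sid
    lines = []
    for tid, s in series_dict.items():
        if s.first_year is None:
            raise ValueError(f"series {tid} is undated")
        sid = short[tid]
        year = s.first_year
        vals = [int(round(w * 100)) for w in s.widths]
        i = 0
        while i < len(vals):
            decade_end = (year // 10) * 10 + 9
            chunk = []
            while i < len(vals) and year <= decade_end:
                chunk.append(vals[i])
                i += 1
                year += 1
            row_year = year - len(chunk)
            cells = "".join(f"{v:6d}" for v in chunk)
            if i == len(vals):
                cells += f"{999:6d}"
            lines.append(f"{sid:<8s}{row_year:4d}{cells}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    return short


def read_rwl(path):
    """Read a Tucson decadal RWL file into {tree_id: RingSeries} (mm).

    Malformed decade lines raise with the offending line number.
    """
    out = {}
    acc = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        sid = raw[:8].strip()
        try:
            year = int(raw[8:12])
            rest = raw[12:]
            vals = [int(rest[i : i + 6]) for i in range(0, len(rest.rstrip()), 6)]
        except ValueError as err:
            raise ValueError(f"{path}: malformed decade line {ln}: {raw!r}") from err
        if not sid:
            raise ValueError(f"{path}: missing series id on line {ln}")
        ser = acc.setdefault(sid, {"first_year": year, "vals": [], "next": year, "done": False})
        if ser["done"]:
            raise ValueError(f"{path}: data after terminator for {sid} on line {ln}")
        if year != ser["next"]:
            raise ValueError(
                f"{path}: line {ln}: decade starts at {year}, expected {ser['next']}"
            )
        for v in vals:
            if v in _TERMINATORS:
                ser["done"] = True
                break
            ser["vals"].append(v / 100.0)
            ser["next"] += 1
    for sid, ser in acc.items():
        out[sid] = RingSeries(tree_id=sid, first_year=ser["first_year"],
                              widths=np.array(ser["vals"]))
    return out


def ring_series_to_frame(series_dict) -> pd.DataFrame:
    """Long-format frame: tree_id, year, width_mm."""
    rows = []
    for tid, s in series_dict.items():
        for year, w in zip(s.years, s.widths):
            rows.append((tid, int(year), float(w)))
    return pd.DataFrame(rows, columns=["tree_id", "year", "width_mm"])


def frame_to_ring_series(df: pd.DataFrame):
    out = {}
    for tid, g in df.groupby("tree_id"):
        g = g.sort_values("year")
        years = g["year"].to_numpy()
        if len(years) > 1 and not (np.diff(years) == 1).all():
            raise ValueError(f"tree {tid}: years are not consecutive")
        out[tid] = RingSeries(tree_id=tid, first_year=int(years[0]),
                              widths=g["width_mm"].to_numpy(dtype=float))
    return out


def read_density_profiles(path, step=0.0254):
    """CSV (tree_id, position_mm, density) -> {tree_id: DensityProfile}."""
    df = pd.read_csv(path)
    out = {}
    for tid, g in df.groupby("tree_id"):
        g = g.sort_values("position_mm")
        out[tid] = DensityProfile(
            tree_id=str(tid),
            positions=g["position_mm"].to_numpy(dtype=float),
            density=g["density"].to_numpy(dtype=float),
            step=step,
        )
    return out


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (YAML round-trippable).

    Defaults reproduce the study conditions: 4 sites, genotyped subset of 40
    half-sib families (~10 trees per family per site), growth years
    1982-2016 with drought events in 2002 and 2010, resilience grouping at
    0.8, family reassignment floor 0.125.
    """

    seed: int = 1
    out_dir: str = "runs/default"
    n_sites: int = 4
    n_families: int = 40
    n_sets: int = 5
    n_blocks: int = 5
    plot_size: int = 4
    spacing_m: float = 2.5
    mortality_rate: float = 0.12
    subsample_per_family_site: int = 10
    years: tuple = (1982, 2016)
    drought_years: tuple = (2002, 2010)
    resilience_threshold: float = 0.8
    unassigned_floor: float = 0.125
    contamination_rate: float = 0.05
    n_snps: int = 500
    qc_threshold: float = 0.2
    h2_denominator: str = "as-printed"
    reml_tol: float = 1e-8
    reml_max_iter: int = 1000
    reml_method: str = "em"
    elevation_range: tuple = (945.0, 1280.0)
    sem_alpha: float = 0.05

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        cfg = cls(**d)
        for key in ("years", "drought_years", "elevation_range"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def save(self, path):
        d = asdict(self)
        for key in ("years", "drought_years", "elevation_range"):
            d[key] = list(d[key])
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def write_truth_json(truth, path):
    d = {
        "traits": truth.traits,
        "variances": truth.variances,
        "genetic_correlation": truth.genetic_correlation.to_dict(),
        "elevation_beta": truth.elevation_beta,
        "breeding_values": truth.breeding_values.round(6).to_dict(),
    }
    if truth.parent_elevation is not None:
        d["parent_elevation"] = truth.parent_elevation.round(2).to_dict()
    Path(path).write_text(json.dumps(d, indent=1))
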