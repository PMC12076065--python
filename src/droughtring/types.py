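"""Lightweight containers shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RingSeries:
    """Per-tree annual ring widths anchored to calendar years.

    widths are in mm, pith-outward; the ring for calendar year
    ``first_year + i`` is ``widths[i]``.  ``qc_flags[i]`` is True where the
    ring failed a quality check.
    """

    tree_id: str
    first_year: int
    widths: np.ndarray
    qc_flags: np.ndarray = None

    def __post_init__(self):
        self.widths = np.asarray(self.widths, dtype=float)
        if self.qc_flags is None:
            self.qc_flags = np.zeros(len(self.widths), dtype=bool)
        else:
            self.qc_flags = np.asarray(self.qc_flags, dtype=bool)

    @property
    def n_rings(self) -> int:
        return len(self.widths)

    @property
    def last_year(self) -> int:
        return self.first_year + self.n_rings - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + self.n_rings)


@dataclass
class DensityProfile:
    """Radial wood-density profile at a fixed sampling step.

    positions are mm from the innermost measured point (strictly increasing,
    constant step); density in kg/m3.
    """

    tree_id: str
    positions: np.ndarray
    density: np.ndarray
    step: float = 0.0254
    true_widths: np.ndarray | None = None  # generator truth, quantized to step

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if len(self.positions) != len(self.density):
            raise ValueError("positions and density lengths differ")

    @property
    def n_samples(self) -> int:
        return len(self.density)


@dataclass
class ClimateTable:
    """Monthly climate plus annual water-balance aggregates.

    monthly: year, month, tmean, tmin, tmax (degC), precip (mm)
    annual:  year, precip (mm), pet (mm, Hargreaves), cmi (mm)
    """

    monthly: pd.DataFrame
    annual: pd.DataFrame
    latitude: float

    @property
    def mat(self) -> float:
        return float(self.monthly["tmean"].mean())

    @property
    def map(self) -> float:
        return float(self.annual["precip"].mean())

    def cmi(self, year: int) -> float:
        row = self.annual.loc[self.annual["year"] == year, "cmi"]
        if row.empty:
            raise KeyError(f"year {year} not in climate table")
        return float(row.iloc[0])


@dataclass
class TruthRecord:
    """Ground truth of a simulated study, for recovery tests.

    breeding_values: DataFrame indexed by individual id, one column per trait.
    variances: trait -> dict with sigma_a2, sigma_block2, sigma_set2, sigma_e2.
    genetic_correlation: trait × trait DataFrame of true additive correlations.
    parent_elevation: Series of elevation of origin (m) per founder dam.
    elevation_beta: trait -> true slope of founder BV on elevation (per m).
    """

    traits: list
    variances: dict
    breeding_values: pd.DataFrame
    genetic_correlation: pd.DataFrame
    parent_elevation: pd.Series | None = None
    elevation_beta: dict = field(default_factory=dict)

    def bv(self, trait: str) -> pd.Series:
        return self.breeding_values[trait]
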