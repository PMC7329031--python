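"""Time-series containers shared across the pipeline.

All series use the CE calendar convention (CE = 1950 − cal BP) on the public
surface; SPDs are annual, demographic series run on a fixed coarse step
(30 years by default, roughly one generation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["SPDSeries", "DemographicSeries", "CovariateSeries", "ce_to_bp", "bp_to_ce"]


def ce_to_bp(year_ce):
    """Calendar CE -> cal BP (present = 1950 CE)."""
    return 1950.0 - np.asarray(year_ce, dtype=float)


def bp_to_ce(cal_bp):
    """Cal BP -> calendar CE."""
    return 1950.0 - np.asarray(cal_bp, dtype=float)


@dataclass
class SPDSeries:
    """Annual summed probability density, the relative population-size proxy."""

    year_ce: np.ndarray
    value: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.year_ce = np.asarray(self.year_ce, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if len(self.year_ce) != len(self.value):
            raise ValueError("grid/value length mismatch")
        if len(self.year_ce) > 1 and not np.allclose(np.diff(self.year_ce), 1.0):
            raise ValueError("SPD grid must be annual and contiguous")
        if np.any(self.value < 0):
            raise ValueError("SPD values must be non-negative")

    @property
    def total_mass(self) -> float:
        return float(self.value.sum())

    def window(self, lo_ce: float, hi_ce: float) -> "SPDSeries":
        m = (self.year_ce >= lo_ce) & (self.year_ce <= hi_ce)
        return SPDSeries(self.year_ce[m], self.value[m], dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year_ce": self.year_ce, "value": self.value})


@dataclass
class DemographicSeries:
    """Coarse-step population proxy N_t with realized growth rates R_t.

    ``n`` carries SPD units (dimensionless, relative); growth rates are
    R_t = ln N_t − ln N_{t−1} per step.
    """

    time_ce: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.time_ce = np.asarray(self.time_ce, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if len(self.time_ce) != len(self.n):
            raise ValueError("time/n length mismatch")
        if len(self.time_ce) > 1:
            steps = np.diff(self.time_ce)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise ValueError("time grid must be strictly increasing with constant step")

    @property
    def step(self) -> float:
        return float(self.time_ce[1] - self.time_ce[0]) if len(self.time_ce) > 1 else np.nan

    @property
    def r_obs(self) -> np.ndarray:
        """Realized per-capita growth rates, length len(n) − 1."""
        if np.any(self.n <= 0):
            raise ValueError("growth rates require strictly positive n")
        return np.diff(np.log(self.n))

    def window(self, lo_ce: float, hi_ce: float) -> "DemographicSeries":
        m = (self.time_ce >= lo_ce) & (self.time_ce <= hi_ce)
        return DemographicSeries(self.time_ce[m], self.n[m])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ce": self.time_ce, "n": self.n})


@dataclass
class CovariateSeries:
    """Palm-pollen % and SOI-like climate index on a common time grid."""

    time_ce: np.ndarray
    palm: Optional[np.ndarray] = None
    soi: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time_ce = np.asarray(self.time_ce, dtype=float)
        for name in ("palm", "soi"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                setattr(self, name, v)
                if len(v) != len(self.time_ce):
                    raise ValueError(f"{name} length mismatch")
        if self.palm is not None and (np.any(self.palm < 0) or np.any(self.palm > 100)):
            raise ValueError("palm pollen % must lie in [0, 100]")

    def on_step_grid(self, time_ce: np.ndarray, step: float) -> "CovariateSeries":
        """Align covariates with a coarse model grid.

        Pollen is linearly interpolated at the grid times; the climate index is
        averaged over each preceding interval (t − step, t], matching the way
        the population proxy is averaged.
        """
        time_ce = np.asarray(time_ce, dtype=float)
        palm = soi = None
        if self.palm is not None:
            palm = np.interp(time_ce, self.time_ce, self.palm)
        if self.soi is not None:
            soi = np.empty_like(time_ce)
            for i, t in enumerate(time_ce):
                m = (self.time_ce > t - step) & (self.time_ce <= t)
                soi[i] = self.soi[m].mean() if m.any() else np.interp(t, self.time_ce, self.soi)
        return CovariateSeries(time_ce, palm, soi)

    def to_frame(self) -> pd.DataFrame:
        d = {"time_ce": self.time_ce}
        if self.palm is not None:
            d["palm"] = self.palm
        if self.soi is not None:
            d["soi"] = self.soi
        return pd.DataFrame(d)
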