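"""CSV/JSON readers and writers for the pipeline's external formats."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, RadiocarbonDate
from .series import CovariateSeries, DemographicSeries

__all__ = [
    "read_dates_csv",
    "write_dates_csv",
    "read_covariates_csv",
    "read_pollen_csv",
    "read_demographic_csv",
    "write_curve_file",
    "write_json",
    "read_json",
]

DATE_COLUMNS = ["lab_id", "site_id", "age_14c", "error", "material", "marine_fraction", "d13c"]


def read_dates_csv(path: Union[str, Path]) -> list[RadiocarbonDate]:
    """Read a radiocarbon date table (header: lab_id,site_id,age_14c,error,...).

    ``material`` defaults to terrestrial; ``marine_fraction`` and ``d13c`` are
    optional columns.
    """
    df = pd.read_csv(path)
    missing = {"lab_id", "site_id", "age_14c", "error"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    dates = []
    for _, row in df.iterrows():
        material = row.get("material")
        if material is None or (isinstance(material, float) and np.isnan(material)):
            material = "terrestrial"
        mf = row.get("marine_fraction")
        mf = None if mf is None or (isinstance(mf, float) and np.isnan(mf)) else float(mf)
        d13c = row.get("d13c")
        d13c = None if d13c is None or (isinstance(d13c, float) and np.isnan(d13c)) else float(d13c)
        dates.append(
            RadiocarbonDate(
                lab_id=str(row["lab_id"]),
                site_id=str(row["site_id"]),
                age_14c=float(row["age_14c"]),
                error=float(row["error"]),
                material=str(material),
                marine_fraction=mf,
                d13c=d13c,
            )
        )
    return dates


def write_dates_csv(dates: Sequence[RadiocarbonDate], path: Union[str, Path]) -> None:
    rows = [
        {
            "lab_id": d.lab_id,
            "site_id": d.site_id,
            "age_14c": d.age_14c,
            "error": d.error,
            "material": d.material,
            "marine_fraction": d.marine_fraction,
            "d13c": d.d13c,
        }
        for d in dates
    ]
    pd.DataFrame(rows, columns=DATE_COLUMNS).to_csv(path, index=False)


def read_covariates_csv(path: Union[str, Path]) -> CovariateSeries:
    """Covariate series CSV with columns time_ce[,palm][,soi]."""
    df = pd.read_csv(path)
    if "time_ce" not in df.columns:
        raise ValueError(f"{path}: missing time_ce column")
    return CovariateSeries(
        df["time_ce"].to_numpy(),
        df["palm"].to_numpy() if "palm" in df.columns else None,
        df["soi"].to_numpy() if "soi" in df.columns else None,
    )


def read_pollen_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Pollen sample table with columns time_ce,palm_pct."""
    df = pd.read_csv(path)
    missing = {"time_ce", "palm_pct"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_demographic_csv(path: Union[str, Path]) -> DemographicSeries:
    df = pd.read_csv(path)
    missing = {"time_ce", "n"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return DemographicSeries(df["time_ce"].to_numpy(), df["n"].to_numpy())


def write_curve_file(curve: CalibrationCurve, path: Union[str, Path]) -> None:
    """Write a curve in the standard 3-column layout (cal BP, 14C age, error)."""
    with open(path, "w") as fh:
        fh.write(f"# {curve.name}: cal BP, 14C age BP, 1-sigma error\n")
        for bp, mu, sd in zip(curve.cal_bp, curve.mu_14c, curve.sigma_curve):
            fh.write(f"{bp:.1f},{mu:.2f},{sd:.2f}\n")


def write_json(obj: dict, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        return json.load(fh)
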