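"""Palm-pollen regression: vegetation response to population and climate.

Palm pollen percentage F (the vegetation-cover proxy) is modelled as

    F = alpha + beta*N + gamma*C + omega*(N*C) + eps,

where N is the mean population proxy (SPD) over the 30 years preceding the
pollen sample and C is the climate index over the same window. Nested term
subsets are fitted by OLS and compared by AICc; the interaction term is only
admitted alongside both main effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .growth import aicc, akaike_weights
from .series import CovariateSeries, SPDSeries

__all__ = [
    "VegetationParams",
    "VegetationFit",
    "align_pollen_predictors",
    "fit_vegetation",
    "fit_vegetation_set",
    "CANDIDATE_TERM_SETS",
]

logger = logging.getLogger(__name__)

TERMS = ("N", "C", "NxC")
CANDIDATE_TERM_SETS: tuple[tuple[str, ...], ...] = (
    ("N",),
    ("C",),
    ("N", "C"),
    ("N", "C", "NxC"),
)


@dataclass(frozen=True)
class VegetationParams:
    alpha: float
    beta: float = 0.0
    gamma: float = 0.0
    omega: float = 0.0
    sigma_eps: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be >= 0")


@dataclass
class VegetationFit:
    params: VegetationParams
    included_terms: tuple[str, ...]
    rss: float
    n_obs: int
    aicc: float
    r2: float
    bse: dict
    akaike_weight: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "included_terms": list(self.included_terms),
            "params": {
                "alpha": self.params.alpha,
                "beta": self.params.beta,
                "gamma": self.params.gamma,
                "omega": self.params.omega,
                "sigma_eps": self.params.sigma_eps,
            },
            "bse": self.bse,
            "rss": float(self.rss),
            "n_obs": int(self.n_obs),
            "aicc": float(self.aicc),
            "r2": float(self.r2),
            "akaike_weight": None if self.akaike_weight is None else float(self.akaike_weight),
        }


def align_pollen_predictors(
    pollen: pd.DataFrame,
    spd: SPDSeries,
    soi: CovariateSeries,
    window: float = 30.0,
) -> pd.DataFrame:
    """Build the regression table: F(t) vs mean SPD and SOI over (t−window, t].

    ``pollen`` needs columns ``time_ce`` and ``palm_pct``. Sample times whose
    preceding window is not covered by the SPD or SOI series are dropped with
    a log entry.
    """
    rows = []
    for _, row in pollen.iterrows():
        t = float(row["time_ce"])
        m_spd = (spd.year_ce > t - window) & (spd.year_ce <= t)
        m_soi = (soi.time_ce > t - window) & (soi.time_ce <= t)
        if not m_spd.any() or not m_soi.any() or soi.soi is None:
            logger.info("pollen sample at %s CE outside SPD/SOI coverage; dropped", t)
            continue
        rows.append(
            {
                "time_ce": t,
                "F": float(row["palm_pct"]),
                "N": float(spd.value[m_spd].mean()),
                "C": float(soi.soi[m_soi].mean()),
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["NxC"] = table["N"] * table["C"]
    return table


def fit_vegetation(table: pd.DataFrame, included_terms: Sequence[str]) -> VegetationFit:
    """OLS fit of the pollen response for one term subset (hierarchy enforced)."""
    terms = tuple(included_terms)
    for t in terms:
        if t not in TERMS:
            raise ValueError(f"unknown term {t!r}")
    if "NxC" in terms and not {"N", "C"} <= set(terms):
        raise ValueError("interaction N×C requires both main effects (hierarchy)")
    n = len(table)
    if n < len(terms) + 2:
        raise ValueError(f"need >= {len(terms) + 2} rows, got {n}")
    X = table.loc[:, list(terms)].to_numpy() if terms else np.empty((n, 0))
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design; collinear terms among {terms}")
    model = sm.OLS(table["F"].to_numpy(), X).fit()
    coef = dict(zip(("const",) + terms, model.params))
    bse = dict(zip(("const",) + terms, model.bse))
    rss = float(model.ssr)
    n_params = 1 + len(terms)
    dof = max(n - n_params, 1)
    params = VegetationParams(
        alpha=float(coef["const"]),
        beta=float(coef.get("N", 0.0)),
        gamma=float(coef.get("C", 0.0)),
        omega=float(coef.get("NxC", 0.0)),
        sigma_eps=float(np.sqrt(rss / dof)),
    )
    return VegetationFit(
        params=params,
        included_terms=terms,
        rss=rss,
        n_obs=n,
        aicc=aicc(n, n_params + 1, rss),
        r2=float(model.rsquared),
        bse={k: float(v) for k, v in bse.items()},
    )


def fit_vegetation_set(
    table: pd.DataFrame,
    term_sets: Sequence[Sequence[str]] = CANDIDATE_TERM_SETS,
) -> list[VegetationFit]:
    """Fit the candidate term subsets and attach Akaike weights."""
    fits = [fit_vegetation(table, ts) for ts in term_sets]
    for fit, w in zip(fits, akaike_weights([f.aicc for f in fits])):
        fit.akaike_weight = float(w)
    return fits
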