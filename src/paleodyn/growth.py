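"""Ricker-logistic population models with covariate-driven carrying capacity.

The population proxy N_t follows the exponential (Ricker) form of the discrete
logistic,

    N_t = N_{t-1} * exp(r_max * (1 - N_{t-1} / K)),

where the carrying capacity K is constant or a linear function of a
vegetation proxy (palm-pollen %, F) and/or a climate index (SOI-like, C)
evaluated one step earlier:

    K(F, C) = k0 + k_f * F + k_c * C.

Fitting works on realized per-capita growth rates R_t = ln N_t − ln N_{t-1}
via nonlinear least squares on

    R_t = r_max * (1 - N_{t-1} / K(F_{t-1}, C_{t-1})),

with a deterministic Latin-hypercube multistart. Candidate capacity forms are
compared by small-sample-corrected AIC (AICc) and Akaike weights; trajectory
uncertainty comes from multivariate-normal resampling of the estimates and
percentile bands over forward simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Union

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .series import CovariateSeries, DemographicSeries

__all__ = [
    "KForm",
    "GrowthModelSpec",
    "GrowthModelParams",
    "GrowthModelFit",
    "TrajectoryBand",
    "RatioRegression",
    "per_capita_growth",
    "carrying_capacity",
    "ricker_step",
    "fit_growth_model",
    "fit_model_set",
    "aicc",
    "akaike_weights",
    "simulate_trajectory",
    "prediction_r2",
    "trajectory_ci",
    "ratio_regression",
]

KForm = Literal["constant", "palm", "soi", "palm_soi"]
K_FORMS: tuple[str, ...] = ("constant", "palm", "soi", "palm_soi")

# free parameters per capacity form, in optimization order
_PARAM_NAMES = {
    "constant": ("r_max", "k0"),
    "palm": ("r_max", "k0", "k_f"),
    "soi": ("r_max", "k0", "k_c"),
    "palm_soi": ("r_max", "k0", "k_f", "k_c"),
}

_MULTISTART_SEED = 1729  # fixed: starts must be deterministic
_N_STARTS = 20


class InvalidCapacityError(ValueError):
    """Raised when K(F, C) is non-positive in a context that forbids it."""


@dataclass(frozen=True)
class GrowthModelSpec:
    """Which carrying-capacity form to fit and at what covariate lag (steps)."""

    k_form: KForm = "constant"
    lag: int = 1

    def __post_init__(self) -> None:
        if self.k_form not in K_FORMS:
            raise ValueError(f"unknown k_form {self.k_form!r}; choose from {K_FORMS}")
        if self.lag < 1:
            raise ValueError("lag must be >= 1")

    @property
    def param_names(self) -> tuple[str, ...]:
        return _PARAM_NAMES[self.k_form]

    @property
    def n_params(self) -> int:
        return len(self.param_names)


@dataclass(frozen=True)
class GrowthModelParams:
    """Ricker parameters; unused capacity coefficients stay at 0."""

    r_max: float
    k0: float
    k_f: float = 0.0
    k_c: float = 0.0

    def to_vector(self, spec: GrowthModelSpec) -> np.ndarray:
        return np.array([getattr(self, p) for p in spec.param_names])

    @classmethod
    def from_vector(cls, theta: Sequence[float], spec: GrowthModelSpec) -> "GrowthModelParams":
        d = dict(zip(spec.param_names, map(float, theta)))
        return cls(d["r_max"], d["k0"], d.get("k_f", 0.0), d.get("k_c", 0.0))


def carrying_capacity(params: GrowthModelParams, f=0.0, c=0.0, check: bool = True):
    """K = k0 + k_f·F + k_c·C (vectorized over f and c)."""
    k = params.k0 + params.k_f * np.asarray(f, dtype=float) + params.k_c * np.asarray(
        c, dtype=float
    )
    if check and np.any(k <= 0):
        raise InvalidCapacityError("carrying capacity K <= 0 in requested region")
    return k


def ricker_step(params: GrowthModelParams, n_prev, k):
    """One Ricker update: n_prev * exp(r_max * (1 − n_prev/K))."""
    n_prev = np.asarray(n_prev, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(n_prev <= 0):
        raise ValueError("n_prev must be > 0")
    if np.any(k <= 0):
        raise InvalidCapacityError("K must be > 0")
    out = n_prev * np.exp(params.r_max * (1.0 - n_prev / k))
    return float(out) if out.ndim == 0 else out


def per_capita_growth(series: DemographicSeries) -> np.ndarray:
    """Realized growth rates R_t = ln n_t − ln n_{t−1} (length len(n) − 1)."""
    return series.r_obs


@dataclass
class GrowthModelFit:
    spec: GrowthModelSpec
    params: GrowthModelParams
    covariance: np.ndarray
    rss: float
    n_obs: int
    aicc: float
    akaike_weight: Optional[float] = None
    pred_r2: Optional[float] = None
    n_starts_converged: int = 0

    def to_dict(self) -> dict:
        return {
            "k_form": self.spec.k_form,
            "lag": self.spec.lag,
            "params": {p: getattr(self.params, p) for p in self.spec.param_names},
            "covariance": np.asarray(self.covariance).tolist(),
            "rss": float(self.rss),
            "n_obs": int(self.n_obs),
            "aicc": float(self.aicc),
            "akaike_weight": None if self.akaike_weight is None else float(self.akaike_weight),
            "pred_r2": None if self.pred_r2 is None else float(self.pred_r2),
        }


def aicc(n_obs: int, n_params: int, rss: float) -> float:
    """Small-sample AIC, Gaussian errors: n·ln(rss/n) + 2k + 2k(k+1)/(n−k−1).

    ``n_params`` must already count every estimated quantity, including the
    error variance. The additive likelihood constant is omitted consistently,
    so only differences between models on the same data are meaningful.
    """
    k = n_params
    if n_obs <= k + 1:
        raise ValueError("AICc requires n_obs > n_params + 1")
    if rss <= 0:
        return -np.inf
    return n_obs * np.log(rss / n_obs) + 2 * k + 2 * k * (k + 1) / (n_obs - k - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Relative model plausibilities w_i ∝ exp(−Δ_i/2); sum to 1."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size < 2:
        raise ValueError("need at least two models to weight")
    finite = a[np.isfinite(a)]
    if finite.size == 0:
        raise ValueError("need at least one finite AICc value")
    delta = a - finite.min()
    w = np.exp(-0.5 * delta)
    w[~np.isfinite(a)] = 0.0  # +inf AICc -> zero weight
    return w / w.sum()


def _lagged_design(
    series: DemographicSeries, covariates: Optional[CovariateSeries], spec: GrowthModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(R_t, N_{t−1}, F_{t−lag}, C_{t−lag}) aligned for the fitting target."""
    r = per_capita_growth(series)
    lag = spec.lag
    if lag >= len(series.n):
        raise ValueError("lag too large for series length")
    # R_t corresponds to transitions t-1 -> t for t = 1..m; predictors at t-lag
    n_prev = series.n[:-1]
    m = len(r)
    idx = np.arange(1, m + 1) - lag  # covariate index per transition
    if np.any(idx < 0):
        # drop transitions without a lagged covariate (only when lag > 1)
        keep = idx >= 0
        r, n_prev, idx = r[keep], n_prev[keep], idx[keep]
    if spec.k_form in ("palm", "palm_soi") or spec.k_form in ("soi", "palm_soi"):
        if covariates is None:
            raise ValueError(f"k_form {spec.k_form!r} requires covariates")
    f = np.zeros_like(r)
    c = np.zeros_like(r)
    if covariates is not None:
        cov = covariates.on_step_grid(series.time_ce, series.step)
        if spec.k_form in ("palm", "palm_soi"):
            if cov.palm is None:
                raise ValueError("palm covariate missing")
            f = cov.palm[idx]
        if spec.k_form in ("soi", "palm_soi"):
            if cov.soi is None:
                raise ValueError("soi covariate missing")
            c = cov.soi[idx]
    return r, n_prev, f, c


def _predicted_r(
    theta: np.ndarray, spec: GrowthModelSpec, n_prev, f, c, k_floor: float = 0.0
) -> np.ndarray:
    p = GrowthModelParams.from_vector(theta, spec)
    k = carrying_capacity(p, f, c, check=False)
    safe_k = np.where(k > k_floor, k, np.nan if k_floor == 0.0 else k_floor)
    return p.r_max * (1.0 - n_prev / safe_k)


_PENALTY_GAIN = 10.0


def _k_and_grads(theta, spec, f, c):
    p = GrowthModelParams.from_vector(theta, spec)
    k = carrying_capacity(p, f, c, check=False)
    return p, k


def _residuals(theta, spec, r, n_prev, f, c, scale) -> np.ndarray:
    """Model residuals plus smooth K-positivity penalty rows."""
    p, k = _k_and_grads(theta, spec, f, c)
    k_floor = 1e-6 * scale
    bad = k < k_floor
    k_safe = np.where(bad, k_floor, k)
    resid = r - p.r_max * (1.0 - n_prev / k_safe)
    penalty = _PENALTY_GAIN * np.maximum(k_floor - k, 0.0) / scale
    return np.concatenate([resid, penalty])


def _residual_jac(theta, spec, r, n_prev, f, c, scale) -> np.ndarray:
    """Analytic Jacobian matching :func:`_residuals`."""
    p, k = _k_and_grads(theta, spec, f, c)
    m = len(r)
    k_floor = 1e-6 * scale
    bad = k < k_floor
    k_safe = np.where(bad, k_floor, k)
    dk = {"k0": np.ones_like(k), "k_f": f, "k_c": c}
    J = np.zeros((2 * m, spec.n_params))
    for j, name in enumerate(spec.param_names):
        if name == "r_max":
            J[:m, j] = -(1.0 - n_prev / k_safe)
        else:
            g = dk[name]
            # d resid / d param = -r_max * n_prev / K^2 * dK/dparam (0 where floored)
            J[:m, j] = np.where(bad, 0.0, -p.r_max * n_prev / k_safe**2 * g)
            J[m:, j] = np.where(bad, -_PENALTY_GAIN * g / scale, 0.0)
    return J


def _start_grid(spec: GrowthModelSpec, n_prev, f, c) -> np.ndarray:
    """Deterministic Latin-hypercube multistart over plausible parameter boxes."""
    d = spec.n_params
    sampler = qmc.LatinHypercube(d=d, seed=_MULTISTART_SEED)
    u = sampler.random(_N_STARTS)
    nmax = float(np.max(n_prev))
    lows, highs = [], []
    for name in spec.param_names:
        if name == "r_max":
            lows.append(0.05), highs.append(2.0)
        elif name == "k0":
            lows.append(0.1 * nmax), highs.append(4.0 * nmax)
        elif name == "k_f":
            fmax = max(float(np.max(np.abs(f))), 1e-9)
            lows.append(-2.0 * nmax / fmax), highs.append(2.0 * nmax / fmax)
        elif name == "k_c":
            cmax = max(float(np.max(np.abs(c))), 1e-9)
            lows.append(-2.0 * nmax / cmax), highs.append(2.0 * nmax / cmax)
    return qmc.scale(u, lows, highs)


def _smart_start(
    spec: GrowthModelSpec, r, n_prev, f, c, nmax: float
) -> Optional[np.ndarray]:
    """Start point from the first-order linearization of the growth model.

    Expanding R ≈ r − (r/k0)·N + (r·k_f/k0²)·N·F + (r·k_c/k0²)·N·C makes the
    model linear in (1, N, N·F, N·C); the OLS coefficients are solved back to
    Ricker parameters when their signs are admissible.
    """
    cols = [np.ones_like(r), n_prev]
    if "k_f" in spec.param_names:
        cols.append(n_prev * f)
    if "k_c" in spec.param_names:
        cols.append(n_prev * c)
    X = np.column_stack(cols)
    try:
        beta, *_ = np.linalg.lstsq(X, r, rcond=None)
    except np.linalg.LinAlgError:
        return None
    b0, b1 = beta[0], beta[1]
    if not (b0 > 0 and b1 < 0):
        return None
    r0, k0 = b0, -b0 / b1
    theta = [r0, k0]
    i = 2
    if "k_f" in spec.param_names:
        theta.append(float(beta[i] * k0**2 / r0))
        i += 1
    if "k_c" in spec.param_names:
        theta.append(float(beta[i] * k0**2 / r0))
    return np.asarray(theta)


def fit_growth_model(
    series: DemographicSeries,
    covariates: Optional[CovariateSeries],
    spec: GrowthModelSpec,
    n_polish: int = 10,
) -> GrowthModelFit:
    """Nonlinear-least-squares fit of the growth-rate model for one K form.

    Minimizes Σ (R_t − r_max·(1 − N_{t−1}/K(F_{t−1}, C_{t−1})))² over the
    free parameters. Candidate starts are 20 deterministic Latin-hypercube
    points plus one linearization-based start; the ``n_polish`` starts with
    the lowest initial cost are run to convergence and the best residual sum
    of squares wins (ties to the earliest start). The parameter covariance is
    the asymptotic Gauss–Newton estimate s²(JᵀJ)⁻¹.
    """
    r, n_prev, f, c = _lagged_design(series, covariates, spec)
    m = len(r)
    if m < spec.n_params + 3:
        raise ValueError(
            f"need >= {spec.n_params + 3} growth-rate observations for {spec.k_form}, got {m}"
        )
    scale = float(np.max(n_prev))
    starts = _start_grid(spec, n_prev, f, c)
    smart = _smart_start(spec, r, n_prev, f, c, scale)
    if smart is not None:
        starts = np.vstack([smart, starts])
    best = None
    n_ok = 0
    lb = np.full(spec.n_params, -np.inf)
    ub = np.full(spec.n_params, np.inf)
    lb[0] = 1e-8  # r_max is a positive rate
    ub[0] = 10.0
    if n_polish < len(starts):
        costs = [
            float(np.sum(_residuals(np.clip(s, lb, ub), spec, r, n_prev, f, c, scale) ** 2))
            for s in starts
        ]
        starts = starts[np.argsort(costs, kind="stable")[:n_polish]]
    for theta0 in starts:
        try:
            res = optimize.least_squares(
                _residuals,
                np.clip(theta0, lb, ub),
                jac=_residual_jac,
                args=(spec, r, n_prev, f, c, scale),
                bounds=(lb, ub),
                method="trf",
                xtol=1e-11,
                ftol=1e-11,
                gtol=1e-11,
                max_nfev=200,
            )
        except Exception:
            continue
        if not res.success and not np.isfinite(res.cost):
            continue
        n_ok += 1
        # rss under the same floored-K convention as the objective, so a
        # start ending in the penalized region still yields a comparable value
        pred = _predicted_r(res.x, spec, n_prev, f, c, k_floor=1e-6 * scale)
        if np.any(~np.isfinite(pred)):
            continue
        rss_model = float(np.sum((r - pred) ** 2))
        cost = rss_model + float(
            np.sum(_residuals(res.x, spec, r, n_prev, f, c, scale)[len(r):] ** 2)
        )
        if best is None or cost < best[0] - 1e-15:
            best = (cost, rss_model, res)
    if best is None:
        raise RuntimeError(
            f"nonlinear fit failed to converge from any of {_N_STARTS} starts "
            f"(k_form={spec.k_form})"
        )
    _, rss, res = best
    params = GrowthModelParams.from_vector(res.x, spec)
    # asymptotic covariance from the model-residual Jacobian at the optimum
    J = _residual_jac(res.x, spec, r, n_prev, f, c, scale)[: len(r)]
    dof = max(m - spec.n_params, 1)
    s2 = rss / dof
    try:
        cov = s2 * np.linalg.pinv(J.T @ J)
    except np.linalg.LinAlgError:
        cov = np.full((spec.n_params, spec.n_params), np.nan)
    fit = GrowthModelFit(
        spec=spec,
        params=params,
        covariance=cov,
        rss=rss,
        n_obs=m,
        aicc=aicc(m, spec.n_params + 1, rss),
        n_starts_converged=n_ok,
    )
    # coefficient of prediction from the full forward simulation
    try:
        traj = simulate_trajectory(fit, float(series.n[0]), covariates, series.time_ce)
        fit.pred_r2 = prediction_r2(series.n, traj)
    except (InvalidCapacityError, ValueError):
        fit.pred_r2 = None
    return fit


def fit_model_set(
    series: DemographicSeries,
    covariates: Optional[CovariateSeries],
    k_forms: Sequence[str] = K_FORMS,
    lag: int = 1,
) -> list[GrowthModelFit]:
    """Fit every candidate capacity form and attach Akaike weights."""
    fits = [
        fit_growth_model(series, covariates, GrowthModelSpec(kf, lag)) for kf in k_forms
    ]
    for fit, w in zip(fits, akaike_weights([f.aicc for f in fits])):
        fit.akaike_weight = float(w)
    return fits


def simulate_trajectory(
    fit_or_params: Union[GrowthModelFit, GrowthModelParams],
    n0: float,
    covariates: Optional[CovariateSeries],
    time_ce: np.ndarray,
    spec: Optional[GrowthModelSpec] = None,
    on_invalid_k: Literal["truncate", "error"] = "truncate",
) -> np.ndarray:
    """Deterministically iterate the fitted model forward from n0.

    The step from t−1 to t uses K(F, C) evaluated ``lag`` steps before t.
    Non-positive K is truncated to a small positive floor with a warning
    (or raises, per ``on_invalid_k``).
    """
    if isinstance(fit_or_params, GrowthModelFit):
        params, spec = fit_or_params.params, fit_or_params.spec
    else:
        params = fit_or_params
        spec = spec or GrowthModelSpec("constant")
    time_ce = np.asarray(time_ce, dtype=float)
    step = time_ce[1] - time_ce[0]
    f = np.zeros_like(time_ce)
    c = np.zeros_like(time_ce)
    if covariates is not None:
        cov = covariates.on_step_grid(time_ce, step)
        if cov.palm is not None:
            f = cov.palm
        if cov.soi is not None:
            c = cov.soi
    n = np.empty_like(time_ce)
    n[0] = n0
    floor = 1e-6 * max(n0, params.k0 if params.k0 > 0 else 1.0)
    for t in range(1, len(time_ce)):
        j = max(t - spec.lag, 0)
        k = float(carrying_capacity(params, f[j], c[j], check=False))
        if k <= 0:
            if on_invalid_k == "error":
                raise InvalidCapacityError(
                    f"K <= 0 at step {t} (time {time_ce[t]:g} CE)"
                )
            warnings.warn(
                f"K <= 0 at time {time_ce[t]:g} CE; truncated to positive floor",
                stacklevel=2,
            )
            k = floor
        n[t] = ricker_step(params, n[t - 1], k)
    return n


def prediction_r2(observed, predicted) -> float:
    """Coefficient of prediction 1 − Σ(Y−X)²/Σ(X−mean X)²; may be negative."""
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("observed and predicted must share length >= 2")
    denom = np.sum((x - x.mean()) ** 2)
    if denom == 0:
        raise ValueError("observed series is constant")
    return float(1.0 - np.sum((y - x) ** 2) / denom)


@dataclass
class TrajectoryBand:
    """Point trajectory with percentile uncertainty bounds."""

    time_ce: np.ndarray
    point: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    level: float
    n_iter: int
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if np.any(self.lo > self.hi):
            raise ValueError("band requires lo <= hi")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_ce": self.time_ce, "point": self.point, "lo": self.lo, "hi": self.hi}
        )


def trajectory_ci(
    fit: GrowthModelFit,
    n0: float,
    covariates: Optional[CovariateSeries],
    time_ce: np.ndarray,
    n_iter: int = 10_000,
    level: float = 0.95,
    rng: Union[int, np.random.Generator, None] = 0,
) -> TrajectoryBand:
    """Percentile confidence band for the simulated trajectory.

    Parameter vectors are resampled from the asymptotic multivariate normal of
    the estimates; each draw is simulated forward and per-time percentile
    bounds are taken. Draws that put K ≤ 0 anywhere along the horizon are
    rejected; a rejection rate above 50% aborts with advice to
    reparameterize.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    time_ce = np.asarray(time_ce, dtype=float)
    step = time_ce[1] - time_ce[0]
    spec = fit.spec
    f = np.zeros_like(time_ce)
    c = np.zeros_like(time_ce)
    if covariates is not None:
        cov_al = covariates.on_step_grid(time_ce, step)
        if cov_al.palm is not None:
            f = cov_al.palm
        if cov_al.soi is not None:
            c = cov_al.soi

    mean = fit.params.to_vector(spec)
    cov = np.asarray(fit.covariance, dtype=float)
    if not np.all(np.isfinite(cov)):
        raise ValueError("fit covariance is not finite")
    # symmetrize and draw; PSD enforced through eigenvalue clipping
    cov = 0.5 * (cov + cov.T)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    draws = mean + rng.standard_normal((n_iter, len(mean))) @ (
        evecs * np.sqrt(evals)
    ).T

    # indices of the lagged covariate for each step
    jdx = np.maximum(np.arange(1, len(time_ce)) - spec.lag, 0)
    names = spec.param_names
    r_d = draws[:, names.index("r_max")]
    k0_d = draws[:, names.index("k0")]
    kf_d = draws[:, names.index("k_f")] if "k_f" in names else np.zeros(n_iter)
    kc_d = draws[:, names.index("k_c")] if "k_c" in names else np.zeros(n_iter)
    K = k0_d[:, None] + kf_d[:, None] * f[jdx][None, :] + kc_d[:, None] * c[jdx][None, :]
    valid = (r_d > 0) & np.all(K > 0, axis=1)
    n_rej = int(n_iter - valid.sum())
    if n_rej > 0.5 * n_iter:
        raise RuntimeError(
            f"{n_rej}/{n_iter} parameter draws give invalid K; "
            "consider reparameterizing the capacity model"
        )
    r_v, K_v = r_d[valid], K[valid]
    n_traj = np.empty((int(valid.sum()), len(time_ce)))
    n_traj[:, 0] = n0
    for t in range(1, len(time_ce)):
        prev = n_traj[:, t - 1]
        n_traj[:, t] = prev * np.exp(r_v * (1.0 - prev / K_v[:, t - 1]))
    alpha = 100.0 * (1.0 - level) / 2.0
    lo = np.percentile(n_traj, alpha, axis=0)
    hi = np.percentile(n_traj, 100.0 - alpha, axis=0)
    point = simulate_trajectory(fit, n0, covariates, time_ce)
    return TrajectoryBand(time_ce, point, lo, hi, level, n_iter, n_rej)


@dataclass(frozen=True)
class RatioRegression:
    slope: float
    intercept: float
    f_stat: float
    df: tuple[int, int]
    r2: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "F": self.f_stat,
            "df": list(self.df),
            "r2": self.r2,
            "p_value": self.p_value,
        }


def ratio_regression(r_obs, ratio) -> RatioRegression:
    """OLS of growth rate on a per-capita resource ratio (N/F or N/C).

    A linear R-vs-ratio relationship is the signature of a carrying capacity
    proportional to the resource: R = r_max − (r_max/k)·(N/resource).
    """
    import statsmodels.api as sm

    y = np.asarray(r_obs, dtype=float)
    x = np.asarray(ratio, dtype=float)
    if y.shape != x.shape or y.size < 3:
        raise ValueError("need equal-length vectors with >= 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("ratio vector is constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RatioRegression(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        f_stat=float(model.fvalue),
        df=(int(model.df_model), int(model.df_resid)),
        r2=float(model.rsquared),
        p_value=float(model.f_pvalue),
    )
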