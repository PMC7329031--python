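"""Shared fixtures: synthetic curves, oracle integrators, small date sets."""

from __future__ import annotations

import numpy as np
import pytest

from paleodyn.calibration import CalibrationCurve
from paleodyn.synthetic import synthetic_calibration_curve


def make_identity_curve(lo: int = 0, hi: int = 3000) -> CalibrationCurve:
    """Curve with mu(theta) = theta and zero curve error."""
    grid = np.arange(lo, hi + 1, dtype=float)
    return CalibrationCurve(grid, grid.copy(), np.zeros_like(grid), name="identity")


def make_random_smooth_curve(rng: np.random.Generator, lo=0, hi=2200, step=1) -> CalibrationCurve:
    """Random but realistically smooth curve: monotone 14C age with mild
    wiggles and a slowly varying error column."""
    knots = np.arange(lo, hi + 1, step, dtype=float)
    mu = knots + rng.uniform(-80, 120)
    for _ in range(3):
        amp = rng.uniform(3, 25)
        per = rng.uniform(80, 600)
        ph = rng.uniform(0, 2 * np.pi)
        if 2 * np.pi * amp / per > 0.3:
            amp = 0.3 * per / (2 * np.pi)  # keep overall slope positive
        mu = mu + amp * np.sin(2 * np.pi * knots / per + ph)
    sig = rng.uniform(8, 15) + rng.uniform(2, 6) * np.sin(
        2 * np.pi * knots / rng.uniform(200, 800) + rng.uniform(0, 2 * np.pi)
    )
    return CalibrationCurve(knots, mu, sig, name="random-smooth")


def oracle_calibrated_density(
    age: float, error: float, curve: CalibrationCurve, years: np.ndarray, sub: int = 400
) -> np.ndarray:
    """Brute-force fine-grid trapezoid integration of the calibration
    likelihood over each yearly cell, normalized to sum one. Independent of
    the package's Simpson-based implementation."""
    h = 1.0 / sub
    out = np.empty(len(years))
    for i, y in enumerate(years):
        t = y - 0.5 + h * np.arange(sub + 1)
        mu = np.interp(t, curve.cal_bp, curve.mu_14c)
        v = error**2 + np.interp(t, curve.cal_bp, curve.sigma_curve) ** 2
        f = np.exp(-0.5 * (age - mu) ** 2 / v) / np.sqrt(2.0 * np.pi * v)
        out[i] = np.trapezoid(f, dx=h)
    return out / out.sum()


@pytest.fixture(scope="session")
def synth_curve() -> CalibrationCurve:
    return synthetic_calibration_curve()


@pytest.fixture()
def identity_curve() -> CalibrationCurve:
    return make_identity_curve()
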