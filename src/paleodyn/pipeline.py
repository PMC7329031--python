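"""End-to-end pipeline: SPD construction, model fitting, reporting.

Artifacts are written as diffable CSV/JSON, schema-validated by re-reading
each file after writing. The run log goes to stderr with a run ID; the JSON
report carries the configuration hash for provenance and contains no
timestamps, so identical configs and seeds reproduce byte-identical reports.
"""

from __future__ import annotations

import logging
import uuid
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .calibration import ReservoirCorrection, read_calibration_curve
from .config import PipelineConfig
from .growth import fit_model_set, ratio_regression, trajectory_ci
from .io import (
    read_covariates_csv,
    read_dates_csv,
    read_json,
    read_pollen_csv,
    write_json,
)
from .series import CovariateSeries
from .spd import build_spd, mc_null_envelope, resample_interval
from .vegetation import align_pollen_predictors, fit_vegetation_set

__all__ = ["run_full_pipeline", "PipelineError"]

logger = logging.getLogger("paleodyn.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def _write_frame(df: pd.DataFrame, path: Path) -> None:
    """Write a CSV and validate the round trip (schema + values)."""
    df.to_csv(path, index=False)
    back = pd.read_csv(path)
    if list(back.columns) != list(df.columns):
        raise PipelineError(f"round-trip schema mismatch for {path}")
    for col in df.columns:
        if not np.allclose(back[col].to_numpy(dtype=float), df[col].to_numpy(dtype=float),
                           rtol=0, atol=1e-9, equal_nan=True):
            raise PipelineError(f"round-trip value mismatch for {path}:{col}")


def _write_report(obj: dict, path: Path) -> None:
    write_json(obj, path)
    if read_json(path) != obj:
        raise PipelineError(f"round-trip mismatch for {path}")


def run_full_pipeline(config: PipelineConfig, stages: Optional[set[str]] = None) -> dict:
    """Execute spd → resample → null test → model fits → CIs → regressions.

    ``stages`` may restrict execution to a subset of
    {"spd", "nulltest", "fit", "simulate", "ratio", "vegfit"}; stages that
    feed a requested stage always run. Returns the report dictionary (also
    written to ``<outdir>/report.json``).
    """
    all_stages = {"spd", "nulltest", "fit", "simulate", "ratio", "vegfit"}
    stages = set(stages) if stages is not None else set(all_stages)
    if stages - all_stages:
        raise PipelineError(f"unknown stages {sorted(stages - all_stages)}")
    if stages & {"fit", "simulate", "ratio", "vegfit"}:
        stages.add("spd")
    if stages & {"simulate", "ratio"}:
        stages.add("fit")

    run_id = uuid.uuid4().hex[:8]
    log = logging.LoggerAdapter(logger, {})
    logging.basicConfig(level=logging.INFO)
    log.info("[run %s] config hash %s seed %d", run_id, config.config_hash(), config.seed)

    config.validate_options()
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "artifacts": {},
    }

    def _stage(name):
        log.info("[run %s] stage %s", run_id, name)

    # ---- inputs -------------------------------------------------------
    try:
        terrestrial = read_calibration_curve(config.curve_terrestrial)
        marine = (
            read_calibration_curve(config.curve_marine) if config.curve_marine else None
        )
        reservoir = ReservoirCorrection(
            config.reservoir_delta_r, config.reservoir_delta_r_error
        )
        dates = read_dates_csv(config.dates)
        covariates = read_covariates_csv(config.covariates)
    except Exception as exc:  # noqa: BLE001 - stage context for any input failure
        raise PipelineError(f"stage 'inputs' failed: {exc}") from exc

    # ---- SPD ----------------------------------------------------------
    _stage("spd")
    try:
        spd, n_bins = build_spd(
            dates,
            terrestrial,
            marine,
            reservoir,
            bin_width=config.bin_width,
            smooth_window=config.smooth_window,
            drop_modern=config.drop_modern,
        )
        demo_full = resample_interval(spd, config.step, config.start_ce)
        demo = demo_full.window(*config.window_ce)
    except Exception as exc:
        raise PipelineError(f"stage 'spd' failed on {config.dates}: {exc}") from exc
    _write_frame(spd.to_frame(), outdir / "spd.csv")
    _write_frame(demo.to_frame(), outdir / "demographic.csv")
    report["artifacts"]["spd"] = "spd.csv"
    report["artifacts"]["demographic"] = "demographic.csv"
    report["spd"] = {"n_bins": int(n_bins), "n_dates": len(dates)}

    # ---- Monte-Carlo null test ---------------------------------------
    if "nulltest" in stages and config.run_nulltest:
        _stage("nulltest")
        try:
            null = mc_null_envelope(
                dates,
                terrestrial,
                marine,
                reservoir,
                null_model=config.null_model,
                n_sim=config.n_sim,
                level=config.envelope_level,
                rng=config.seed,
                bin_width=config.bin_width,
                smooth_window=config.smooth_window,
                drop_modern=config.drop_modern,
            )
        except Exception as exc:
            raise PipelineError(f"stage 'nulltest' failed: {exc}") from exc
        _write_frame(null.to_frame(), outdir / "nulltest_envelope.csv")
        _write_report(null.summary(), outdir / "nulltest.json")
        report["artifacts"]["nulltest"] = "nulltest.json"
        report["nulltest"] = null.summary()

    # ---- growth-model fits -------------------------------------------
    fits = None
    if "fit" in stages:
        _stage("fit")
        try:
            fits = fit_model_set(demo, covariates, config.k_forms, config.lag)
        except Exception as exc:
            raise PipelineError(f"stage 'fit' failed: {exc}") from exc
        report["fits"] = [f.to_dict() for f in fits]
        _write_report({"models": report["fits"]}, outdir / "fits.json")
        report["artifacts"]["fits"] = "fits.json"

    # ---- trajectories with uncertainty bands -------------------------
    if "simulate" in stages and fits is not None:
        _stage("simulate")
        report["trajectory_notes"] = {}
        for fit in fits:
            try:
                band = trajectory_ci(
                    fit,
                    float(demo.n[0]),
                    covariates,
                    demo.time_ce,
                    n_iter=config.ci_n_iter,
                    level=config.ci_level,
                    rng=config.seed,
                )
            except RuntimeError as exc:
                # a weakly identified model (e.g. constant K on boom-bust
                # data) can reject most parameter draws; report, don't abort
                log.warning("[run %s] no CI band for %s: %s", run_id, fit.spec.k_form, exc)
                report["trajectory_notes"][fit.spec.k_form] = str(exc)
                continue
            except Exception as exc:
                raise PipelineError(
                    f"stage 'simulate' failed for {fit.spec.k_form}: {exc}"
                ) from exc
            _write_frame(band.to_frame(), outdir / f"trajectory_{fit.spec.k_form}.csv")
            report["artifacts"][f"trajectory_{fit.spec.k_form}"] = (
                f"trajectory_{fit.spec.k_form}.csv"
            )

    # ---- ratio regressions -------------------------------------------
    if "ratio" in stages:
        _stage("ratio")
        try:
            cov_grid = covariates.on_step_grid(demo.time_ce, demo.step)
            r = demo.r_obs
            ratios = {}
            if cov_grid.palm is not None:
                ratios["n_over_palm"] = ratio_regression(
                    r, demo.n[:-1] / cov_grid.palm[:-1]
                ).to_dict()
            if cov_grid.soi is not None:
                ratios["n_over_soi"] = ratio_regression(
                    r, demo.n[:-1] / cov_grid.soi[:-1]
                ).to_dict()
        except Exception as exc:
            raise PipelineError(f"stage 'ratio' failed: {exc}") from exc
        _write_report(ratios, outdir / "ratio_regressions.json")
        report["artifacts"]["ratio_regressions"] = "ratio_regressions.json"
        report["ratio_regressions"] = ratios

    # ---- vegetation model --------------------------------------------
    if "vegfit" in stages:
        _stage("vegfit")
        try:
            if config.pollen:
                pollen_df = read_pollen_csv(config.pollen)
            elif covariates.palm is not None:
                pollen_df = pd.DataFrame(
                    {"time_ce": demo.time_ce, "palm_pct": covariates.on_step_grid(
                        demo.time_ce, demo.step
                    ).palm}
                )
            else:
                raise ValueError("no pollen data available")
            soi_series = CovariateSeries(covariates.time_ce, None, covariates.soi)
            table = align_pollen_predictors(pollen_df, spd, soi_series, window=config.step)
            veg_fits = fit_vegetation_set(table)
        except Exception as exc:
            raise PipelineError(f"stage 'vegfit' failed: {exc}") from exc
        veg = {"models": [f.to_dict() for f in veg_fits]}
        _write_report(veg, outdir / "vegetation.json")
        report["artifacts"]["vegetation"] = "vegetation.json"
        report["vegetation"] = veg

    _write_report(report, outdir / "report.json")
    log.info("[run %s] done; artifacts in %s", run_id, outdir)
    return report
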