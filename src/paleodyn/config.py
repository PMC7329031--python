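"""Pipeline configuration: defaults, YAML loading, validation, provenance hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .growth import K_FORMS

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


@dataclass
class PipelineConfig:
    """End-to-end analysis settings with study defaults.

    Defaults encode the study conditions: 50-yr site bins, a 100-yr rolling
    mean, 30-yr demographic steps starting at 890 CE, an analysis window of
    1100-1760 CE, a linear Monte-Carlo null with 1000 simulations at the 95%
    level, the four carrying-capacity forms, and 10 000 draws for 95%
    trajectory bands.
    """

    # paths
    curve_terrestrial: str = ""
    curve_marine: Optional[str] = None
    dates: str = ""
    covariates: str = ""
    pollen: Optional[str] = None
    outdir: str = "paleodyn_out"
    # marine reservoir correction (years)
    reservoir_delta_r: float = -83.0
    reservoir_delta_r_error: float = 34.0
    # SPD options
    bin_width: float = 50.0
    smooth_window: int = 100
    step: int = 30
    start_ce: float = 890.0
    window_ce: tuple[float, float] = (1100.0, 1760.0)
    drop_modern: bool = True
    # null-test options
    run_nulltest: bool = True
    null_model: str = "linear"
    n_sim: int = 1000
    envelope_level: float = 95.0
    # model set
    k_forms: tuple[str, ...] = K_FORMS
    lag: int = 1
    # trajectory CI options
    ci_n_iter: int = 10_000
    ci_level: float = 0.95
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        self.k_forms = tuple(self.k_forms)
        self.window_ce = tuple(float(v) for v in self.window_ce)
        self.validate_options()

    def validate_options(self) -> None:
        for kf in self.k_forms:
            if kf not in K_FORMS:
                raise ConfigError(f"unknown k_form {kf!r}; choose from {K_FORMS}")
        if not self.k_forms:
            raise ConfigError("model set is empty")
        if self.bin_width <= 0 or self.smooth_window < 1 or self.step < 1:
            raise ConfigError("bin_width, smooth_window and step must be positive")
        if self.null_model not in ("linear", "exponential"):
            raise ConfigError(f"unknown null model {self.null_model!r}")
        if self.n_sim < 2:
            raise ConfigError("n_sim must be >= 2")
        if not 50.0 <= self.envelope_level < 100.0:
            raise ConfigError("envelope level must lie in [50, 100)")
        if not 0.0 < self.ci_level < 1.0:
            raise ConfigError("ci_level must lie in (0, 1)")
        if self.ci_n_iter < 2:
            raise ConfigError("ci_n_iter must be >= 2")
        if self.window_ce[1] <= self.window_ce[0]:
            raise ConfigError("analysis window must be increasing")
        if self.lag < 1:
            raise ConfigError("lag must be >= 1")
        if self.reservoir_delta_r_error < 0:
            raise ConfigError("reservoir_delta_r_error must be >= 0")

    def validate_paths(self) -> None:
        required = {"curve_terrestrial": self.curve_terrestrial, "dates": self.dates,
                    "covariates": self.covariates}
        for name, p in required.items():
            if not p:
                raise ConfigError(f"config field {name!r} is required")
            if not Path(p).exists():
                raise ConfigError(f"{name}: file not found: {p}")
        for name, p in (("curve_marine", self.curve_marine), ("pollen", self.pollen)):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name}: file not found: {p}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path], seed: Optional[int] = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping of options")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        if seed is not None:
            cfg.seed = int(seed)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_forms"] = list(self.k_forms)
        d["window_ce"] = list(self.window_ce)
        return d

    def config_hash(self) -> str:
        """Stable provenance hash of the configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
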