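"""Run configuration: one validated record for every tunable the toolkit has.

A config file (YAML) sets any subset of keys; CLI flags override file
values.  Unknown keys are rejected so a typo cannot silently fall back to
a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import yaml

from .catalog import DEFAULT_CLASSIFY_TOLERANCE
from .errors import ValidationError
from .light import (
    DEFAULT_COVERAGE_THRESHOLD,
    DEFAULT_HALF_BAND_NM,
    DEFAULT_WATER_WINDOW,
)
from .photomap import PhysicalConstants
from .spectra import DEFAULT_MIN_SNR, DEFAULT_N_POINTS


@dataclass(frozen=True)
class RunConfig:
    scale: str = "eiip_protein"
    n_points: int = DEFAULT_N_POINTS
    min_snr: float = DEFAULT_MIN_SNR
    classify_tolerance: float = DEFAULT_CLASSIFY_TOLERANCE
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD
    half_band_nm: float = DEFAULT_HALF_BAND_NM
    water_window: tuple[float, float] = DEFAULT_WATER_WINDOW
    output_dir: str = "."
    log_level: str = "INFO"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_points < 4:
            raise ValidationError(f"n_points must be >= 4, got {self.n_points}")
        if self.min_snr < 0:
            raise ValidationError(f"min_snr must be >= 0, got {self.min_snr}")
        if self.classify_tolerance < 0:
            raise ValidationError("classify_tolerance must be >= 0")
        if not 0 < self.coverage_threshold < 1:
            raise ValidationError("coverage_threshold must be in (0, 1)")
        if self.half_band_nm <= 0:
            raise ValidationError("half_band_nm must be positive")
        if not self.water_window[0] < self.water_window[1]:
            raise ValidationError("water_window must satisfy min < max")
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValidationError(f"unknown log level {self.log_level!r}")


_CONSTANT_KEYS = {"K", "charge_velocity", "residue_spacing", "light_speed"}


def load_config(path: str | Path | None = None, **overrides: Any) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    File keys mirror the dataclass fields; the nested ``constants`` mapping
    takes the PhysicalConstants field names.  Unknown keys raise.
    """
    data: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        data.update(loaded)
    for key, value in overrides.items():
        if value is not None:
            data[key] = value

    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(
            f"unknown config key(s): {', '.join(sorted(unknown))}; "
            f"valid keys: {', '.join(sorted(known))}"
        )
    if "constants" in data and isinstance(data["constants"], dict):
        bad = set(data["constants"]) - _CONSTANT_KEYS
        if bad:
            raise ValidationError(
                f"unknown constants key(s): {', '.join(sorted(bad))}"
            )
        data["constants"] = PhysicalConstants(**data["constants"])
    if "water_window" in data and not isinstance(data["water_window"], tuple):
        window = data["water_window"]
        if not (isinstance(window, (list, tuple)) and len(window) == 2):
            raise ValidationError("water_window must be a [min, max] pair")
        data["water_window"] = (float(window[0]), float(window[1]))
    return RunConfig(**data)


def config_as_dict(config: RunConfig) -> dict[str, Any]:
    constants = config.constants
    return {
        "scale": config.scale,
        "n_points": config.n_points,
        "min_snr": config.min_snr,
        "classify_tolerance": config.classify_tolerance,
        "constants": {
            "K": constants.K,
            "charge_velocity": constants.charge_velocity,
            "residue_spacing": constants.residue_spacing,
            "light_speed": constants.light_speed,
        },
        "coverage_threshold": config.coverage_threshold,
        "half_band_nm": config.half_band_nm,
        "water_window": list(config.water_window),
        "output_dir": config.output_dir,
        "log_level": config.log_level,
        "seed": config.seed,
    }
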