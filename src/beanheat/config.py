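"""Run-wide configuration shared by every pipeline stage.

All temperatures are in degrees Celsius, CO2 concentrations in µmol mol⁻¹,
irradiance in µmol photons m⁻² s⁻¹. Nothing converts units silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration file or value violates the schema."""


@dataclass
class AnalysisConfig:
    """Tunable knobs of the full analysis.

    Parameters
    ----------
    reference_temperature
        Ambient temperature (°C) at which covariance-adjusted genotype
        responses are evaluated, and the threshold used for the annual
        "hot day" count in the climatology stage.
    ca_reference
        Ambient CO2 set point (µmol mol⁻¹) used for stomatal-limitation
        when no per-row Ca column is present.
    sowing_doy
        Day of year of sowing for each season window.
    window_start, window_end
        Season risk window, in days after sowing, both endpoints included.
    day_threshold, night_threshold
        Daily Tmax / Tmin exceedance thresholds (°C).
    lsp_fraction
        Fraction of gross light-saturated assimilation that defines the
        light saturation point; must lie strictly inside (0, 1).
    gamma_grid_step
        Resolution (°C) of the exhaustive join-point search of the
        two-segment thermal model.
    gamma_margin
        Fraction of the x-range excluded at each end of the join-point
        search grid (the grid covers the central 1 - 2*margin of the range).
    correlation_granularity
        'records' or 'genotypes': whether trait correlation matrices are
        computed on raw observations or on per-genotype means.
    stressed_year_role
        'second' (default) or 'first': which experiment plays the stressed
        (numerator) role in the stress-intensity index.
    """

    reference_temperature: float = 27.74
    ca_reference: float = 400.0
    sowing_doy: int = 60
    window_start: int = 20
    window_end: int = 60
    day_threshold: float = 30.0
    night_threshold: float = 20.0
    seed: int = 0
    lsp_fraction: float = 0.90
    gamma_grid_step: float = 0.01
    gamma_margin: float = 0.05
    correlation_granularity: str = "genotypes"
    stressed_year_role: str = "second"
    permutations: int = 999
    kmax: int = 8
    column_aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.lsp_fraction < 1.0):
            raise ConfigError(
                f"lsp_fraction must lie in (0, 1), got {self.lsp_fraction}"
            )
        if self.gamma_grid_step <= 0:
            raise ConfigError("gamma_grid_step must be positive")
        if self.window_start >= self.window_end:
            raise ConfigError("window_start must precede window_end")
        if self.correlation_granularity not in ("records", "genotypes"):
            raise ConfigError(
                "correlation_granularity must be 'records' or 'genotypes'"
            )
        if self.stressed_year_role not in ("first", "second"):
            raise ConfigError("stressed_year_role must be 'first' or 'second'")
        for name in ("reference_temperature", "day_threshold", "night_threshold"):
            value = float(getattr(self, name))
            if value != value or value in (float("inf"), float("-inf")):
                raise ConfigError(f"{name} must be finite")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an AnalysisConfig from a YAML key: value file."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a key: value mapping")
    known = {f.name for f in AnalysisConfig.__dataclass_fields__.values()}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return AnalysisConfig(**raw)
    except TypeError as exc:  # wrong value type
        raise ConfigError(str(exc)) from exc


def save_config(cfg: AnalysisConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
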