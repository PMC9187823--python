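"""Run configuration: typed, range-checked parameters for the full pipeline.

Configs are flat ``key = value`` text files. Every stage parameter has a
default matching the method's stated values (2-min increments, 20-min
maximum, 50-m mapping grid, 4.7 km/h standard pedestrian); unknown keys are
rejected so typos fail loudly. An echo of the effective config accompanies
every output.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    stages: tuple[str, ...] = ("simulate", "isochrones", "exposure", "index", "map", "validate")
    increment_min: float = 2.0
    max_time_min: float = 20.0
    buffer_m: float = 40.0
    max_snap_m: float = 500.0
    logit_b: float = 0.005
    logit_m: float | None = None          # None -> half the outermost ring distance
    n_iterations: int = 20
    drop_threshold: float = 0.05
    variant: str = "combined"
    speed_kmh: float = 4.7
    grid_m: float = 50.0
    test_fraction: float = 0.2
    cv_folds: int = 10
    seed: int = 0
    # synthetic-scenario knobs (only used when the simulate stage runs)
    extent_m: float = 5000.0
    street_spacing: float = 150.0
    street_irregularity: float = 0.3
    n_census_areas: int = 120
    ses_spatial_range: float = 800.0
    ndvi_smoothness: float = 300.0
    ndvi_ses_coupling: float = -0.4
    n_participants: int = 5125
    true_index_log_or: float = 0.5
    target_prevalence: float = 0.099
    input_dir: str | None = None
    out_dir: str = "run"
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.increment_min <= 0 or self.max_time_min <= 0:
            raise ConfigError("time parameters must be positive")
        n = self.max_time_min / self.increment_min
        if abs(n - round(n)) > 1e-9:
            raise ConfigError("max_time_min must be divisible by increment_min")
        if self.buffer_m <= 0:
            raise ConfigError("buffer_m must be positive")
        if self.logit_b < 0:
            raise ConfigError("logit_b must be non-negative")
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")
        if self.speed_kmh <= 0 or self.grid_m <= 0:
            raise ConfigError("speed and grid size must be positive")
        if not 0 < self.test_fraction < 1:
            raise ConfigError("test_fraction must be in (0, 1)")
        if self.variant not in ("combined", "ses_only", "greenspace_only"):
            raise ConfigError(f"unknown variant {self.variant!r}")
        unknown = [s for s in self.stages if s not in
                   ("simulate", "isochrones", "exposure", "index", "map", "validate")]
        if unknown:
            raise ConfigError(f"unknown stage(s): {unknown}")

    def echo(self) -> dict:
        doc = asdict(self)
        doc.pop("extra", None)
        return doc


_FIELD_TYPES = {f.name: f for f in fields(RunConfig)}
_BOOLS = {"true": True, "false": False, "yes": True, "no": False}


def _coerce(name: str, raw: str):
    raw = raw.strip()
    if raw.lower() in ("none", ""):
        return None
    if name == "stages":
        return tuple(s.strip() for s in raw.split(",") if s.strip())
    default = getattr(RunConfig, name, None)
    if isinstance(default, bool):
        if raw.lower() not in _BOOLS:
            raise ConfigError(f"{name}: expected a boolean, got {raw!r}")
        return _BOOLS[raw.lower()]
    if isinstance(default, int) and not isinstance(default, bool):
        try:
            return int(raw)
        except ValueError as err:
            raise ConfigError(f"{name}: expected an integer, got {raw!r}") from err
    if isinstance(default, float):
        try:
            return float(raw)
        except ValueError as err:
            raise ConfigError(f"{name}: expected a number, got {raw!r}") from err
    if name in ("logit_m", "input_dir"):
        return float(raw) if name == "logit_m" else raw
    return raw


def validate_config(text: str) -> RunConfig:
    """Parse ``key = value`` lines into a checked RunConfig.

    Blank lines and ``#`` comments are ignored; an empty file yields all
    defaults; unknown keys and out-of-range values raise ConfigError naming
    the offender.
    """
    kwargs = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in _FIELD_TYPES or key == "extra":
            raise ConfigError(f"line {lineno}: unknown key {key!r}")
        kwargs[key] = _coerce(key, val)
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    return validate_config(Path(path).read_text())
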