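"""Simulation configuration: defaults, validation, YAML/JSON loading, presets.

The defaults are the model's standard conditions: 10-gene networks at 0.75
connectance, sigmoid gain 1, fitness width sigma = 0.05, per-genome mutation
rate mu = 0.1, populations of 250 drawn from pools of 1000 viable offspring,
36000 generations, noise autocorrelation exponent gamma = 1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError

REGIMES = ("stabilizing", "directional", "red", "white")
REPRODUCTION_MODES = ("sexual", "asexual")
PERIODS = (10, 30, 50, 70)


@dataclass
class SimConfig:
    """Full parameter set for one simulation run."""

    N: int = 10
    c: float = 0.75
    a: float = 1.0  # sigmoid gain
    sigma: float = 0.05  # fitness-function width
    mu: float = 0.1  # per-genome mutation rate
    pop_size: int = 250
    pool_size: int = 1000
    generations: int = 36_000
    regime: str = "stabilizing"
    period: Optional[int] = None  # dominant period n, required for noise regimes
    gamma: float = 1.0
    reproduction: str = "sexual"
    directional_target: int = 1  # which of the 5 displaced targets (1..5)
    assay_every: int = 2000
    fine_cadence: bool = False  # extra metrics every 50 generations up to 500
    assay_sample: int = 100
    dev_steps: int = 100
    stability_threshold: float = 1e-4
    normalize_noise: bool = True
    attempt_cap_factor: int = 100  # meltdown after cap_factor * pool_size attempts
    founder_max_tries: int = 10_000
    # heavyweight per-network assays along the run (off by default; the assay
    # module is the first-class interface for these measurements)
    assay_mutation: bool = False
    assay_evolvability: bool = False

    def __post_init__(self):
        self.validate()

    @property
    def n_loci(self) -> int:
        return int(round(self.c * self.N * self.N))

    @property
    def per_locus_rate(self) -> float:
        """Per-element mutation probability mu / (c * N^2)."""
        return self.mu / self.n_loci

    def validate(self) -> None:
        if self.N < 2:
            raise ConfigError(f"N must be >= 2, got {self.N}")
        if not (0.0 < self.c <= 1.0):
            raise ConfigError(f"c must lie in (0, 1], got {self.c}")
        if self.a <= 0:
            raise ConfigError(f"a must be positive, got {self.a}")
        if self.sigma <= 0:
            raise ConfigError(f"sigma must be positive, got {self.sigma}")
        if self.mu < 0:
            raise ConfigError(f"mu must be >= 0, got {self.mu}")
        if self.pop_size < 1 or self.pool_size < self.pop_size:
            raise ConfigError(
                f"need pool_size >= pop_size >= 1, got {self.pool_size}/{self.pop_size}"
            )
        if self.generations < 0:
            raise ConfigError("generations must be >= 0")
        if self.regime not in REGIMES:
            raise ConfigError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if self.regime in ("red", "white", "directional") and self.period is None:
            raise ConfigError(f"regime {self.regime!r} requires a period")
        if self.period is not None and self.period < 2:
            raise ConfigError(f"period must be >= 2, got {self.period}")
        if self.gamma < 0:
            raise ConfigError("gamma must be >= 0")
        if self.reproduction not in REPRODUCTION_MODES:
            raise ConfigError(
                f"reproduction must be one of {REPRODUCTION_MODES}, "
                f"got {self.reproduction!r}"
            )
        if not (1 <= self.directional_target <= 5):
            raise ConfigError("directional_target must be in 1..5")
        if self.assay_every < 1 or self.assay_sample < 1:
            raise ConfigError("assay cadence and sample size must be >= 1")
        if self.dev_steps < 10:
            raise ConfigError("dev_steps must be >= 10")
        if self.stability_threshold < 0:
            raise ConfigError("stability_threshold must be >= 0")
        if self.attempt_cap_factor < 1:
            raise ConfigError("attempt_cap_factor must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


_FIELD_NAMES = {f.name for f in dataclasses.fields(SimConfig)}


def config_from_dict(doc: dict) -> SimConfig:
    unknown = set(doc) - _FIELD_NAMES
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    try:
        return SimConfig(**doc)
    except TypeError as exc:  # wrong value types
        raise ConfigError(str(exc)) from exc


def load_config(path) -> SimConfig:
    """Load a YAML (or JSON) configuration file; omitted keys take defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path} must contain a mapping of configuration keys")
    return config_from_dict(doc)


def presets() -> dict[str, SimConfig]:
    """The standard experiment grid as named configurations.

    Noise regimes at every dominant period crossed with reproduction mode,
    plus stabilizing and directional (period-50 targets) controls.
    """
    grid: dict[str, SimConfig] = {}
    for repro in REPRODUCTION_MODES:
        grid[f"stabilizing-{repro}"] = SimConfig(regime="stabilizing", reproduction=repro)
        grid[f"directional-n50-{repro}"] = SimConfig(
            regime="directional", period=50, reproduction=repro
        )
        for color in ("red", "white"):
            for n in PERIODS:
                grid[f"{color}-n{n}-{repro}"] = SimConfig(
                    regime=color, period=n, reproduction=repro
                )
    return grid
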