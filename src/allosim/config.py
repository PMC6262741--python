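"""Simulation and experiment configuration objects plus YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .allometry import AllometryConstants
from .landscape import LandscapeConfig

__all__ = ["ObserverConfig", "SimulationConfig", "ExperimentDesign", "load_config", "save_config"]


@dataclass(frozen=True)
class ObserverConfig:
    """Sampling cadences of the measurement protocol.

    The biomass panel and occupancy are sampled every ``panel_every`` days
    over the final ``panel_window`` days (11 samples at the defaults);
    genotype snapshots of at most ``snapshot_max`` individuals are taken
    every ``snapshot_every`` days; a cohort of ``cohort_n`` eggs laid in the
    final ``cohort_window`` days is followed for life.
    """

    timeseries_every: int = 10
    snapshot_every: int = 500
    snapshot_max: int = 50_000
    panel_patches: int = 100
    panel_every: int = 10
    panel_window: int = 100
    cohort_window: int = 600
    cohort_n: int = 1_000


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that determines one run: landscape, mode, rates, seed."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    allometry: AllometryConstants = field(default_factory=AllometryConstants)
    observers: ObserverConfig = field(default_factory=ObserverConfig)
    mode: str = "coupled"  # "coupled" | "decoupled"
    q: float = 0.1  # immigration probability per day
    n_init: int = 1_000  # founding adults
    mutation_rate: float = 0.001
    n_eggs: int = 15
    t_max: int = 5_000  # run length, days
    seed: int = 0
    audit: bool = False  # record the daily energy ledger

    def __post_init__(self) -> None:
        if self.mode not in ("coupled", "decoupled"):
            raise ValueError("mode must be 'coupled' or 'decoupled'")
        if self.q < 0:
            raise ValueError("immigration rate must be non-negative")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.n_init < 0 or self.n_eggs < 1:
            raise ValueError("invalid population sizes")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be a probability")


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial design over mode x isolation x resource growth x replicate."""

    nnd_levels: tuple[int, ...] = tuple(range(11))
    growth_levels: tuple[float, ...] = (0.1, 0.5, 0.9)
    modes: tuple[str, ...] = ("coupled", "decoupled")
    replicates: int = 10
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1 or not self.nnd_levels or not self.growth_levels:
            raise ValueError("empty design")


def _to_dict(cfg: SimulationConfig) -> dict:
    return asdict(cfg)


def save_config(cfg: SimulationConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))


def load_config(path_or_mapping) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML file or nested mapping."""
    if isinstance(path_or_mapping, (str, Path)):
        data = yaml.safe_load(Path(path_or_mapping).read_text()) or {}
    else:
        data = dict(path_or_mapping)
    land = LandscapeConfig(**data.pop("landscape", {}))
    allo = AllometryConstants(**data.pop("allometry", {}))
    obs = ObserverConfig(**data.pop("observers", {}))
    return SimulationConfig(landscape=land, allometry=allo, observers=obs, **data)
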