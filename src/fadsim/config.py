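"""Run configuration: validated parameter sets loadable from YAML or JSON."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional

import yaml

from .experiments import SteadyStateConfig
from .genome import GeneticParams, Strategy
from .lifecycle import DispersalParams

__all__ = ["ConfigError", "RunConfig", "load_config", "write_config"]


class ConfigError(ValueError):
    """A configuration document failed validation; the message names the key."""


def _check(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"invalid value for '{key}': {msg}")


@dataclass
class RunConfig:
    """Full configuration of a simulation run.

    Defaults are the full-scale study conditions: N = 5,000 individuals in
    demes of capacity 20, L = 10,000 fitness loci, U = 0.5 mutations and
    R = 20 crossovers per genome per generation, s = 0.1, and a
    30,000-generation invasion cap.
    """

    experiment: str = "steady-state"  # steady-state | invade | sweep
    # population
    n_total: int = 5000
    capacity: int = 20
    # genetics
    L: int = 10_000
    s: float = 0.1
    h: float = 0.2
    U: float = 0.5
    R: float = 20.0
    # dispersal
    alpha_U: float = 0.1
    alpha_F: float = 0.1
    c: float = 0.0
    fad_scope: str = "global"
    # experiment selection
    strategy: str = "UNI"  # steady-state / resident strategy
    invader_strategy: str = "FAD"
    invader_alpha: Optional[float] = None
    f0: float = 0.01
    g_max: int = 30_000
    replicates: int = 1
    # steady-state criterion
    ss_min_gens: int = 2000
    ss_max_gens: int = 20_000
    ss_window: int = 500
    ss_check_every: int = 100
    ss_level: float = 0.05
    # sweep grids (None = the standard study grid)
    grid_alphas: Optional[list] = None
    grid_costs: Optional[list] = None
    grid_hs: Optional[list] = None
    # reproducibility / output
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        _check(
            self.experiment in ("steady-state", "invade", "sweep"),
            "experiment",
            "must be one of steady-state, invade, sweep",
        )
        _check(self.n_total >= 2, "n_total", "must be >= 2")
        _check(self.capacity >= 1, "capacity", "must be >= 1")
        _check(self.L >= 1, "L", "must be >= 1")
        _check(0.0 < self.s < 1.0, "s", "must lie in (0, 1)")
        _check(0.0 <= self.h <= 1.0, "h", "must lie in [0, 1]")
        _check(self.U >= 0.0, "U", "must be >= 0")
        _check(self.R >= 0.0, "R", "must be >= 0")
        for key in ("alpha_U", "alpha_F", "c"):
            _check(0.0 <= getattr(self, key) <= 1.0, key, "must lie in [0, 1]")
        if self.invader_alpha is not None:
            _check(0.0 <= self.invader_alpha <= 1.0, "invader_alpha", "must lie in [0, 1]")
        _check(self.fad_scope in ("global", "deme"), "fad_scope", "must be global or deme")
        for key in ("strategy", "invader_strategy"):
            _check(getattr(self, key) in ("UNI", "FAD"), key, "must be UNI or FAD")
        _check(0.0 < self.f0 < 1.0, "f0", "must lie in (0, 1)")
        _check(self.g_max >= 1, "g_max", "must be >= 1")
        _check(self.replicates >= 1, "replicates", "must be >= 1")
        _check(self.ss_window >= 10, "ss_window", "must be >= 10")
        _check(self.ss_min_gens >= self.ss_window, "ss_min_gens", "must cover one window")
        _check(self.ss_max_gens >= self.ss_min_gens, "ss_max_gens", "must be >= ss_min_gens")
        _check(0.0 < self.ss_level < 1.0, "ss_level", "must lie in (0, 1)")
        _check(self.ss_check_every >= 1, "ss_check_every", "must be >= 1")
        for key in ("grid_alphas", "grid_costs", "grid_hs"):
            grid = getattr(self, key)
            if grid is not None:
                _check(
                    isinstance(grid, list) and len(grid) > 0,
                    key,
                    "must be a non-empty list",
                )
                lo, hi = (0.0, 1.0)
                for v in grid:
                    _check(
                        isinstance(v, (int, float)) and lo <= v <= hi,
                        key,
                        f"entry {v!r} outside [{lo}, {hi}]",
                    )
        _check(isinstance(self.seed, int) and self.seed >= 0, "seed", "must be a non-negative integer")

    # -- typed views -------------------------------------------------------
    def genetic_params(self) -> GeneticParams:
        return GeneticParams(L=self.L, s=self.s, h=self.h, U=self.U, R=self.R)

    def dispersal_params(self) -> DispersalParams:
        return DispersalParams(
            alpha_U=self.alpha_U, alpha_F=self.alpha_F, c=self.c, fad_scope=self.fad_scope
        )

    def steady_state_config(self) -> SteadyStateConfig:
        return SteadyStateConfig(
            min_gens=self.ss_min_gens,
            max_gens=self.ss_max_gens,
            window=self.ss_window,
            check_every=self.ss_check_every,
            level=self.ss_level,
        )

    def resident_strategy(self) -> Strategy:
        return Strategy[self.strategy]

    def invading_strategy(self) -> Strategy:
        return Strategy[self.invader_strategy]

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) configuration document.

    Omitted keys take the full-scale defaults; unknown keys and out-of-range
    values are rejected with the offending key named.
    """
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse configuration file {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("configuration document must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown configuration key '{unknown[0]}'")
    return RunConfig(**data)


def write_config(cfg: RunConfig, path) -> None:
    """Serialize a configuration so that ``load_config`` round-trips it."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
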