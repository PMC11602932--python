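"""Scenario and run configuration files.

Two YAML/JSON layouts are understood.  A *scenario* file is a flat
mapping of :class:`~offtreat.simulate.ScenarioConfig` fields (plus the
optional generative constants); a *grid* file carries a ``grid:``
mapping whose list-valued factors are crossed into the full factorial of
scenarios, with any remaining top-level keys shared by every cell.
Unknown keys are rejected by name rather than ignored.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .simulate import ScenarioConfig, SimulationParameters

__all__ = ["RunConfig", "parse_config", "load_scenarios", "default_grid_path"]

_SCENARIO_KEYS = {
    "mechanism", "disc_rate_control", "disc_rate_active", "withdrawal_rate",
    "withdrawal_balance", "off_trajectory", "disc_time_split", "seed",
    "n_per_arm", "mean_control_on", "effect_on", "covariance", "J",
}
_GRID_FACTORS = {
    "mechanism", "disc_rates", "withdrawal_rate", "withdrawal_balance",
    "off_trajectory",
}
_RUN_KEYS = {"master_seed", "n_sims", "m", "alpha", "out_dir", "models"}


@dataclass
class RunConfig:
    """Harness-level settings shared by every scenario of a run."""

    master_seed: int = 0
    n_sims: int = 1000
    m: int = 25
    alpha: float = 0.05
    out_dir: str = "."
    models: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_sims < 1 or self.m < 1:
            raise ValueError("n_sims and m must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def default_grid_path() -> Path:
    """Path of the packaged 96-scenario factorial grid."""
    return Path(__file__).parent / "grids" / "full_grid.yaml"


def _build_params(raw: dict) -> SimulationParameters:
    kwargs = {}
    for key in ("n_per_arm", "J"):
        if key in raw:
            kwargs[key] = int(raw[key])
    for key in ("mean_control_on", "effect_on"):
        if key in raw:
            kwargs[key] = tuple(float(v) for v in raw[key])
    if "off_trajectory" in raw:
        kwargs["off_trajectory"] = raw["off_trajectory"]
    if raw.get("covariance") is not None:
        kwargs["covariance"] = np.asarray(raw["covariance"], dtype=float)
    return SimulationParameters(**kwargs)


def _build_scenario(raw: dict) -> ScenarioConfig:
    unknown = set(raw) - _SCENARIO_KEYS
    if unknown:
        raise ValueError(f"unknown scenario key(s): {sorted(unknown)}")
    missing = {
        "mechanism", "disc_rate_control", "disc_rate_active",
        "withdrawal_rate", "withdrawal_balance",
    } - set(raw)
    if missing:
        raise ValueError(f"scenario is missing required key(s): {sorted(missing)}")
    params = _build_params(raw)
    kwargs = dict(
        mechanism=raw["mechanism"],
        disc_rate_control=float(raw["disc_rate_control"]),
        disc_rate_active=float(raw["disc_rate_active"]),
        withdrawal_rate=float(raw["withdrawal_rate"]),
        withdrawal_balance=raw["withdrawal_balance"],
        sim_params=params,
        seed=int(raw.get("seed", 0)),
    )
    if "disc_time_split" in raw:
        kwargs["disc_time_split"] = tuple(float(v) for v in raw["disc_time_split"])
    return ScenarioConfig(**kwargs)


def _expand_grid(doc: dict) -> list:
    grid = doc["grid"]
    unknown = set(grid) - _GRID_FACTORS
    if unknown:
        raise ValueError(f"unknown grid factor(s): {sorted(unknown)}")
    shared = {k: v for k, v in doc.items() if k not in {"grid"} | _RUN_KEYS}
    unknown = set(shared) - _SCENARIO_KEYS
    if unknown:
        raise ValueError(f"unknown key(s): {sorted(unknown)}")
    factors = {
        "mechanism": grid.get("mechanism", ["DAR"]),
        "disc_rates": grid.get("disc_rates", [[0.1, 0.1]]),
        "withdrawal_rate": grid.get("withdrawal_rate", [0.5]),
        "withdrawal_balance": grid.get("withdrawal_balance", ["balanced"]),
        "off_trajectory": grid.get("off_trajectory", ["return_to_baseline"]),
    }
    for name, values in factors.items():
        if not isinstance(values, (list, tuple)) or not values:
            raise ValueError(f"grid factor {name!r} must be a non-empty list")
    scenarios = []
    for mech, rates, wrate, bal, traj in itertools.product(
        factors["mechanism"], factors["disc_rates"], factors["withdrawal_rate"],
        factors["withdrawal_balance"], factors["off_trajectory"],
    ):
        cell = dict(shared)
        cell.update(
            mechanism=mech, disc_rate_control=rates[0], disc_rate_active=rates[1],
            withdrawal_rate=wrate, withdrawal_balance=bal, off_trajectory=traj,
        )
        scenarios.append(_build_scenario(cell))
    return scenarios


def parse_config(path) -> tuple[RunConfig, list]:
    """Parse a scenario or grid file into (RunConfig, scenario list)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or not doc:
        raise ValueError(f"{path}: configuration must be a non-empty mapping")
    run_kwargs = {k: doc[k] for k in _RUN_KEYS if k in doc}
    run = RunConfig(**run_kwargs)
    if "grid" in doc:
        scenarios = _expand_grid(doc)
    else:
        scenario_doc = {k: v for k, v in doc.items() if k not in _RUN_KEYS}
        scenarios = [_build_scenario(scenario_doc)]
    if not scenarios:
        raise ValueError(f"{path}: configuration defines no scenarios")
    return run, scenarios


def load_scenarios(path) -> list:
    return parse_config(path)[1]
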