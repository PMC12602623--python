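"""Scenario-grid configuration: YAML in, Scenario list out.

The default grid is the full factorial design: 4 models x 5 sample sizes x
3 error distributions x 4 heteroskedasticity levels, minus the unattainable
(n = 25, severe) cells — 224 scenarios.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .synthetic_data import DISTRIBUTIONS, MODEL_BETAS, Scenario

__all__ = ["default_grid_config", "load_config", "scenarios_from_config"]

_DEFAULT = {
    "models": [1, 2, 3, 4],
    "ns": [25, 50, 100, 200, 500],
    "distributions": ["normal", "moderate", "severe"],
    "g_levels": [0, 0.5, 1, 2],
    "n_reps": 10_000,
    "B": 1_000,
    "seed": 12345,
    "constrained_sampling": True,
}

_KEYS = set(_DEFAULT)


def default_grid_config() -> dict:
    """A fresh copy of the full-design configuration."""
    return {k: (list(v) if isinstance(v, list) else v) for k, v in _DEFAULT.items()}


def load_config(path: str | Path) -> dict:
    """Read a YAML grid config, filling unspecified keys with defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = default_grid_config()
    cfg.update(raw)
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    for m in cfg["models"]:
        if m not in MODEL_BETAS:
            raise ValueError(f"models: unknown model id {m!r}")
    for d in cfg["distributions"]:
        if d not in DISTRIBUTIONS:
            raise ValueError(
                f"distributions: {d!r} not one of {sorted(DISTRIBUTIONS)}"
            )
    for key in ("n_reps", "B", "seed"):
        if not isinstance(cfg[key], int) or cfg[key] < 0:
            raise ValueError(f"{key}: expected a non-negative integer")


def scenarios_from_config(cfg: dict) -> list[Scenario]:
    """Enumerate the grid, silently dropping the excluded (25, severe) cells."""
    scenarios = []
    for model in cfg["models"]:
        for n in cfg["ns"]:
            for dist in cfg["distributions"]:
                if n == 25 and dist == "severe":
                    continue
                for g in cfg["g_levels"]:
                    scenarios.append(
                        Scenario(
                            model_id=model,
                            n=n,
                            dist=DISTRIBUTIONS[dist],
                            g=float(g),
                            n_reps=cfg["n_reps"],
                            B=cfg["B"],
                            seed=cfg["seed"],
                            constrained_sampling=cfg["constrained_sampling"],
                        )
                    )
    return scenarios
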