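"""Flat key/value experiment configuration (YAML) with strict key checking."""

from __future__ import annotations

from pathlib import Path

import yaml

from .experiment import ExperimentConfig

__all__ = ["KNOWN_KEYS", "load_config", "parse_config", "write_config", "config_to_dict"]

KNOWN_KEYS = frozenset(
    {
        "scenarios",
        "sample_sizes",
        "n_reps",
        "criteria",
        "analysis_types",
        "master_seed",
        "experimental_corrected",
        "rho_node",
        "rho_hc",
    }
)

_LIST_KEYS = {"scenarios", "sample_sizes", "criteria", "analysis_types", "rho_node", "rho_hc"}


def _as_list(value) -> list:
    """Accept YAML lists or comma-separated scalars for list-valued keys."""
    if isinstance(value, str):
        return [item.strip() for item in value.split(",") if item.strip()]
    if isinstance(value, (list, tuple)):
        return list(value)
    return [value]


def parse_config(mapping: dict) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a flat mapping.

    Unspecified keys take the full-study defaults (both scenarios, n in
    {30, 100, 300}, 1000 replicates, all three analysis types and criteria).
    Unknown keys are an error -- no silent typo tolerance.
    """
    if mapping is None:
        mapping = {}
    if not isinstance(mapping, dict):
        raise ValueError("config must be a flat key/value mapping")
    unknown = set(mapping) - KNOWN_KEYS
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; known keys: {sorted(KNOWN_KEYS)}"
        )
    kwargs: dict = {}
    for key, value in mapping.items():
        if key in _LIST_KEYS:
            items = _as_list(value)
            if key == "sample_sizes":
                kwargs[key] = tuple(int(v) for v in items)
            elif key in ("rho_node", "rho_hc"):
                kwargs[key] = tuple(float(v) for v in items)
            else:
                kwargs[key] = tuple(str(v) for v in items)
        elif key in ("n_reps", "master_seed"):
            kwargs[key] = int(value)
        elif key == "experimental_corrected":
            kwargs[key] = bool(value)
    return ExperimentConfig(**kwargs)


def load_config(path: str | Path) -> ExperimentConfig:
    """Load an experiment configuration from a flat YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        mapping = yaml.safe_load(fh)
    return parse_config(mapping)


def config_to_dict(config: ExperimentConfig) -> dict:
    """Flat dict representation; round-trips through :func:`parse_config`."""
    out = {
        "scenarios": list(config.scenarios),
        "sample_sizes": list(config.sample_sizes),
        "n_reps": config.n_reps,
        "criteria": list(config.criteria),
        "analysis_types": list(config.analysis_types),
        "master_seed": config.master_seed,
        "experimental_corrected": config.experimental_corrected,
    }
    if config.rho_node is not None:
        out["rho_node"] = list(config.rho_node)
    if config.rho_hc is not None:
        out["rho_hc"] = list(config.rho_hc)
    return out


def write_config(config: ExperimentConfig, path: str | Path) -> None:
    """Write a configuration as flat YAML (inverse of :func:`load_config`)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
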