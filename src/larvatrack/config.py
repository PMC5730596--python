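"""Run configuration: defaults ← YAML file ← explicit overrides.

The configuration tree mirrors the pipeline stages (``bg``, ``seg``,
``track``, ``eval``).  Every key is validated against the schema (known
name, coercible type) before any computation runs.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .background import BackgroundParams
from .segmentation import SegmentationParams
from .tracking import TrackerConfig

__all__ = ["DEFAULTS", "load_config", "merge_config", "validate_config", "build_params"]

DEFAULTS: dict = {
    "bg": {
        "alpha": 0.001,
        "c_f": 0.1,
        "c_T": 0.05,
        "max_components": 4,
        "lambda": 3.0,
        "var_init": 225.0,
        "var_floor": 4.0,
        "warmup_frames": 500,
    },
    "seg": {
        "size_fraction": 0.20,
        "median_window": 3,
        "erosion_size": 3,
        "connectivity": 8,
        "erosion_first": False,
    },
    "track": {
        "max_displacement_px": 10.0,
        "bridge_ratio": 1.2,
        "use_gt_gate": True,
        "gate_is_squared": True,
        "gate_slack_px": 3.0,
    },
    "eval": {
        "match_radius": None,  # None → the tracking gate in pixels
        "per_video_counts": False,
    },
}

_TYPES = {bool: bool, int: (int,), float: (int, float), str: (str,)}


def validate_config(config: dict) -> None:
    """Reject unknown keys and values of the wrong type."""
    if not isinstance(config, dict):
        raise ValueError("configuration must be a mapping")
    for section, values in config.items():
        if section not in DEFAULTS:
            raise ValueError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        for key, value in values.items():
            if key not in DEFAULTS[section]:
                raise ValueError(f"unknown config key {section}.{key}")
            default = DEFAULTS[section][key]
            if default is None or value is None:
                continue
            if isinstance(default, bool):
                if not isinstance(value, bool):
                    raise ValueError(f"config key {section}.{key} must be a boolean")
            elif isinstance(default, (int, float)):
                if isinstance(value, bool) or not isinstance(value, (int, float)):
                    raise ValueError(f"config key {section}.{key} must be numeric")
            elif not isinstance(value, type(default)):
                raise ValueError(
                    f"config key {section}.{key} must be {type(default).__name__}"
                )


def merge_config(*layers: dict | None) -> dict:
    """Merge configuration layers left-to-right over the defaults."""
    merged = copy.deepcopy(DEFAULTS)
    for layer in layers:
        if not layer:
            continue
        validate_config(layer)
        for section, values in layer.items():
            merged[section].update(values)
    return merged


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML config file (if given) and merge it with the defaults."""
    layers = []
    if path is not None:
        with open(path) as fh:
            layers.append(yaml.safe_load(fh) or {})
    layers.append(overrides)
    return merge_config(*layers)


def build_params(config: dict):
    """Materialise parameter objects from a merged configuration tree."""
    bg = config["bg"]
    seg = config["seg"]
    trk = config["track"]
    return (
        BackgroundParams(
            alpha=bg["alpha"],
            c_f=bg["c_f"],
            c_T=bg["c_T"],
            max_components=int(bg["max_components"]),
            lambda_match=bg["lambda"],
            var_init=bg["var_init"],
            var_floor=bg["var_floor"],
            warmup_frames=int(bg["warmup_frames"]),
        ),
        SegmentationParams(
            size_fraction=seg["size_fraction"],
            median_window=int(seg["median_window"]),
            erosion_size=int(seg["erosion_size"]),
            connectivity=int(seg["connectivity"]),
            erosion_first=seg["erosion_first"],
        ),
        TrackerConfig(
            max_displacement=trk["max_displacement_px"],
            bridge_ratio=trk["bridge_ratio"],
            gate_is_squared=trk["gate_is_squared"],
            gate_slack_px=trk["gate_slack_px"],
        ),
    )
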