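"""Pipeline configuration: one YAML document covering every stage."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .patches import AugmentationConfig, PatchSpec
from .synthetic import CohortConfig
from .taxonomy import build_default_taxonomy
from .training import TrainingConfig

__all__ = ["default_config", "dump_default_config", "load_config"]


def _clean(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, tuple):
            v = list(v)
        elif isinstance(v, np.ndarray):
            v = v.tolist()
        out[k] = v
    return out


def default_config() -> dict:
    """All tunable defaults, grouped by pipeline stage."""
    return {
        "taxonomy": build_default_taxonomy().to_dict(),
        "cohort": _clean(asdict(CohortConfig())),
        "patches": {
            "u-net": _clean(asdict(PatchSpec(shape=(412, 412)))),
            "dense-net": _clean(asdict(PatchSpec(shape=(128, 128)))),
        },
        "augmentation": _clean(asdict(AugmentationConfig())),
        "training": {
            "u-net": _clean(asdict(TrainingConfig(batch_size=4))),
            "dense-net": _clean(asdict(TrainingConfig(batch_size=16))),
        },
    }


def dump_default_config() -> str:
    return yaml.safe_dump(default_config(), sort_keys=False)


def load_config(path: str | Path) -> dict:
    merged = default_config()
    user = yaml.safe_load(Path(path).read_text()) or {}
    for section, values in user.items():
        if isinstance(values, dict) and isinstance(merged.get(section), dict):
            merged[section].update(values)
        else:
            merged[section] = values
    return merged
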