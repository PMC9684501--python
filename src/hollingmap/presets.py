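"""Named parameter presets for the worked examples."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Optional

import yaml

from .model import ModelParams

__all__ = ["Preset", "load_presets", "get_preset", "preset_names"]


@dataclass(frozen=True)
class Preset:
    name: str
    params: ModelParams
    #: nominal control-parameter value, when the preset is a control example
    c0: Optional[float] = None
    #: reference prey-gain used by the control example
    rho1: Optional[float] = None


def _read_registry() -> Dict[str, dict]:
    text = resources.files("hollingmap").joinpath("data/presets.yaml").read_text()
    return yaml.safe_load(text)


def load_presets() -> Dict[str, Preset]:
    registry = {}
    for name, fields in _read_registry().items():
        extra = {k: fields.pop(k) for k in ("c0", "rho1") if k in fields}
        registry[name] = Preset(name=name, params=ModelParams(**fields), **extra)
    return registry


def preset_names() -> list:
    return sorted(_read_registry())


def get_preset(name: str) -> Preset:
    presets = load_presets()
    if name not in presets:
        available = ", ".join(sorted(presets))
        raise KeyError(f"unknown preset {name!r}; available: {available}")
    return presets[name]
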