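"""Configuration for the facade and CLI.

Precedence (highest wins): explicit overrides (CLI flags or constructor
arguments) > ``SYNTHZOO_*`` environment variables > a TOML config file
(``SYNTHZOO_CONFIG`` or ``./synthzoo.toml``) > built-in defaults. The
built-in registry source is the bundled catalog of published models.
"""

from __future__ import annotations

import os
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from .registry import BUNDLED_ZOO

_ENV_PREFIX = "SYNTHZOO_"
_KEYS = ("registry_source", "cache_dir", "samples_dir", "default_batch_size", "log_level")


@dataclass
class FacadeConfig:
    registry_source: str = str(BUNDLED_ZOO)
    cache_dir: str = str(Path.home() / ".cache" / "synthzoo")
    samples_dir: str = "synthzoo_samples"
    default_batch_size: int = 32
    log_level: str = "INFO"


def load_config(overrides: dict[str, Any] | None = None,
                config_file: str | Path | None = None) -> FacadeConfig:
    """Layer config sources into a FacadeConfig."""
    values: dict[str, Any] = {}

    path = config_file or os.environ.get(_ENV_PREFIX + "CONFIG")
    if path is None and Path("synthzoo.toml").is_file():
        path = "synthzoo.toml"
    if path is not None and Path(path).is_file():
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        values.update({k: v for k, v in data.items() if k in _KEYS})

    for key in _KEYS:
        env = os.environ.get(_ENV_PREFIX + key.upper())
        if env is not None:
            values[key] = env

    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None and k in _KEYS})

    if "default_batch_size" in values:
        values["default_batch_size"] = int(values["default_batch_size"])
    return FacadeConfig(**values)
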