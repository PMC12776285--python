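"""Pipeline configuration: schema-validated key-value config (JSON/TOML).

A resolved copy of the configuration is written beside every CLI run's
outputs so any run is reproducible from its artifacts alone. Unknown keys
are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .analysis import HYDROPHOBIC_DEFAULT
from .docking import FilterConfig
from .errors import ConfigError
from .filters import CascadeConfig


@dataclass
class PipelineConfig:
    architecture: str = "I3"
    seed: int = 0
    output_dir: str = "."
    filter: FilterConfig = field(default_factory=FilterConfig)
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    hydrophobic_set: str = "".join(sorted(HYDROPHOBIC_DEFAULT))
    interface_contact_hi: float = 8.0


def _build(cls, data: dict, context: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key == "filter":
            kwargs[key] = _build(FilterConfig, dict(value), f"{context}.filter")
        elif key == "cascade":
            if "stage_order" in value:
                value = dict(value, stage_order=tuple(value["stage_order"]))
            if "manual_exclude" in value:
                value = dict(value, manual_exclude=frozenset(value["manual_exclude"]))
            kwargs[key] = _build(CascadeConfig, dict(value), f"{context}.cascade")
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def load_config(path) -> PipelineConfig:
    """Load a pipeline config from JSON or TOML."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        with open(path) as fh:
            data = json.load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    return _build(PipelineConfig, data, str(path))


def dump_config(config: PipelineConfig, path) -> None:
    """Write the fully resolved config as JSON beside run outputs."""

    def encode(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        if isinstance(obj, frozenset):
            return sorted(obj)
        if isinstance(obj, tuple):
            return list(obj)
        raise TypeError(f"cannot serialize {type(obj)}")

    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, default=encode)
        fh.write("\n")
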