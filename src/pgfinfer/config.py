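"""Run configuration: a serializable record of every knob of a run.

A run is reproducible from its config and seed alone; the CLI loads a
YAML config file and lets flags override individual fields.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    family: str = "telegraph"
    model_file: str = None
    method: str = "pgf"  # pgf | mom | mle
    mode: str = None  # steady | time (None: inferred from data)
    z_min: float = 0.0
    z_max: float = 1.0
    quad_order: int = 8
    init: str = "unit-log"  # unit-log | mom
    maxiter: int = 2000
    seed: int = 0
    capture_p: float = None
    outlier_value: int = None
    outlier_k: int = 0
    data_format: str = "long"
    extra: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in obj.items() if k in known}
        kwargs["extra"] = {k: v for k, v in obj.items() if k not in known}
        return cls(**kwargs)

    def merged(self, **overrides) -> "RunConfig":
        """Copy with non-None overrides applied (CLI flags win)."""
        data = asdict(self)
        for k, v in overrides.items():
            if v is not None:
                data[k] = v
        return RunConfig(**data)

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
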