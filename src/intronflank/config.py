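"""Run configuration: one declarative record of every effective parameter.

Defaults are the published hard-filter and deleterious thresholds; any value
may be overridden from a YAML file or the command line (CLI wins).  The run
log reports each threshold with its provenance (``default`` vs
``user-override``) so a run is reconstructable from its log alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .qc_filters import DeleteriousThresholds, HardFilterThresholds
from .variant_io import FieldMap


@dataclass
class RunConfig:
    W: int = 200
    hard: HardFilterThresholds = field(default_factory=HardFilterThresholds)
    deleterious: DeleteriousThresholds = field(
        default_factory=DeleteriousThresholds)
    field_map: FieldMap = field(default_factory=FieldMap)
    pass_policy: str = "any"          # any | majority | all
    score_policy: str = "present"     # present | strict
    signed_dpsi: bool = True
    missing_qc_fails: bool = False
    paired: bool = True
    alpha: float = 0.05
    seed: int = 0
    overridden: set = field(default_factory=set, repr=False)

    @classmethod
    def from_yaml(cls, path: Optional[str | Path], **overrides) -> "RunConfig":
        data: dict = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        cfg = cls()
        for src in (data, {k: v for k, v in overrides.items() if v is not None}):
            for key, value in src.items():
                if key in ("hard", "deleterious"):
                    base = getattr(cfg, key)
                    setattr(cfg, key, dataclasses.replace(base, **value))
                    cfg.overridden.update(f"{key}.{k}" for k in value)
                elif key == "field_map":
                    cfg.field_map = FieldMap.from_dict(value)
                    cfg.overridden.add("field_map")
                elif hasattr(cfg, key):
                    setattr(cfg, key, value)
                    cfg.overridden.add(key)
                else:
                    raise KeyError(f"unknown config key {key!r}")
        return cfg

    def threshold_log(self) -> list[str]:
        """One line per effective threshold with its provenance."""
        lines = []
        for group in ("hard", "deleterious"):
            obj = getattr(self, group)
            for f in dataclasses.fields(obj):
                tag = ("user-override" if f"{group}.{f.name}" in self.overridden
                       else "default")
                lines.append(f"{group}.{f.name}={getattr(obj, f.name)} [{tag}]")
        for key in ("W", "pass_policy", "score_policy", "signed_dpsi",
                    "missing_qc_fails", "alpha"):
            tag = "user-override" if key in self.overridden else "default"
            lines.append(f"{key}={getattr(self, key)} [{tag}]")
        return lines
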