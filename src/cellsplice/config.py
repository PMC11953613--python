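"""Run configuration: one flat YAML file, overridable per CLI flag.

The effective configuration is echoed into every output directory so a
run can be reproduced from its artifacts alone.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .models import SpecificityThresholds
from .psi import DEFAULT_BALANCE_ALPHA, DEFAULT_TIER_CUTOFFS


@dataclass
class RunConfig:
    """Thresholds and filter settings for one pipeline run."""

    thresholds: SpecificityThresholds = field(default_factory=SpecificityThresholds)
    tier_cutoffs: tuple[int, ...] = DEFAULT_TIER_CUTOFFS
    balance_alpha: float = DEFAULT_BALANCE_ALPHA
    min_tier: str = "LOW"
    min_samples: int = 10
    require_balance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.balance_alpha < 1:
            raise ValueError("balance_alpha must lie in (0, 1)")
        cutoffs = tuple(self.tier_cutoffs)
        if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])) or any(c <= 0 for c in cutoffs):
            raise ValueError("tier_cutoffs must be strictly increasing and positive")
        self.tier_cutoffs = cutoffs

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tier_cutoffs"] = list(self.tier_cutoffs)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        th_fields = {f.name for f in fields(SpecificityThresholds)}
        th_data = dict(data.pop("thresholds", {}))
        # flat keys belonging to the thresholds block are accepted too
        for key in list(data):
            if key in th_fields:
                th_data[key] = data.pop(key)
        known = {f.name for f in fields(cls)} - {"thresholds"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "tier_cutoffs" in data:
            data["tier_cutoffs"] = tuple(data["tier_cutoffs"])
        return cls(thresholds=SpecificityThresholds(**th_data), **data)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a key-value mapping")
    return RunConfig.from_dict(data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
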