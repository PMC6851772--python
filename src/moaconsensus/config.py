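"""Run configuration loaded from a YAML file.

Unknown keys are rejected so typos fail loudly instead of silently using a
default.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    mode: str = "default"
    binmap: str | None = None
    metal_policy: str | None = None
    strict_labels: bool = False
    seed: int = 0
    log_level: str = "INFO"
    # acute windows: {trophic_level: {endpoints: [...], min_hours, max_hours}}
    acute_windows: dict | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("default", "conservative"):
            raise ValueError(f"mode must be 'default' or 'conservative', got {self.mode!r}")


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {', '.join(unknown)}")
    return RunConfig(**raw)


def acute_config_from(run: RunConfig):
    """Build an AcuteConfig from a RunConfig (package defaults where unset)."""
    from .toxicity import AcuteConfig, AcuteWindow

    if not run.acute_windows:
        return AcuteConfig()
    base = AcuteConfig().windows.copy()
    for level, spec in run.acute_windows.items():
        base[level] = AcuteWindow(
            endpoints=frozenset(e.upper() for e in spec["endpoints"]),
            min_hours=float(spec["min_hours"]),
            max_hours=float(spec["max_hours"]),
        )
    return AcuteConfig(windows=base)
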