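"""Pipeline configuration with TOML round-tripping.

Defaults reproduce the reference analysis settings: 401 FIR taps, 1 s band
and 2 s LMP smoothing windows, a ±1000 ms lag grid at 50 ms steps, fivefold
cross-validation, nine decoder inputs and 1024 shuffles for the chance
null.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .synth import SynthConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    fir_taps: int = 401
    band_smooth_s: float = 1.0
    lmp_smooth_s: float = 2.0
    max_lag_ms: float = 1000.0
    lag_step_ms: float = 50.0
    folds: int = 5
    n_inputs: int = 9
    n_shuffles: int = 1024
    shuffle_mode: str = "circular_shift"
    trim_margin_s: float = 2.0
    pipeline_order: str = "paper"
    targets: tuple[str, ...] = ("pc1", "pc2", "pc3")
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"]["informative"] = [list(e) for e in self.synth.informative]
        d["synth"]["workspace"] = [list(ax) for ax in self.synth.workspace]
        d["targets"] = list(self.targets)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sy = dict(d.pop("synth", {}))
        if "informative" in sy:
            sy["informative"] = tuple(tuple(e) for e in sy["informative"])
        if "workspace" in sy:
            sy["workspace"] = tuple(tuple(ax) for ax in sy["workspace"])
        if "reach_duration_s" in sy:
            sy["reach_duration_s"] = tuple(sy["reach_duration_s"])
        if "rest_duration_s" in sy:
            sy["rest_duration_s"] = tuple(sy["rest_duration_s"])
        if "home_fraction" in sy:
            sy["home_fraction"] = tuple(sy["home_fraction"])
        if "targets" in d:
            d["targets"] = tuple(d["targets"])
        return cls(synth=SynthConfig(**sy), **d)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def _toml_dumps(d: dict, prefix: str = "") -> str:
    lines, tables = [], []
    for k, v in d.items():
        if isinstance(v, dict):
            tables.append((k, v))
        else:
            lines.append(f"{k} = {_toml_value(v)}")
    out = "\n".join(lines)
    for k, v in tables:
        name = f"{prefix}{k}"
        out += f"\n\n[{name}]\n" + _toml_dumps(v, prefix=name + ".")
    return out


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(_toml_dumps(config.to_dict()) + "\n")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, "rb") as fh:
        return PipelineConfig.from_dict(tomllib.load(fh))
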