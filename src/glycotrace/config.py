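"""Run configuration: one flat, validated bundle of pipeline parameters.

Defaults follow the published protocol wherever it states a value
(smoothing SD of 5 measurement points, 1% height+prominence threshold,
boundaries at +/-3 fitted SDs, the 150-350 nt glycomic region); everything
else is an exposed engineering choice.  Unknown keys in a config file are
rejected rather than ignored.
"""
from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import GlycotraceError
from .types import LIZ500, LadderDefinition


@dataclass
class RunConfig:
    glycan_tag: str = "DATA,1"
    ladder_tag: str = "DATA,105"
    region: tuple[float, float] = (150.0, 350.0)
    step: float = 0.05
    ladder_sizes: tuple[float, ...] = LIZ500.fragment_sizes
    ladder_name: str = "LIZ500"
    map_kind: str = "pchip"
    ladder_rel_threshold: float = 0.10
    smooth_sigma_points: float = 5.0
    smooth_truncation: float = 4.0
    arpls_lam: float = 1e5
    arpls_ratio: float = 1e-6
    arpls_max_iter: int = 100
    rel_threshold: float = 0.01
    boundary_sigmas: float = 3.0
    dtw_band_nt: float = 10.0
    match_rule: str = "apex-window"
    cv_tol_nt: float = 1.0
    seed: int = 0

    def ladder(self) -> LadderDefinition:
        return LadderDefinition(self.ladder_sizes, name=self.ladder_name)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["region"] = list(self.region)
        d["ladder_sizes"] = list(self.ladder_sizes)
        return d

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".toml":
            raw = tomllib.loads(text)
        else:
            raw = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise GlycotraceError(f"unknown config keys: {sorted(unknown)}")
        if "region" in raw:
            raw["region"] = tuple(raw["region"])
        if "ladder_sizes" in raw:
            raw["ladder_sizes"] = tuple(raw["ladder_sizes"])
        return cls(**raw)
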