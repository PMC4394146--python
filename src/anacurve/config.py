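"""Run configuration: every tunable of the pipelines with its default.

Defaults are the protocol constants of the method: slab tolerance 1 mm for
torso transects and 1.2 mm for lip strips, a 12 mm neighbourhood for the
local frame at prom, 51 radial / 50 vertical transects, smoothing at 6
(breast transect), 8 (lip strip), 12 (breast boundary) and 25 (lip
boundary) effective degrees of freedom, exclusion constants 0.7 and 10 mm,
derivative-change threshold 5, shape-penalty factor kappa = 100 lambda,
r = 20 semi-landmarks per breast transect and 50 per lip boundary curve.
Configs round-trip losslessly through TOML; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from pathlib import Path

from .breast import BreastConfig
from .lips import LipConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    # breast pipeline
    n_transects: int = 51
    torso_delta: float = 1.0
    neighborhood_radius: float = 12.0
    transect_df: float = 6.0
    boundary_df: float = 12.0
    proportion: float = 0.7
    tolerance: float = 10.0
    length_multiple: float = 1.5
    # lip pipeline
    n_strips: int = 50
    lip_delta: float = 1.2
    strip_df: float = 8.0
    threshold: float = 5.0
    lip_boundary_df: float = 25.0
    kappa_factor: float = 100.0
    prelim_df: float = 18.0
    # semi-landmarks
    r: int = 20
    n_boundary: int = 50
    # misc
    seed: int = 0

    def breast(self) -> BreastConfig:
        return BreastConfig(
            n_transects=self.n_transects, delta=self.torso_delta,
            neighborhood_radius=self.neighborhood_radius,
            transect_df=self.transect_df, boundary_df=self.boundary_df,
            proportion=self.proportion, tolerance=self.tolerance,
            length_multiple=self.length_multiple)

    def lips(self) -> LipConfig:
        return LipConfig(
            n_strips=self.n_strips, delta=self.lip_delta,
            strip_df=self.strip_df, threshold=self.threshold,
            boundary_df=self.lip_boundary_df, kappa_factor=self.kappa_factor,
            prelim_df=self.prelim_df)

    def to_toml(self) -> str:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool):
                lines.append(f"{f.name} = {'true' if v else 'false'}")
            elif isinstance(v, (int, float)):
                lines.append(f"{f.name} = {v!r}")
            else:
                lines.append(f'{f.name} = "{v}"')
        return "\n".join(lines) + "\n"


def load_config(path) -> RunConfig:
    import tomllib

    data = tomllib.loads(Path(path).read_text())
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(config.to_toml())
    return path
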