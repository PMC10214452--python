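"""Validated run configuration (YAML/JSON) with reference defaults.

An empty configuration reproduces the reference simulation conditions:
J = 0.55 k_BT, J_sT = 0.136 k_BT, J_dC = -0.057 k_BT, composition ratio
2/3, coverage sigma = 30%, a 320 x 372 box, t_MC = 2x10^7 cycles and 15
replicates.  Unknown keys are rejected with field-level messages.
"""

from __future__ import annotations

import json
import logging
import pathlib

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .lattice import LatticeSpec
from .params import ModelParams, Schedule
from .tiles import AnchorLayout

logger = logging.getLogger("lineactant")

__all__ = ["RunConfig", "parse_config", "ConfigError"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LatticeConfig(_Strict):
    width: int = 320
    height: int = 372


class ModelConfig(_Strict):
    j: float = 0.55
    j_st: float = 0.136
    j_dc: float = -0.057
    ratio: float = 2.0 / 3.0
    sigma: float = Field(default=0.30, ge=0.0, lt=1.0)
    seed: int = 0


class LayoutConfig(_Strict):
    design: str | None = "12x"   # None disables tiles
    nm_per_site: float = 2.0
    length_nm: float = 90.0
    width_nm: float = 20.0
    delta_nm: float = 16.0


class ScheduleConfig(_Strict):
    t_mc: int = 20_000_000
    stride: int = 100_000
    deactivate_at: int | None = None
    n_replicates: int = 15
    record_snapshots: bool = False


class RunConfig(_Strict):
    """Full configuration for a simulation run."""

    lattice: LatticeConfig = Field(default_factory=LatticeConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    layout: LayoutConfig = Field(default_factory=LayoutConfig)
    schedule: ScheduleConfig = Field(default_factory=ScheduleConfig)
    out_dir: str = "lineactant_out"
    verbosity: str = "info"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.lattice.height % 2 != 0:
            raise ValueError("lattice.height must be even")
        if self.schedule.deactivate_at is not None and not (
            0 <= self.schedule.deactivate_at <= self.schedule.t_mc
        ):
            raise ValueError("schedule.deactivate_at must lie within [0, t_mc]")
        return self

    # -- conversions to domain objects -------------------------------------

    def lattice_spec(self) -> LatticeSpec:
        return LatticeSpec(self.lattice.width, self.lattice.height)

    def model_params(self) -> ModelParams:
        m = self.model
        return ModelParams(j=m.j, j_st=m.j_st, j_dc=m.j_dc, ratio=m.ratio,
                           sigma=m.sigma, seed=m.seed)

    def anchor_layout(self) -> AnchorLayout | None:
        lc = self.layout
        if lc.design is None or str(lc.design).lower() in ("none", "null", ""):
            return None
        return AnchorLayout.design(
            lc.design, nm_per_site=lc.nm_per_site, length_nm=lc.length_nm,
            width_nm=lc.width_nm, delta_nm=lc.delta_nm,
        )

    def mc_schedule(self) -> Schedule:
        s = self.schedule
        return Schedule(t_mc=s.t_mc, stride=s.stride,
                        deactivate_at=s.deactivate_at,
                        n_replicates=s.n_replicates,
                        record_snapshots=s.record_snapshots)


def _deep_update(base: dict, upd: dict, path: str = "") -> dict:
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v, f"{path}{k}.")
        else:
            if k in base and base[k] != v:
                logger.warning("config override: %s%s = %r (file had %r)",
                               path, k, v, base[k])
            base[k] = v
    return base


def parse_config(
    path: str | pathlib.Path | None = None,
    overrides: dict | None = None,
) -> RunConfig:
    """Load and validate a YAML/JSON configuration.

    ``overrides`` (typically from command-line flags) win over file values;
    each conflicting key is logged.  An empty input yields the reference
    defaults.
    """
    data: dict = {}
    if path is not None:
        path = pathlib.Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text) or {}
        else:
            data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    if overrides:
        _deep_update(data, overrides)
    try:
        return RunConfig.model_validate(data)
    except ValidationError as err:
        msgs = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        )
        raise ConfigError(f"invalid configuration: {msgs}") from err
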