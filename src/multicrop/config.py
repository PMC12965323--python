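"""Run configuration: every tunable parameter of the pipeline with its default.

Defaults encode the method's reference parameterization: a month counts
toward multiple-cropping suitability when monthly grass GPP exceeds
100 g C m^-2, a cell is suitable when at least nine months qualify,
off-season yields and water use are dampened by 25%, and water may be
conveyed over at most 100 km. Irrigation-system efficiencies follow the
standard surface/sprinkler/drip parameterizations used in global
irrigation accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

from .errors import ConfigError

#: Canonical orderings used for all array axes.
SYSTEMS = ("surface", "sprinkler", "drip")
REGIMES = ("rainfed", "irrigated")

#: 1 mm of water depth on 1 ha is 10 m^3 = 1e-8 km^3.
MM_HA_TO_KM3 = 1e-8


@dataclass(frozen=True)
class EfficiencyTable:
    """Per-system irrigation efficiencies.

    field_efficiency
        Fraction of water reaching the field that is usefully applied.
    conveyance_efficiency
        Fraction of withdrawn water that survives transport to the field.
    consumptive_loss_share
        Fraction of conveyance losses that evaporates (is consumed) rather
        than returning to the river.
    """

    field_efficiency: dict[str, float] = field(
        default_factory=lambda: {"surface": 0.60, "sprinkler": 0.75, "drip": 0.90}
    )
    conveyance_efficiency: dict[str, float] = field(
        default_factory=lambda: {"surface": 0.70, "sprinkler": 0.95, "drip": 0.95}
    )
    consumptive_loss_share: float = 0.5

    def validate(self) -> None:
        for name, table in (
            ("field_efficiency", self.field_efficiency),
            ("conveyance_efficiency", self.conveyance_efficiency),
        ):
            if set(table) != set(SYSTEMS):
                raise ConfigError(
                    f"{name}: expected exactly the systems {SYSTEMS}, got {sorted(table)}"
                )
            for system, value in table.items():
                if not 0.0 < value <= 1.0:
                    raise ConfigError(
                        f"{name}[{system}]={value}: efficiency must be in (0, 1]"
                    )
        if not 0.0 <= self.consumptive_loss_share <= 1.0:
            raise ConfigError(
                f"consumptive_loss_share={self.consumptive_loss_share}: must be in [0, 1]"
            )


@dataclass(frozen=True)
class RunConfig:
    """Typed, range-checked pipeline parameters (units in field names/docs)."""

    gpp_threshold: float = 100.0  # g C m^-2 month^-1
    min_growing_months: int = 9
    consecutive_months: bool = False
    offseason_dampening: float = 0.25  # fraction of off-season potential removed
    carbon_fraction: float = 0.45  # g C per g DM
    radius_km: float = 100.0
    calibration_cap: float | None = None  # optional cap on calibration factors
    efficiency: EfficiencyTable = field(default_factory=EfficiencyTable)
    seed: int = 0
    n_cells: int = 200
    n_basins: int = 8
    n_crops: int = 4

    def validate(self) -> None:
        if self.gpp_threshold < 0:
            raise ConfigError(f"gpp_threshold={self.gpp_threshold}: must be >= 0")
        if not 1 <= self.min_growing_months <= 12:
            raise ConfigError(
                f"min_growing_months={self.min_growing_months}: must be in 1..12"
            )
        if not 0.0 <= self.offseason_dampening <= 1.0:
            raise ConfigError(
                f"offseason_dampening={self.offseason_dampening}: must be in [0, 1]"
            )
        if not 0.0 < self.carbon_fraction <= 1.0:
            raise ConfigError(
                f"carbon_fraction={self.carbon_fraction}: must be in (0, 1]"
            )
        if self.radius_km <= 0:
            raise ConfigError(f"radius_km={self.radius_km}: must be > 0")
        if self.calibration_cap is not None and self.calibration_cap <= 0:
            raise ConfigError(
                f"calibration_cap={self.calibration_cap}: must be > 0 or null"
            )
        if self.n_cells < self.n_basins or self.n_basins < 1:
            raise ConfigError(
                f"n_cells={self.n_cells}, n_basins={self.n_basins}: "
                "need n_cells >= n_basins >= 1"
            )
        if self.n_crops < 1:
            raise ConfigError(f"n_crops={self.n_crops}: must be >= 1")
        self.efficiency.validate()


_SCALAR_KEYS = {
    f.name for f in RunConfig.__dataclass_fields__.values() if f.name != "efficiency"
}
_EFF_KEYS = set(EfficiencyTable.__dataclass_fields__)


def validate_config(raw: Mapping | None) -> RunConfig:
    """Build a :class:`RunConfig` from a plain mapping, rejecting unknown keys.

    An empty/None mapping yields all defaults.
    """
    raw = dict(raw or {})
    eff_raw = raw.pop("efficiency", {})
    unknown = set(raw) - _SCALAR_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if not isinstance(eff_raw, Mapping):
        raise ConfigError("efficiency: must be a mapping")
    unknown = set(eff_raw) - _EFF_KEYS
    if unknown:
        raise ConfigError(f"unknown efficiency keys: {sorted(unknown)}")
    try:
        eff = EfficiencyTable(**{k: v for k, v in eff_raw.items()})
        cfg = RunConfig(efficiency=eff, **raw)
    except TypeError as exc:  # wrong value shapes
        raise ConfigError(str(exc)) from exc
    cfg.validate()
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    return asdict(cfg)


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
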