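"""Station-table I/O, run configuration and run manifests."""
from __future__ import annotations

import hashlib
import json
import logging
import math
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .params import (
    CLADOCERAN,
    COPEPOD,
    NAUPLIUS,
    SENSITIVITY_NAUPLIUS,
    LarvalStage,
    ModelParams,
    PreyType,
    default_stages,
)
from .synthetic import Station
from .visual_foraging import CalibrationAnchor

__all__ = [
    "read_station_csv",
    "write_station_csv",
    "RunConfig",
    "load_config",
    "save_config",
    "write_manifest",
    "COLUMN_ALIASES",
]

log = logging.getLogger(__name__)

# Case-insensitive header aliases for the survey table.
COLUMN_ALIASES = {
    "station_id": {"station_id", "id", "station", "st"},
    "year": {"year"},
    "longitude": {"longitude", "lon", "long"},
    "latitude": {"latitude", "lat"},
    "temperature_c": {"temperature_c", "temperature", "temp", "temp_c", "mixed_layer_temperature", "sst"},
    "nauplii_m3": {"nauplii_m3", "nauplii", "nauplius"},
    "cladocera_m3": {"cladocera_m3", "cladocera", "cladocerans", "cladoceran"},
    "copepods_m3": {"copepods_m3", "copepods", "copepod"},
    "bluefin_m3": {"bluefin_m3", "bluefin", "bluefin_larvae", "tuna_larvae"},
}
_PREY_COLUMNS = ("nauplii_m3", "cladocera_m3", "copepods_m3")


def _canonical_columns(columns: Sequence[str]) -> Dict[str, str]:
    mapping = {}
    for col in columns:
        key = col.strip().lower()
        for canonical, aliases in COLUMN_ALIASES.items():
            if key in aliases and canonical not in mapping:
                mapping[canonical] = col
    return mapping


def read_station_csv(path) -> List[Station]:
    """Read a survey-station table into :class:`Station` records.

    Headers are matched case-insensitively against common aliases. Station
    id and temperature columns are mandatory; rows missing a prey density
    get 0 with a warning; rows with a negative density are reported (row
    and column named) and skipped, processing continues.
    """
    path = Path(path)
    df = pd.read_csv(path)
    mapping = _canonical_columns(df.columns)
    missing = [c for c in ("station_id", "temperature_c") if c not in mapping]
    if missing:
        raise ValueError(
            f"{path.name}: missing mandatory column(s) {missing}; "
            f"found headers {list(df.columns)}"
        )
    if df.empty:
        log.warning("%s: no data rows", path.name)
        return []

    stations: List[Station] = []
    for idx, row in df.iterrows():
        densities = {}
        bad = False
        for col in _PREY_COLUMNS + ("bluefin_m3",):
            if col in mapping:
                value = row[mapping[col]]
                value = float(value) if pd.notna(value) else None
            else:
                value = None
            if value is None and col in _PREY_COLUMNS:
                log.warning(
                    "%s row %d: missing %s; treated as absent (0 m^-3)", path.name, idx, col
                )
                value = 0.0
            if value is not None and value < 0:
                log.error(
                    "%s row %d: negative density %g in column %s; row skipped",
                    path.name,
                    idx,
                    value,
                    col,
                )
                bad = True
            densities[col] = value
        if bad:
            continue
        temp = row[mapping["temperature_c"]]
        temp = float(temp) if pd.notna(temp) else None
        stations.append(
            Station(
                id=str(row[mapping["station_id"]]),
                year=row[mapping["year"]] if "year" in mapping else "unknown",
                longitude=float(row[mapping["longitude"]]) if "longitude" in mapping else math.nan,
                latitude=float(row[mapping["latitude"]]) if "latitude" in mapping else math.nan,
                temperature=temp,
                nauplii=densities["nauplii_m3"],
                cladocera=densities["cladocera_m3"],
                copepods=densities["copepods_m3"],
                bluefin=densities["bluefin_m3"],
            )
        )
    return stations


def write_station_csv(stations: Sequence[Station], path) -> None:
    from .synthetic import stations_to_frame

    stations_to_frame(list(stations)).to_csv(path, index=False)


class StageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    code: str
    standard_length: float = Field(gt=0)

    def to_stage(self) -> LarvalStage:
        return LarvalStage(self.code, self.standard_length)


class PreyConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    length: float = Field(gt=0)
    dry_weight: float = Field(gt=0)
    capture_mode: str = "ontogenetic_ramp"

    def to_prey(self) -> PreyType:
        return PreyType(self.name, self.length, self.dry_weight, self.capture_mode)


class AnchorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    stage: str = "F0"
    prey: str = "nauplius"
    temp: float = 22.0
    target_density: float = Field(default=4000.0, gt=0)
    target: str = "max_growth"


class RunConfig(BaseModel):
    """Full description of an analysis run; round-trips through YAML.

    Unknown keys are rejected so a typo in a constant name cannot silently
    fall back to the default.
    """

    model_config = ConfigDict(extra="forbid")

    params: Dict[str, object] = Field(default_factory=dict)  # ModelParams overrides
    stages: Optional[List[StageConfig]] = None
    preys: Optional[List[PreyConfig]] = None
    sensitivity_nauplius: bool = False
    anchor: AnchorConfig = Field(default_factory=AnchorConfig)
    scenarios: List[str] = Field(
        default_factory=lambda: ["nauplii_only", "cladocera_only", "copepods_only", "combined"]
    )
    temps: List[float] = Field(default_factory=lambda: [22.0, 25.0, 28.0])
    seed: int = 0
    output_dir: str = "."
    verbosity: str = "info"

    @field_validator("params")
    @classmethod
    def _known_param_keys(cls, v: Dict[str, object]) -> Dict[str, object]:
        valid = set(ModelParams.__dataclass_fields__)
        unknown = set(v) - valid
        if unknown:
            raise ValueError(
                f"unknown ModelParams override(s): {sorted(unknown)}; valid keys: {sorted(valid)}"
            )
        return v

    def model_params(self) -> ModelParams:
        overrides = dict(self.params)
        if "resp_conversions" in overrides:
            overrides["resp_conversions"] = tuple(overrides["resp_conversions"])
        return ModelParams(**overrides)

    def stage_list(self) -> List[LarvalStage]:
        if self.stages is None:
            return list(default_stages())
        return [s.to_stage() for s in self.stages]

    def prey_list(self) -> List[PreyType]:
        if self.preys is not None:
            return [p.to_prey() for p in self.preys]
        naup = SENSITIVITY_NAUPLIUS if self.sensitivity_nauplius else NAUPLIUS
        return [naup, CLADOCERAN, COPEPOD]

    def calibration_anchor(self) -> CalibrationAnchor:
        stages = {s.code: s for s in self.stage_list()}
        preys = {p.name: p for p in self.prey_list()}
        if self.anchor.stage not in stages:
            raise ValueError(f"anchor stage {self.anchor.stage!r} not in configured stages")
        if self.anchor.prey not in preys:
            raise ValueError(f"anchor prey {self.anchor.prey!r} not in configured preys")
        return CalibrationAnchor(
            stage=stages[self.anchor.stage],
            prey=preys[self.anchor.prey],
            temp=self.anchor.temp,
            target_density=self.anchor.target_density,
            target=self.anchor.target,
        )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)


def write_manifest(
    out_dir,
    command: str,
    config: RunConfig,
    seed: Optional[int] = None,
    calibrated_c: Optional[float] = None,
    extra: Optional[Dict[str, object]] = None,
) -> Path:
    """Record everything needed to reproduce a run next to its outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config_yaml = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    manifest = {
        "command": command,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
        "config": config.model_dump(mode="json"),
        "seed": seed,
        "detection_calib_c": calibrated_c,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / f"manifest_{command.replace(' ', '_')}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
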