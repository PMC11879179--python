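"""Critical prey densities and station-level food-limitation assessment.

A critical density is the ambient concentration of a single prey type at
which a larva exactly meets a growth target: "maintenance" (assimilation
balances metabolism, zero growth) or "max_growth" (the temperature-driven
ad-libitum ceiling). Because ingestion is linear in density the threshold is
closed-form,

    N* = i_req / (P · β · W_prey),

which the numeric response surface reproduces exactly (a test invariant).

The station assessment evaluates four diet scenarios (each prey alone and
all combined) against survey observations and flags food limitation where
the food-limitation index FLI = realized SGR / ad-libitum SGR falls below 1.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import bioenergetics, visual_foraging
from .params import LarvalStage, ModelParams, PreyType, default_preys, default_stages
from .synthetic import Station

__all__ = [
    "critical_density",
    "critical_density_table",
    "response_surface",
    "assess_stations",
    "assessment_frame",
    "StationAssessment",
    "ScenarioResult",
    "DIET_SCENARIOS",
    "DEFAULT_STATION_TEMP",
]

log = logging.getLogger(__name__)

# Fallback mixed-layer temperature when a station record lacks one (°C).
DEFAULT_STATION_TEMP = 24.5

DIET_SCENARIOS = ("nauplii_only", "cladocera_only", "copepods_only", "combined")


def critical_density(
    stage: LarvalStage,
    prey: PreyType,
    temp: float,
    target: str,
    params: ModelParams,
) -> float:
    """Single-prey density (m⁻³) at which the growth target is exactly met.

    Returns ``inf`` when the capture probability is zero (the prey cannot
    contribute at this stage, so no finite density suffices).
    """
    i_req = visual_foraging.required_ingestion(stage, temp, target, params)
    p = visual_foraging.capture_probability(prey, stage, params)
    if p == 0.0:
        return math.inf
    r = visual_foraging.detection_distance(prey, stage, "day", params)
    beta = visual_foraging.search_rate(r, stage, params)
    return i_req / (p * beta * prey.dry_weight)


def critical_density_table(
    stages: Optional[Sequence[LarvalStage]] = None,
    preys: Optional[Sequence[PreyType]] = None,
    temps: Sequence[float] = (22.0, 25.0, 28.0),
    targets: Sequence[str] = ("maintenance", "max_growth"),
    params: ModelParams = None,
) -> pd.DataFrame:
    """Cartesian grid of critical densities as a long-format DataFrame.

    Columns: stage, standard_length_mm, prey, temperature_c, target,
    critical_density_m3.
    """
    if params is None:
        raise ValueError("calibrated ModelParams required")
    stages = list(stages) if stages is not None else list(default_stages())
    preys = list(preys) if preys is not None else list(default_preys())
    rows = []
    for stage in stages:
        for prey in preys:
            for temp in temps:
                for target in targets:
                    rows.append(
                        {
                            "stage": stage.code,
                            "standard_length_mm": stage.standard_length,
                            "prey": prey.name,
                            "temperature_c": temp,
                            "target": target,
                            "critical_density_m3": critical_density(
                                stage, prey, temp, target, params
                            ),
                        }
                    )
    return pd.DataFrame(rows)


def response_surface(
    stage: LarvalStage,
    prey: PreyType,
    temps: Sequence[float],
    densities: Sequence[float],
    params: ModelParams = None,
) -> pd.DataFrame:
    """Realized daily SGR over a density grid, one curve per temperature.

    Each curve rises linearly with density, crosses zero at the maintenance
    density and saturates exactly at the ad-libitum ceiling. Columns:
    temperature_c, density_m3, daily_sgr, daily_sgr_uncapped, fli.
    """
    if params is None:
        raise ValueError("calibrated ModelParams required")
    rows = []
    for temp in temps:
        for density in densities:
            b = bioenergetics.growth_budget(stage, [(prey, density)], temp, params)
            rows.append(
                {
                    "temperature_c": temp,
                    "density_m3": density,
                    "daily_sgr": b.daily_sgr,
                    "daily_sgr_uncapped": b.daily_sgr_uncapped,
                    "fli": b.fli,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScenarioResult:
    """Outcome of one diet scenario for one larval stage at one station."""

    scenario: str
    stage: str
    daily_sgr: float
    fli: float
    limited: bool  # FLI < 1: food does not support ad-libitum growth
    starving: bool  # realized SGR < 0: metabolism not covered


@dataclass(frozen=True)
class StationAssessment:
    station_id: str
    temperature_c: float
    results: Tuple[ScenarioResult, ...]

    def result(self, scenario: str, stage: str) -> ScenarioResult:
        for r in self.results:
            if r.scenario == scenario and r.stage == stage:
                return r
        raise KeyError((scenario, stage))


def _scenario_diet(
    scenario: str, station: Station, preys: Mapping[str, PreyType]
) -> list:
    densities = {
        "nauplii_only": [("nauplius", station.nauplii)],
        "cladocera_only": [("cladoceran", station.cladocera)],
        "copepods_only": [("copepod", station.copepods)],
        "combined": [
            ("nauplius", station.nauplii),
            ("cladoceran", station.cladocera),
            ("copepod", station.copepods),
        ],
    }[scenario]
    return [(preys[key], dens) for key, dens in densities]


def assess_stations(
    stations: Iterable[Station],
    stages: Optional[Sequence[LarvalStage]] = None,
    params: ModelParams = None,
    scenarios: Sequence[str] = DIET_SCENARIOS,
    preys: Optional[Mapping[str, PreyType]] = None,
) -> list:
    """Evaluate the diet scenarios for every station and stage.

    Missing station temperatures fall back to ``DEFAULT_STATION_TEMP`` with
    a warning; a malformed station is reported and skipped rather than
    aborting the survey run. Returns a list of :class:`StationAssessment`.
    """
    if params is None:
        raise ValueError("calibrated ModelParams required")
    stages = list(stages) if stages is not None else list(default_stages())
    if preys is None:
        naup, clad, cop = default_preys()
        preys = {"nauplius": naup, "cladoceran": clad, "copepod": cop}
    unknown = set(scenarios) - set(DIET_SCENARIOS)
    if unknown:
        raise ValueError(f"unknown diet scenarios: {sorted(unknown)}")

    out = []
    for station in stations:
        temp = station.temperature
        if temp is None or (isinstance(temp, float) and math.isnan(temp)):
            log.warning(
                "station %s has no temperature; using default %.1f °C",
                station.id,
                DEFAULT_STATION_TEMP,
            )
            temp = DEFAULT_STATION_TEMP
        try:
            results = []
            for scenario in scenarios:
                diet = _scenario_diet(scenario, station, preys)
                for stage in stages:
                    b = bioenergetics.growth_budget(stage, diet, temp, params)
                    results.append(
                        ScenarioResult(
                            scenario=scenario,
                            stage=stage.code,
                            daily_sgr=b.daily_sgr,
                            fli=b.fli,
                            limited=b.fli < 1.0,
                            starving=b.daily_sgr < 0.0,
                        )
                    )
        except (ValueError, TypeError) as exc:
            log.error("station %s skipped: %s", station.id, exc)
            continue
        out.append(
            StationAssessment(
                station_id=str(station.id), temperature_c=temp, results=tuple(results)
            )
        )
    return out


def assessment_frame(assessments: Sequence[StationAssessment]) -> pd.DataFrame:
    """Flatten assessments to one row per station × stage × scenario."""
    rows = []
    for a in assessments:
        for r in a.results:
            rows.append(
                {
                    "station_id": a.station_id,
                    "temperature_c": a.temperature_c,
                    "scenario": r.scenario,
                    "stage": r.stage,
                    "daily_sgr": r.daily_sgr,
                    "fli": r.fli,
                    "limited": r.limited,
                    "starving": r.starving,
                }
            )
    return pd.DataFrame(rows)
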