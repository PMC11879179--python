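"""Size- and temperature-dependent physiology and the daily growth budget.

The budget balances assimilated ingestion against routine metabolism::

    SGR_hourly · W = α · i_total − R(W, T)

with W the larval dry weight (mg), i_total the summed hourly ingestion over
prey types (mg dw h⁻¹) and R routine metabolism (mg dw h⁻¹). The daily rate
is the hourly rate accumulated over the photoperiod and capped at the
temperature-dependent ad-libitum ceiling measured in rearing experiments.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

from .params import LarvalStage, ModelParams, PreyType

__all__ = [
    "weight_from_length",
    "metabolic_rate",
    "sgr_max",
    "growth_budget",
    "GrowthBudget",
    "PreyIntake",
    "SGR_VALID_RANGE",
]

# Temperature range of the ad-libitum growth experiments; the linear SGR
# ceiling is an extrapolation outside it.
SGR_VALID_RANGE = (22.0, 28.0)


def weight_from_length(sl: float, params: ModelParams = ModelParams()) -> float:
    """Larval dry weight (mg) from standard length (mm), W = a·e^(b·SL)."""
    if not sl > 0:
        raise ValueError(f"standard length must be > 0, got {sl}")
    return params.lw_coef * math.exp(params.lw_exp * sl)


def metabolic_rate(w: float, temp: float, params: ModelParams = ModelParams()) -> float:
    """Routine metabolism (mg dw h⁻¹) of a larva of dry weight ``w`` mg.

    The allometric oxygen-consumption rate at the reference temperature is
    converted to dry mass through the ordered factor chain
    ``params.resp_conversions`` and scaled by Q10 to ``temp``.
    """
    if not w > 0:
        raise ValueError(f"dry weight must be > 0, got {w}")
    base = params.resp_coef * w**params.resp_exp * params.resp_conversion_product
    return base * params.q10 ** ((temp - params.t_ref) / 10.0)


def sgr_max(temp: float, params: ModelParams = ModelParams()) -> float:
    """Ad-libitum (food-unlimited) specific growth rate, day⁻¹.

    Linear in temperature; emits a warning outside the experimentally
    supported 22–28 °C range, where the line is an extrapolation.
    """
    lo, hi = SGR_VALID_RANGE
    if temp < lo or temp > hi:
        warnings.warn(
            f"temperature {temp} °C outside the {lo}-{hi} °C range of the "
            "ad-libitum growth experiments; SGR ceiling is extrapolated",
            stacklevel=2,
        )
    return params.sgr_slope * temp - params.sgr_intercept


@dataclass(frozen=True)
class PreyIntake:
    """Per-prey foraging components of a budget (all daylight rates)."""

    prey: PreyType
    density: float  # m⁻³
    detection_distance_m: float
    search_rate_m3_h: float
    capture_probability: float
    encounter_rate_h: float  # encounters h⁻¹ (before capture)
    ingestion_count_h: float  # captures h⁻¹
    ingestion_mg_h: float


@dataclass(frozen=True)
class GrowthBudget:
    """Complete hourly/daily energy budget of one larva at one station."""

    stage: LarvalStage
    temp: float
    dry_weight_mg: float
    per_prey: Tuple[PreyIntake, ...]
    ingestion_mg_h: float
    metabolic_mg_h: float
    hourly_sgr: float  # h⁻¹, daylight
    daily_sgr_uncapped: float  # day⁻¹, before the ad-libitum cap
    sgr_ad_libitum: float  # day⁻¹ ceiling at this temperature
    daily_sgr: float  # day⁻¹, realized (capped)
    capped: bool
    fli: float  # food limitation index, realized / ad-libitum, ≤ 1

    @property
    def daily_growth_mg(self) -> float:
        """Uncapped daily mass change (mg dw day⁻¹)."""
        return self.daily_sgr_uncapped * self.dry_weight_mg


def growth_budget(
    stage: LarvalStage,
    diet: Iterable[Tuple[PreyType, float]],
    temp: float,
    params: ModelParams,
) -> GrowthBudget:
    """Assemble the full energy budget for one larva, diet and temperature.

    ``diet`` pairs each prey type with its ambient density (m⁻³); an empty
    diet describes starvation. The realized daily rate is
    ``min(uncapped, sgr_max(temp))``; the food-limitation index FLI is the
    realized rate divided by the ceiling (FLI = 1 means unlimited growth).
    """
    from . import visual_foraging  # deferred: visual_foraging imports this module

    diet = list(diet)
    for prey, density in diet:
        if density < 0:
            raise ValueError(f"negative density {density} for prey {prey.name!r}")

    w = stage.dry_weight(params)
    r_h = metabolic_rate(w, temp, params)

    per_prey = []
    i_total = 0.0
    for prey, density in diet:
        r_det = visual_foraging.detection_distance(prey, stage, "day", params)
        beta = visual_foraging.search_rate(r_det, stage, params)
        p = visual_foraging.capture_probability(prey, stage, params)
        count, mass = visual_foraging.ingestion_rate(prey, density, stage, "day", params)
        per_prey.append(
            PreyIntake(
                prey=prey,
                density=density,
                detection_distance_m=r_det,
                search_rate_m3_h=beta,
                capture_probability=p,
                encounter_rate_h=beta * density,
                ingestion_count_h=count,
                ingestion_mg_h=mass,
            )
        )
        i_total += mass

    hourly = (params.alpha * i_total - r_h) / w
    daylight = params.daylight_hours
    uncapped = hourly * daylight
    if params.metabolism_accounting == "full_day":
        uncapped -= (24.0 - daylight) * r_h / w

    ceiling = sgr_max(temp, params)
    capped = uncapped >= ceiling
    realized = ceiling if capped else uncapped
    fli = realized / ceiling if ceiling > 0 else math.nan

    return GrowthBudget(
        stage=stage,
        temp=temp,
        dry_weight_mg=w,
        per_prey=tuple(per_prey),
        ingestion_mg_h=i_total,
        metabolic_mg_h=r_h,
        hourly_sgr=hourly,
        daily_sgr_uncapped=uncapped,
        sgr_ad_libitum=ceiling,
        daily_sgr=realized,
        capped=capped,
        fli=fli,
    )
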