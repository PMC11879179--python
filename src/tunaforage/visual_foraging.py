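"""Visual prey detection, search volume, capture and ingestion.

Larvae are visual daylight predators cruising at a fixed number of body
lengths per second and scanning the upper half of the visual field (prey are
detected against the bright sea surface). The clearance (search) rate for a
prey type is the half-disc swept per unit time::

    β = ½ π R² V_L        [m³ h⁻¹]

with R the prey-specific detection distance and V_L the swimming speed.
Detection distance grows with both prey size and larval eye development; we
model it as proportional to the product of prey length and larval length,

    R[mm] = c · l_prey[mm] · L[mm],

with a single optical constant c calibrated against one known critical
density (see :func:`calibrate_detection`). Ingestion is linear in prey
density — no handling-time saturation; the ad-libitum growth ceiling in
:mod:`tunaforage.bioenergetics` is the only saturating mechanism.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

from . import bioenergetics
from .params import (
    MM_PER_M,
    NAUPLIUS,
    CalibrationError,
    LarvalStage,
    ModelParams,
    PreyType,
)

__all__ = [
    "detection_distance",
    "search_rate",
    "capture_probability",
    "ingestion_rate",
    "CalibrationAnchor",
    "DEFAULT_ANCHOR",
    "calibrate_detection",
    "required_ingestion",
]

_F0 = LarvalStage("F0", 4.8)


def detection_distance(
    prey: PreyType,
    stage: LarvalStage,
    light: str = "day",
    params: ModelParams = ModelParams(),
) -> float:
    """Maximum visual detection distance (m) for one prey type.

    Zero at night: the larvae do not feed in darkness, which the model
    realizes as a vanishing detection distance.
    """
    if light not in ("day", "night"):
        raise ValueError(f"light must be 'day' or 'night', got {light!r}")
    if light == "night":
        return 0.0
    c = params.require_calibrated()
    return c * prey.length * stage.standard_length / MM_PER_M


def search_rate(
    detection_r: float, stage: LarvalStage, params: ModelParams = ModelParams()
) -> float:
    """Clearance rate β = ½·π·R²·V_L (m³ h⁻¹) for detection distance R (m)."""
    if detection_r < 0:
        raise ValueError("detection distance must be >= 0")
    return 0.5 * math.pi * detection_r**2 * stage.swim_speed_m_per_h(params)


def capture_probability(
    prey: PreyType, stage: LarvalStage, params: ModelParams = ModelParams()
) -> float:
    """Probability that an encountered prey item is captured, in [0, 1].

    Nauplii-class prey are always captured. For evasive, larger prey the
    probability ramps linearly with larval length from 0 at first feeding
    to 1 at post-flexion. With ``params.assume_full_capture`` every prey is
    captured (the mode under which single-prey critical-density tables are
    produced).
    """
    if params.assume_full_capture or prey.capture_mode == "always_one":
        return 1.0
    span = params.capture_ramp_end - params.capture_ramp_start
    frac = (stage.standard_length - params.capture_ramp_start) / span
    return min(1.0, max(0.0, frac))


def ingestion_rate(
    prey: PreyType,
    density: float,
    stage: LarvalStage,
    light: str = "day",
    params: ModelParams = ModelParams(),
) -> Tuple[float, float]:
    """Hourly ingestion of one prey type: (items h⁻¹, mg dw h⁻¹).

    i = P · β · N per hour; mass flux is the count times the prey dry
    weight. Linear in density (type-I functional response).
    """
    if density < 0:
        raise ValueError(f"density must be >= 0, got {density}")
    r = detection_distance(prey, stage, light, params)
    beta = search_rate(r, stage, params)
    count = capture_probability(prey, stage, params) * beta * density
    return count, count * prey.dry_weight


def required_ingestion(
    stage: LarvalStage, temp: float, target: str, params: ModelParams
) -> float:
    """Hourly ingestion (mg dw h⁻¹) needed to meet a growth target.

    "maintenance": assimilation exactly balances daylight metabolism;
    "max_growth": additionally funds the ad-libitum daily growth ceiling,
    spread over the feeding hours. Under full-day metabolism accounting the
    night-time metabolic cost must be earned during daylight as well.
    """
    if target not in ("maintenance", "max_growth"):
        raise ValueError(f"target must be 'maintenance' or 'max_growth', got {target!r}")
    w = stage.dry_weight(params)
    r_h = bioenergetics.metabolic_rate(w, temp, params)
    growth_h = (
        bioenergetics.sgr_max(temp, params) * w / params.daylight_hours
        if target == "max_growth"
        else 0.0
    )
    metab_h = r_h
    if params.metabolism_accounting == "full_day":
        metab_h = r_h * 24.0 / params.daylight_hours
    return (growth_h + metab_h) / params.alpha


@dataclass(frozen=True)
class CalibrationAnchor:
    """One known critical density used to pin the optical constant c."""

    stage: LarvalStage = _F0
    prey: PreyType = NAUPLIUS
    temp: float = 22.0
    target_density: float = 4000.0  # m⁻³
    target: str = "max_growth"

    def __post_init__(self) -> None:
        if not self.target_density > 0:
            raise ValueError("anchor target_density must be > 0")


DEFAULT_ANCHOR = CalibrationAnchor()


def calibrate_detection(
    params: ModelParams = ModelParams(), anchor: CalibrationAnchor = DEFAULT_ANCHOR
) -> ModelParams:
    """Solve the optical constant c from one anchor critical density.

    Closed form: the clearance rate that makes the anchor density exactly
    critical is β* = i_req / (P·N·W_prey); inverting β = ½πR²V and
    R = c·l·L gives

        c = √(2 i_req / (π V_L N W_prey P)) / (l_prey · L)     [per mm²]

    Returns a copy of ``params`` with ``detection_calib_c`` set; every other
    critical density predicted by the model is then out-of-sample.
    """
    a = anchor
    i_req = required_ingestion(a.stage, a.temp, a.target, params)
    p = capture_probability(a.prey, a.stage, params)
    if not p > 0:
        raise ValueError("anchor capture probability is 0; cannot calibrate")
    beta_req = i_req / (p * a.target_density * a.prey.dry_weight)
    v = a.stage.swim_speed_m_per_h(params)
    r_m = math.sqrt(2.0 * beta_req / (math.pi * v))
    c = r_m * MM_PER_M / (a.prey.length * a.stage.standard_length)
    return params.with_(detection_calib_c=c)
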