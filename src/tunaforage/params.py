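"""Domain types and physiological constants for the larval foraging model.

Units throughout the package: lengths in mm (detection distances are
returned in m), masses in mg dry weight, prey densities in individuals m⁻³,
temperatures in °C, rates per hour unless a name says per day.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

__all__ = [
    "ModelParams",
    "LarvalStage",
    "PreyType",
    "CalibrationError",
    "default_stages",
    "default_preys",
    "NAUPLIUS",
    "CLADOCERAN",
    "COPEPOD",
    "SENSITIVITY_NAUPLIUS",
]

MM_PER_M = 1000.0
S_PER_H = 3600.0


class CalibrationError(RuntimeError):
    """Raised when the detection-distance constant is required but unset."""


@dataclass(frozen=True)
class ModelParams:
    """Physiological and optical constants of the growth/foraging model.

    Parameters
    ----------
    alpha
        Assimilation efficiency (fraction of ingested mass retained).
    q10
        Factor by which routine metabolism multiplies per +10 °C.
    resp_coef, resp_exp
        Allometry of routine respiration at the reference temperature,
        ``resp_coef * W**resp_exp`` in µmol O₂ h⁻¹ for W in mg dw.
    resp_conversions
        Ordered multiplicative factors converting µmol O₂ h⁻¹ to
        mg dw h⁻¹ (O₂→µg, protein fraction, C:protein, dw:C); kept as an
        explicit chain so each factor is auditable.
    t_ref
        Reference temperature of the respiration measurement, °C.
    sgr_slope, sgr_intercept
        Linear temperature dependence of the ad-libitum specific growth
        rate, day⁻¹ = ``sgr_slope * T - sgr_intercept`` (valid 22–28 °C).
    lw_coef, lw_exp
        Exponential length–weight relation, mg = ``lw_coef * e**(lw_exp*SL)``.
    daylight_hours
        Photoperiod; larvae feed only in daylight.
    swim_bl_per_s
        Cruising speed in body lengths per second.
    detection_calib_c
        Proportionality constant of visual prey detection,
        R[mm] = c · prey_length[mm] · larval_length[mm]. ``None`` until
        calibrated (see :func:`tunaforage.visual_foraging.calibrate_detection`).
    capture_ramp_start, capture_ramp_end
        Larval lengths (mm) between which capture probability for large
        prey ramps linearly from 0 (first feeding) to 1 (post-flexion).
    assume_full_capture
        If True, capture probability is 1 for every prey regardless of
        ontogeny (the mode used to reproduce single-prey threshold tables).
    metabolism_accounting
        "daylight": the daily budget accrues metabolism only over the
        feeding (daylight) hours; "full_day" additionally subtracts the
        night-time metabolic cost.
    """

    alpha: float = 0.77
    q10: float = 2.0
    resp_coef: float = 0.404
    resp_exp: float = 0.994
    resp_conversions: Tuple[float, ...] = (32.0, 0.88, 12.0 / 34.0, 100.0 / (1000.0 * 45.0))
    t_ref: float = 26.0
    sgr_slope: float = 0.0418
    sgr_intercept: float = 0.8355
    lw_coef: float = 0.0008
    lw_exp: float = 0.9052
    daylight_hours: float = 15.0
    swim_bl_per_s: float = 3.0
    detection_calib_c: Optional[float] = None
    capture_ramp_start: float = 3.0
    capture_ramp_end: float = 7.5
    assume_full_capture: bool = False
    metabolism_accounting: str = "daylight"

    def __post_init__(self) -> None:
        positive = {
            "q10": self.q10,
            "resp_coef": self.resp_coef,
            "resp_exp": self.resp_exp,
            "lw_coef": self.lw_coef,
            "lw_exp": self.lw_exp,
            "daylight_hours": self.daylight_hours,
            "swim_bl_per_s": self.swim_bl_per_s,
            "sgr_slope": self.sgr_slope,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not self.capture_ramp_start < self.capture_ramp_end:
            raise ValueError("capture_ramp_start must be < capture_ramp_end")
        if any(f <= 0 for f in self.resp_conversions):
            raise ValueError("resp_conversions must all be > 0")
        if self.metabolism_accounting not in ("daylight", "full_day"):
            raise ValueError(
                "metabolism_accounting must be 'daylight' or 'full_day', "
                f"got {self.metabolism_accounting!r}"
            )
        if self.detection_calib_c is not None and not self.detection_calib_c > 0:
            raise ValueError("detection_calib_c must be > 0 when set")
        if not self.daylight_hours <= 24:
            raise ValueError("daylight_hours cannot exceed 24")

    @property
    def resp_conversion_product(self) -> float:
        out = 1.0
        for f in self.resp_conversions:
            out *= f
        return out

    def require_calibrated(self) -> float:
        if self.detection_calib_c is None:
            raise CalibrationError(
                "detection_calib_c is unset; run calibrate_detection() first "
                "or supply the constant explicitly"
            )
        return self.detection_calib_c

    def with_(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


@dataclass(frozen=True)
class LarvalStage:
    """A larval developmental stage, identified by standard length.

    Dry weight is always derived from length through the length–weight
    relation; it is never stored independently.
    """

    code: str
    standard_length: float  # mm
    swim_bl_per_s: Optional[float] = None  # overrides ModelParams if set

    def __post_init__(self) -> None:
        if not self.standard_length > 0:
            raise ValueError("standard_length must be > 0")
        if self.swim_bl_per_s is not None and not self.swim_bl_per_s > 0:
            raise ValueError("swim_bl_per_s must be > 0")

    def dry_weight(self, params: ModelParams) -> float:
        """Dry weight (mg) from the exponential length–weight relation."""
        return params.lw_coef * math.exp(params.lw_exp * self.standard_length)

    def swim_speed_m_per_h(self, params: ModelParams) -> float:
        """Cruising speed in m h⁻¹ (body lengths s⁻¹ × length)."""
        bl = self.swim_bl_per_s if self.swim_bl_per_s is not None else params.swim_bl_per_s
        return bl * self.standard_length / MM_PER_M * S_PER_H


@dataclass(frozen=True)
class PreyType:
    """A zooplankton prey category with fixed size and mass.

    capture_mode "always_one" means every encounter ends in capture at all
    larval sizes (small, easily handled prey such as nauplii);
    "ontogenetic_ramp" means capture probability rises linearly with larval
    length from first feeding to post-flexion (evasive/large prey).
    """

    name: str
    length: float  # mm
    dry_weight: float  # mg
    capture_mode: str = "ontogenetic_ramp"

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError("prey length must be > 0")
        if not self.dry_weight > 0:
            raise ValueError("prey dry_weight must be > 0")
        if self.capture_mode not in ("always_one", "ontogenetic_ramp"):
            raise ValueError(f"unknown capture_mode {self.capture_mode!r}")


# Default prey field of the western Mediterranean spawning ground.
NAUPLIUS = PreyType("nauplius", length=0.15, dry_weight=1.1e-4, capture_mode="always_one")
CLADOCERAN = PreyType("cladoceran", length=0.8, dry_weight=3.15e-3, capture_mode="ontogenetic_ramp")
COPEPOD = PreyType("copepod", length=1.0, dry_weight=1.11e-2, capture_mode="ontogenetic_ramp")
# Alternative (larger) nauplius used in the sensitivity scenario.
SENSITIVITY_NAUPLIUS = PreyType(
    "nauplius_large", length=0.3, dry_weight=5.0e-4, capture_mode="always_one"
)

_STAGE_LENGTHS = {"F0": 4.8, "F1": 5.8, "F2": 6.7, "F3": 7.5}


def default_stages() -> Tuple[LarvalStage, ...]:
    """The four modelled stages: pre-flexion (F0) through post-flexion (F3)."""
    return tuple(LarvalStage(code, sl) for code, sl in _STAGE_LENGTHS.items())


def default_preys(sensitivity_nauplius: bool = False) -> Tuple[PreyType, ...]:
    """Nauplius, cladoceran, copepod (optionally the large sensitivity nauplius)."""
    naup = SENSITIVITY_NAUPLIUS if sensitivity_nauplius else NAUPLIUS
    return (naup, CLADOCERAN, COPEPOD)
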