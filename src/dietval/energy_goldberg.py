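"""BMR, physical activity level, Goldberg cut-offs, and the energy-balance method.

The Goldberg approach asks whether a cohort's reported energy intake is
physiologically plausible: the ratio of reported intake to basal metabolic
rate (TDEI:BMR) should, on average, equal the cohort's physical activity
level (PAL = TDEE:BMR).  A 95% confidence band around PAL is built from a
pooled coefficient of variation S combining day-to-day intake variation
(over d assessment days), BMR repeatability, and between-subject PAL
variation.  Participants whose ratio falls below the band are classified as
under-reporters, above it as over-reporters.

The energy-balance (EB) method converts measured changes in fat mass and
fat-free mass into a daily energy-store change via the tissue energy
densities (9.5 kcal/g fat mass, 1.1 kcal/g fat-free mass), closing the
intake = expenditure + storage identity.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import DomainError

__all__ = [
    "GoldbergConfig",
    "GoldbergResult",
    "EnergyStoresConfig",
    "bmr_mifflin",
    "bmr_harris_benedict",
    "pal",
    "cohort_pal",
    "s_factor",
    "goldberg_limits",
    "upper_limit_from_lower",
    "classify_misreporting",
    "classify_cohort",
    "delta_energy_stores",
]

Classification = Literal["under", "plausible", "over"]


@dataclass(frozen=True)
class GoldbergConfig:
    """Inputs of the Goldberg confidence band.

    ``cv_wtdei`` and ``cv_tp`` may be study-specific (computed from the
    cohort) or literature values; ``cv_wb`` is the repeatability CV of BMR
    measurements (4.1% for free-living women).  ``d_days`` is the number of
    dietary-assessment days entering the within-subject CV.
    """

    d_days: int = 6
    cv_wb: float = 4.1
    cv_tp: float | None = None
    cv_wtdei: float | None = None
    sd_min: float = -2.0
    sd_max: float = 2.0
    pal: float | str = "computed"

    def __post_init__(self) -> None:
        if self.d_days < 1:
            raise DomainError("d_days must be >= 1")
        for name in ("cv_wb", "cv_tp", "cv_wtdei"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DomainError(f"{name} must be >= 0")
        if not (self.sd_min < 0 < self.sd_max):
            raise DomainError("sd_min must be negative and sd_max positive")


@dataclass
class GoldbergResult:
    s_factor: float
    pal: float
    lower_limit: float
    upper_limit: float
    classifications: list[Classification]
    n_under: int
    n_plausible: int
    n_over: int


@dataclass(frozen=True)
class EnergyStoresConfig:
    kcal_per_g_fm: float = 9.5
    kcal_per_g_ffm: float = 1.1

    def __post_init__(self) -> None:
        if self.kcal_per_g_fm <= 0 or self.kcal_per_g_ffm <= 0:
            raise DomainError("energy-density coefficients must be positive")


def bmr_mifflin(weight_kg: float, height_cm: float, age_y: float,
                sex: str = "female") -> float:
    """Mifflin-St Jeor basal metabolic rate, kcal/day.

    female: 10 w + 6.25 h − 5 a − 161; male: same with +5 instead of −161.
    """
    if weight_kg <= 0 or height_cm <= 0 or age_y <= 0:
        raise DomainError("weight, height and age must be strictly positive")
    base = 10.0 * weight_kg + 6.25 * height_cm - 5.0 * age_y
    if sex == "female":
        return base - 161.0
    if sex == "male":
        return base + 5.0
    raise DomainError(f"unknown sex {sex!r}; expected 'female' or 'male'")


def bmr_harris_benedict(weight_kg: float, height_cm: float, age_y: float,
                        sex: str = "female") -> float:
    """Revised Harris–Benedict BMR (Roza & Shizgal 1984), kcal/day."""
    if weight_kg <= 0 or height_cm <= 0 or age_y <= 0:
        raise DomainError("weight, height and age must be strictly positive")
    if sex == "female":
        return 447.593 + 9.247 * weight_kg + 3.098 * height_cm - 4.330 * age_y
    if sex == "male":
        return 88.362 + 13.397 * weight_kg + 4.799 * height_cm - 5.677 * age_y
    raise DomainError(f"unknown sex {sex!r}; expected 'female' or 'male'")


def pal(tdee_kcal: float, bmr_kcal: float) -> float:
    """Physical activity level: TDEE divided by BMR."""
    if bmr_kcal <= 0:
        raise DomainError("BMR must be positive")
    return tdee_kcal / bmr_kcal


def cohort_pal(tdee_kcal: Sequence[float], bmr_kcal: Sequence[float],
               method: str = "mean_of_ratios") -> float:
    """Cohort PAL: mean of the individual TDEE:BMR ratios (default) or ratio of means."""
    tdee = np.asarray(tdee_kcal, dtype=float)
    bmr = np.asarray(bmr_kcal, dtype=float)
    if tdee.shape != bmr.shape or tdee.size == 0:
        raise DomainError("tdee and bmr must be non-empty and aligned")
    if np.any(bmr <= 0):
        raise DomainError("all BMR values must be positive")
    if method == "mean_of_ratios":
        return float(np.mean(tdee / bmr))
    if method == "ratio_of_means":
        return float(np.mean(tdee) / np.mean(bmr))
    raise DomainError(f"unknown cohort PAL method {method!r}")


def s_factor(cv_wtdei: float, d_days: int, cv_wb: float, cv_tp: float) -> float:
    """Pooled variation factor S = sqrt(CVwTDEI²/d + CVwB² + CVtP²), percent."""
    if d_days < 1:
        raise DomainError("d_days must be >= 1")
    if min(cv_wtdei, cv_wb, cv_tp) < 0:
        raise DomainError("coefficients of variation must be non-negative")
    return math.sqrt(cv_wtdei**2 / d_days + cv_wb**2 + cv_tp**2)


def goldberg_limits(pal_value: float, s: float, n: int,
                    sd_min: float = -2.0, sd_max: float = 2.0) -> tuple[float, float]:
    """95% confidence band for the TDEI:BMR ratio around the cohort PAL.

    lower = PAL·exp(sd_min·S/(100√n)), upper = PAL·exp(sd_max·S/(100√n)).
    With symmetric sd bounds the band is geometrically symmetric:
    lower·upper = PAL².
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    if s < 0:
        raise DomainError("S must be non-negative")
    if pal_value <= 0:
        raise DomainError("PAL must be positive")
    scale = s / (100.0 * math.sqrt(n))
    return pal_value * math.exp(sd_min * scale), pal_value * math.exp(sd_max * scale)


def upper_limit_from_lower(lower: float, s: float, n: int,
                           sd_min: float = -2.0, sd_max: float = 2.0) -> float:
    """Upper confidence limit implied by a lower limit and the band width.

    Follows from the exponential band: upper/lower = exp((sd_max−sd_min)·S/(100√n)).
    """
    if lower <= 0:
        raise DomainError("lower limit must be positive")
    if n < 1 or s < 0:
        raise DomainError("need n >= 1 and S >= 0")
    return lower * math.exp((sd_max - sd_min) * s / (100.0 * math.sqrt(n)))


def classify_misreporting(tdei_kcal: float, bmr_kcal: float,
                          limits: tuple[float, float]) -> Classification:
    """Classify one participant's TDEI:BMR ratio against the Goldberg band.

    Strictly below the lower limit → under-reporter; strictly above the
    upper → over-reporter; boundary values are plausible.
    """
    if bmr_kcal <= 0:
        raise DomainError("BMR must be positive")
    lower, upper = limits
    ratio = tdei_kcal / bmr_kcal
    if ratio < lower:
        return "under"
    if ratio > upper:
        return "over"
    return "plausible"


def classify_cohort(
    tdei_kcal: Sequence[float],
    bmr_kcal: Sequence[float],
    tdee_kcal: Sequence[float],
    cfg: GoldbergConfig,
    pal_method: str = "mean_of_ratios",
) -> GoldbergResult:
    """Goldberg classification of a whole cohort.

    The cohort PAL is computed from TDEE and BMR unless ``cfg.pal`` fixes
    it; S uses ``cfg``'s CVs, which must both be set (study-specific values
    are computed upstream from the intake series and the PAL distribution).
    """
    tdei = np.asarray(tdei_kcal, dtype=float)
    bmr = np.asarray(bmr_kcal, dtype=float)
    if cfg.cv_wtdei is None or cfg.cv_tp is None:
        raise DomainError("GoldbergConfig.cv_wtdei and cv_tp must be set for classification")
    if tdei.shape != bmr.shape or tdei.size == 0:
        raise DomainError("tdei and bmr must be non-empty and aligned")
    n = tdei.size
    if isinstance(cfg.pal, (int, float)):
        pal_value = float(cfg.pal)
    else:
        pal_value = cohort_pal(tdee_kcal, bmr_kcal, method=pal_method)
    s = s_factor(cfg.cv_wtdei, cfg.d_days, cfg.cv_wb, cfg.cv_tp)
    limits = goldberg_limits(pal_value, s, n, cfg.sd_min, cfg.sd_max)
    classes: list[Classification] = [
        classify_misreporting(float(a), float(b), limits) for a, b in zip(tdei, bmr)
    ]
    counts = Counter(classes)
    return GoldbergResult(
        s_factor=s, pal=pal_value, lower_limit=limits[0], upper_limit=limits[1],
        classifications=classes,
        n_under=counts["under"], n_plausible=counts["plausible"],
        n_over=counts["over"],
    )


def delta_energy_stores(d_fm_kg: float, d_ffm_kg: float, days: float,
                        cfg: EnergyStoresConfig | None = None) -> float:
    """Daily energy-store change (kcal/day) from body-composition changes.

    ΔES = (ΔFM_g · 9.5 + ΔFFM_g · 1.1) / days.
    """
    cfg = cfg or EnergyStoresConfig()
    if days <= 0:
        raise DomainError("days must be strictly positive")
    return (d_fm_kg * 1000.0 * cfg.kcal_per_g_fm
            + d_ffm_kg * 1000.0 * cfg.kcal_per_g_ffm) / days
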