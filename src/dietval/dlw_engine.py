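"""Two-point doubly labelled water (DLW) engine.

The two-point protocol measures total daily energy expenditure (TDEE) from the
differential elimination of two stable-isotope tracers (deuterium and
oxygen-18) dosed at the start of a metabolic period.  Urine enrichments are
sampled at an initial post-dose plateau and again at the end of the period;
each tracer's mono-exponential elimination constant follows from the two
enrichments, its dilution space from the dose and the plateau, and CO2
production from the difference of the two elimination rates (oxygen leaves the
body both as water and as CO2, deuterium only as water).  The Weir equation
converts CO2 production to energy expenditure given a respiratory quotient.

The same dilution spaces yield body composition: total body water (TBW) is a
weighted average of the two spaces, fat-free mass is TBW under a fixed
hydration fraction, and fat mass is the remainder of body weight.

All enrichments are expressed in ppm excess over the reference standard, with
the participant's pre-dose sample taken as the baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DomainError, ValidationError

__all__ = [
    "DLWConfig",
    "IsotopeKinetics",
    "BodyComposition",
    "QCResult",
    "IsotopeSampleRow",
    "TwoPointResult",
    "elimination_constant",
    "dilution_space",
    "tbw_from_spaces",
    "body_composition",
    "qc_ratios",
    "rco2_speakman",
    "tdee_weir",
    "run_two_point",
    "dose_grams",
]

#: grams of 10 atom% H2(18)O and of 99.9 atom% (2)H2O per kg of body water
DOSE_O18_G_PER_KG_TBW = 1.8
DOSE_D2_G_PER_KG_TBW = 0.12


@dataclass(frozen=True)
class DLWConfig:
    """Physical constants and QC bounds of the DLW computation.

    The dilution-space divisors correct each tracer's apparent space for in
    vivo isotope exchange; the hydration factor converts TBW to fat-free
    mass.  ``dsr_*`` and ``err_*`` bound the dilution space ratio N_d/N_O and
    the elimination rate ratio k_O/k_d used for quality control.
    """

    tbw_divisor_d2: float = 1.041
    tbw_divisor_o18: float = 1.007
    hydration_factor: float = 0.732
    speakman_coeff: float = 0.4554
    o_weight: float = 1.007
    d_weight: float = 1.043
    litres_per_mol_co2: float = 22.26
    water_molar_mass_g: float = 18.02
    dsr_low: float = 1.000
    dsr_high: float = 1.070
    err_low: float = 1.100
    err_high: float = 1.700
    rq: float = 0.85

    def __post_init__(self) -> None:
        for name in (
            "tbw_divisor_d2", "tbw_divisor_o18", "hydration_factor",
            "speakman_coeff", "o_weight", "d_weight", "litres_per_mol_co2",
            "water_molar_mass_g",
        ):
            if getattr(self, name) <= 0:
                raise DomainError(f"DLWConfig.{name} must be strictly positive")
        if not (self.dsr_low < self.dsr_high):
            raise DomainError("DLWConfig requires dsr_low < dsr_high")
        if not (self.err_low < self.err_high):
            raise DomainError("DLWConfig requires err_low < err_high")


@dataclass
class IsotopeKinetics:
    """Elimination constants (per day) and dilution spaces (mol) of the two tracers."""

    k_O: float
    k_d: float
    N_O: float
    N_d: float
    N: float  # body-water pool used in the CO2-production equation, mol
    elapsed_days: float
    flags: list[str] = field(default_factory=list)


@dataclass
class BodyComposition:
    tbw_kg: float
    ffm_kg: float
    fm_kg: float
    source: str = "isotope_dilution"  # or "bioimpedance", "simulated"
    flags: list[str] = field(default_factory=list)


@dataclass
class QCResult:
    dilution_space_ratio: float
    elimination_rate_ratio: float
    flags: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.flags


@dataclass
class IsotopeSampleRow:
    """One participant's enrichment record, mirroring ``isotopes.csv``.

    Post-dose and final enrichments may be a single (already averaged) value
    or the sequence of same-day samples; the engine averages sequences.
    Enrichments are ppm excess over the reference standard.
    """

    participant_id: str
    dose_o18_g: float
    dose_d2_g: float
    ape_o18: float  # atom percent excess of the O-18 dose water
    ape_d2: float
    E_pre_o18: float
    E_post_o18: float | Sequence[float]
    E_final_o18: float | Sequence[float]
    E_pre_d2: float
    E_post_d2: float | Sequence[float]
    E_final_d2: float | Sequence[float]
    t_post_h: float
    t_final_h: float


@dataclass
class TwoPointResult:
    participant_id: str
    kinetics: IsotopeKinetics
    body_composition: BodyComposition
    qc: QCResult
    rco2_l_per_day: float
    tdee_kcal: float
    rq: float


def elimination_constant(
    delta_E_initial: float, delta_E_final: float, elapsed_days: float
) -> float:
    """Mono-exponential elimination constant, per day.

    ``k = ln(E_initial / E_final) / elapsed_days`` for background-corrected
    enrichments.  A final enrichment above the initial one yields a negative
    rate, which is returned (the caller flags it as a protocol violation)
    rather than masked.
    """
    if delta_E_initial <= 0 or delta_E_final <= 0:
        raise DomainError(
            "enrichments must be positive after background correction "
            f"(got initial={delta_E_initial}, final={delta_E_final}); "
            "a non-positive value signals a sample at or below background"
        )
    if elapsed_days <= 0:
        raise DomainError(f"elapsed_days must be > 0, got {elapsed_days}")
    return math.log(delta_E_initial / delta_E_final) / elapsed_days


def dilution_space(
    dose_mol: float, E_dose: float, E_tap: float, E_plateau: float, E_pre: float
) -> float:
    """Tracer dilution space in mol of body water, by the plateau method.

    ``N = dose_mol * (E_dose - E_tap) / (E_plateau - E_pre)``: the dose's
    isotope excess is diluted into the body-water pool until the sampled
    plateau excess is reached.
    """
    if E_plateau <= E_pre:
        raise DomainError(
            "plateau enrichment must exceed the pre-dose baseline "
            f"(plateau={E_plateau}, pre={E_pre}): no measurable enrichment"
        )
    if E_dose <= E_tap:
        raise DomainError("dose enrichment must exceed tap/background enrichment")
    if dose_mol <= 0:
        raise DomainError(f"dose must be positive, got {dose_mol} mol")
    return dose_mol * (E_dose - E_tap) / (E_plateau - E_pre)


def tbw_from_spaces(
    N_d_kg: float, N_O_kg: float, cfg: DLWConfig | None = None
) -> float:
    """Total body water (kg) as the average of the exchange-corrected spaces."""
    cfg = cfg or DLWConfig()
    if N_d_kg <= 0 or N_O_kg <= 0:
        raise DomainError("dilution spaces must be positive")
    return (N_d_kg / cfg.tbw_divisor_d2 + N_O_kg / cfg.tbw_divisor_o18) / 2.0


def body_composition(
    tbw_kg: float, weight_kg: float, cfg: DLWConfig | None = None,
    source: str = "isotope_dilution",
) -> BodyComposition:
    """Fat-free mass = TBW / hydration factor; fat mass = weight − FFM.

    A fat mass below zero (FFM exceeding body weight) is physically
    impossible and is returned flagged rather than clipped.
    """
    cfg = cfg or DLWConfig()
    if tbw_kg <= 0 or weight_kg <= 0:
        raise DomainError("tbw_kg and weight_kg must be positive")
    ffm = tbw_kg / cfg.hydration_factor
    fm = weight_kg - ffm
    flags = []
    if fm < -1e-9:  # tolerate rounding at the exact-hydration boundary
        flags.append("ffm_exceeds_body_weight")
    return BodyComposition(tbw_kg=tbw_kg, ffm_kg=ffm, fm_kg=fm,
                           source=source, flags=flags)


def qc_ratios(kin: IsotopeKinetics, cfg: DLWConfig | None = None) -> QCResult:
    """Dilution space ratio N_d/N_O and elimination rate ratio k_O/k_d with QC flags."""
    cfg = cfg or DLWConfig()
    if kin.N_O <= 0 or kin.N_d <= 0 or kin.k_d <= 0:
        raise DomainError("kinetics must have positive spaces and rates for QC")
    dsr = kin.N_d / kin.N_O
    err = kin.k_O / kin.k_d
    flags = []
    if dsr < cfg.dsr_low:
        flags.append("dsr_below_low")
    if dsr > cfg.dsr_high:
        flags.append("dsr_above_high")
    if err < cfg.err_low:
        flags.append("err_below_low")
    if err > cfg.err_high:
        flags.append("err_above_high")
    return QCResult(dilution_space_ratio=dsr, elimination_rate_ratio=err, flags=flags)


def rco2_speakman(
    N_mol: float, k_O: float, k_d: float, cfg: DLWConfig | None = None
) -> tuple[float, list[str]]:
    """CO2 production in litres/day from the weighted rate difference.

    ``rCO2 = 0.4554 * N * (1.007 k_O − 1.043 k_d) * 22.26`` with N in mol.
    A negative result signals inconsistent kinetics and is returned with a
    flag, never silently clipped.
    """
    cfg = cfg or DLWConfig()
    if N_mol <= 0:
        raise DomainError(f"N_mol must be positive, got {N_mol}")
    rate = cfg.o_weight * k_O - cfg.d_weight * k_d
    rco2 = cfg.speakman_coeff * N_mol * rate * cfg.litres_per_mol_co2
    flags = ["negative_rco2"] if rco2 < 0 else []
    return rco2, flags


def tdee_weir(rco2_l_per_day: float, rq: float) -> float:
    """Weir equation: TDEE (kcal/day) = rCO2 * (1.106 + 3.94 / RQ)."""
    if rq <= 0:
        raise DomainError(f"respiratory quotient must be positive, got {rq}")
    if not (0.67 < rq <= 1.3):
        raise DomainError(f"respiratory quotient {rq} outside the physiological range (0.67, 1.3]")
    if rco2_l_per_day < 0:
        raise DomainError("rCO2 must be non-negative for an energy expenditure")
    return rco2_l_per_day * (1.106 + 3.94 / rq)


def _mean(value: float | Sequence[float]) -> float:
    if np.isscalar(value):
        return float(value)  # type: ignore[arg-type]
    return float(np.mean(np.asarray(value, dtype=float)))


def _require(value, name: str) -> float:
    v = _mean(value) if value is not None else math.nan
    if value is None or math.isnan(v):
        raise ValidationError(f"missing isotope sample: {name}")
    return v


def dose_grams(tbw_kg: float) -> tuple[float, float]:
    """Dose sizes (g of O-18 water, g of deuterated water) for a given body water."""
    if tbw_kg <= 0:
        raise DomainError("tbw_kg must be positive")
    return DOSE_O18_G_PER_KG_TBW * tbw_kg, DOSE_D2_G_PER_KG_TBW * tbw_kg


def run_two_point(
    row: IsotopeSampleRow, weight_kg: float, cfg: DLWConfig | None = None
) -> TwoPointResult:
    """Full two-point chain for one participant.

    Plateau enrichment is the mean of the same-day post-dose samples; each
    elimination constant comes from the plateau vs the mean final enrichment
    over the elapsed time between samplings; dilution spaces come from the
    plateau by isotope dilution; the body-water pool for CO2 production is
    the mean of the two spaces in mol.
    """
    cfg = cfg or DLWConfig()
    elapsed_days = (row.t_final_h - row.t_post_h) / 24.0
    if elapsed_days <= 0:
        raise DomainError(
            f"final sampling must come after the post-dose plateau "
            f"(t_post={row.t_post_h} h, t_final={row.t_final_h} h)"
        )

    e_post_o = _require(row.E_post_o18, "E_post_o18")
    e_final_o = _require(row.E_final_o18, "E_final_o18")
    e_post_d = _require(row.E_post_d2, "E_post_d2")
    e_final_d = _require(row.E_final_d2, "E_final_d2")
    e_pre_o = _require(row.E_pre_o18, "E_pre_o18")
    e_pre_d = _require(row.E_pre_d2, "E_pre_d2")

    flags: list[str] = []
    k_O = elimination_constant(e_post_o - e_pre_o, e_final_o - e_pre_o, elapsed_days)
    k_d = elimination_constant(e_post_d - e_pre_d, e_final_d - e_pre_d, elapsed_days)
    if k_O < 0:
        flags.append("negative_k_O")
    if k_d < 0:
        flags.append("negative_k_d")
    if k_O <= k_d:
        flags.append("k_O_not_above_k_d")

    # ppm excess of the dose water over the reference standard: 1 atom% = 1e4 ppm
    n_o_mol = dilution_space(
        row.dose_o18_g / cfg.water_molar_mass_g,
        row.ape_o18 * 1e4, 0.0, e_post_o, e_pre_o,
    )
    n_d_mol = dilution_space(
        row.dose_d2_g / cfg.water_molar_mass_g,
        row.ape_d2 * 1e4, 0.0, e_post_d, e_pre_d,
    )
    n_mol = (n_o_mol + n_d_mol) / 2.0

    kin = IsotopeKinetics(
        k_O=k_O, k_d=k_d, N_O=n_o_mol, N_d=n_d_mol, N=n_mol,
        elapsed_days=elapsed_days, flags=flags,
    )

    kg_per_mol = cfg.water_molar_mass_g / 1000.0
    tbw_kg = tbw_from_spaces(n_d_mol * kg_per_mol, n_o_mol * kg_per_mol, cfg)
    comp = body_composition(tbw_kg, weight_kg, cfg)
    qc = qc_ratios(kin, cfg)
    rco2, rco2_flags = rco2_speakman(n_mol, k_O, k_d, cfg)
    kin.flags.extend(rco2_flags)
    tdee = tdee_weir(max(rco2, 0.0), cfg.rq) if rco2 >= 0 else float("nan")

    return TwoPointResult(
        participant_id=row.participant_id, kinetics=kin, body_composition=comp,
        qc=qc, rco2_l_per_day=rco2, tdee_kcal=tdee, rq=cfg.rq,
    )
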