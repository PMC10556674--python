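"""Synthetic cohorts with the statistical structure the validation assumes.

The generator emulates a free-living validation study: adult women of
normal body weight, a seven-day metabolic period bracketed by urine
sampling, an image-based app recording every eating occasion, and a
single-day 24-hour recall.  Every quantity the estimators later recover is
laid down as explicit ground truth:

* anthropometrics from truncated normals (BMI constrained to 18.5–24.9);
* a true TDEE per participant, inverted exactly into isotope kinetics so
  the two-point engine recovers it (optional measurement noise on
  enrichments);
* true daily intake with lognormal day-to-day variation at a configured
  within-subject CV, tied to TDEE through an energy-imbalance term;
* tool-specific reporting bias as an additive participant-level shift with
  between-subject spread, applied before the day-level variation (so the
  within-CV of *reported* intake matches the configured value);
* body-weight change driven by the energy imbalance through the
  9.5 / 1.1 kcal/g energy-store coefficients, exactly invertible.

A single global seed governs all draws via named substreams per stage.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from . import cohort_io
from .cohort_io import (EatingOccasion, FoodItem, Participant, Recall24Record,
                        write_report)
from .dlw_engine import (DLWConfig, IsotopeSampleRow, dose_grams)
from .energy_goldberg import EnergyStoresConfig
from .errors import DomainError

__all__ = [
    "SimulationConfig",
    "TrueParameters",
    "SimulatedStudy",
    "simulate_cohort",
    "simulate_isotope_kinetics",
    "simulate_daily_reported",
    "simulate_reported_intake",
    "simulate_study",
    "write_study",
]

#: grams of each macronutrient per kcal of intake, matching the energy share
#: of a mixed Western diet as reported by image-based and recall tools
MACRO_PER_KCAL = {
    "app": {"carb_g": 0.11182, "sugar_g": 0.03710, "fat_g": 0.04023,
            "satfat_g": 0.01332, "protein_g": 0.03812, "fiber_g": 0.01125},
    "recall": {"carb_g": 0.10595, "sugar_g": 0.03765, "fat_g": 0.04330,
               "satfat_g": 0.01625, "protein_g": 0.04137, "fiber_g": 0.01235},
}

#: atom percent excess of the dose waters (10 atom% O-18 water over the
#: ~0.2 atom% natural abundance; 99.9 atom% deuterated water)
APE_O18 = 9.8
APE_D2 = 99.9

POST_DOSE_HOUR = 3.5       # mean of the 3 h and 4 h post-dose samples
STUDY_DAYS = 7.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulated cohort.

    Defaults are the published conditions of the validation study the
    package models: 30 adult women, anthropometric means/SDs, a TDEE
    distribution, a 42.55% within-subject intake CV, and tool-specific
    reporting-bias distributions (participant-level mean shift and
    between-subject SD, kcal/day).
    """

    n_participants: int = 30
    seed: int = 0
    age_mean: float = 28.5
    age_sd: float = 6.7
    age_bounds: tuple[float, float] = (18.0, 55.0)
    height_mean_m: float = 1.63
    height_sd_m: float = 0.07
    height_bounds_m: tuple[float, float] = (1.40, 1.90)
    weight_mean_kg: float = 57.8
    weight_sd_kg: float = 6.1
    weight_bounds_kg: tuple[float, float] = (38.0, 95.0)
    bmi_bounds: tuple[float, float] = (18.5, 24.9)
    fat_fraction_mean: float = 0.28
    fat_fraction_sd: float = 0.04
    fat_fraction_bounds: tuple[float, float] = (0.15, 0.40)
    tdee_mean: float = 2235.2
    tdee_sd: float = 456.5
    tdee_bounds: tuple[float, float] = (1200.0, 4500.0)
    within_cv: float = 42.55
    app_bias: tuple[float, float] = (-329.6, 599.1)
    recall_bias: tuple[float, float] = (-543.0, 642.6)
    energy_balance: bool = True
    imbalance_sd: float = 250.0          # kcal/day deviation of intake from TDEE
    fm_energy_share: float = 0.75        # fraction of the store change held as fat
    enrichment_noise: float = 0.0        # relative SD on simulated enrichments
    rq: float = 0.85
    smoker_rate: float = 0.10
    activity_probs: tuple[float, ...] = (0.17, 0.17, 0.53, 0.13)
    occasions_mean: float = 7.5
    occasions_sd: float = 1.9
    occasions_bounds: tuple[int, int] = (3, 9)
    recall_occasions_mean: float = 4.6
    recall_occasions_sd: float = 1.3
    leftover_rate: float = 0.2           # occasions closed with an 'after' record
    min_reported_kcal: float = 50.0      # floor on a participant's biased mean

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise DomainError("n_participants must be >= 2")
        for name in ("age_sd", "height_sd_m", "weight_sd_kg", "tdee_sd",
                     "within_cv", "imbalance_sd", "enrichment_noise"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if not (0.0 <= self.fm_energy_share <= 1.0):
            raise DomainError("fm_energy_share must be in [0, 1]")


@dataclass
class TrueParameters:
    """Ground truth for one participant, the recovery target of every estimator."""

    participant_id: str
    true_tdee: float
    true_tbw_kg: float
    true_ffm_kg: float
    true_fm_kg: float
    true_mean_intake: float
    true_daily_intake: np.ndarray     # 7 values, kcal/day
    bias_app: float                   # realized participant-level shift, kcal/day
    bias_recall: float
    within_cv: float
    weight_change_kg: float
    d_fm_kg: float
    d_ffm_kg: float
    dsr: float                        # dilution space ratio laid down for the tracers
    err: float                        # elimination rate ratio


@dataclass
class SimulatedStudy:
    participants: list[Participant]
    truths: list[TrueParameters]
    isotopes: list[IsotopeSampleRow]
    occasions: list[EatingOccasion]
    recalls: list[Recall24Record]
    config: SimulationConfig


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(name.encode()),)))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      bounds: tuple[float, float], size: int,
                      max_tries: int = 10_000) -> np.ndarray:
    if sd == 0:
        if not (bounds[0] <= mean <= bounds[1]):
            raise DomainError("degenerate truncated normal outside its bounds")
        return np.full(size, mean)
    out = np.empty(size)
    filled = 0
    for _ in range(max_tries):
        draw = rng.normal(mean, sd, size=size - filled)
        ok = draw[(draw >= bounds[0]) & (draw <= bounds[1])]
        out[filled:filled + ok.size] = ok
        filled += ok.size
        if filled == size:
            return out
    raise DomainError(
        f"truncation at {bounds} infeasible for N({mean}, {sd}²)")


def _lognormal_unit_mean(rng: np.random.Generator, cv_pct: float,
                         size: int) -> np.ndarray:
    """Lognormal multipliers with mean 1 and the given CV (percent)."""
    c = cv_pct / 100.0
    if c == 0:
        return np.ones(size)
    sigma2 = np.log1p(c * c)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[list[Participant], list[TrueParameters]]:
    """Draw the cohort's anthropometrics and ground truth; deterministic per seed."""
    rng = _substream(cfg.seed, "cohort")
    n = cfg.n_participants

    age = _truncated_normal(rng, cfg.age_mean, cfg.age_sd, cfg.age_bounds, n)
    # joint height/weight rejection until BMI lands in the inclusion window
    height = np.empty(n)
    weight = np.empty(n)
    filled = 0
    for _ in range(10_000):
        h = _truncated_normal(rng, cfg.height_mean_m, cfg.height_sd_m,
                              cfg.height_bounds_m, n - filled)
        w = _truncated_normal(rng, cfg.weight_mean_kg, cfg.weight_sd_kg,
                              cfg.weight_bounds_kg, n - filled)
        bmi = w / h**2
        ok = (bmi >= cfg.bmi_bounds[0]) & (bmi <= cfg.bmi_bounds[1])
        take = int(ok.sum())
        height[filled:filled + take] = h[ok]
        weight[filled:filled + take] = w[ok]
        filled += take
        if filled == n:
            break
    else:
        raise DomainError("BMI truncation infeasible under the configured anthropometrics")

    fat_frac = _truncated_normal(rng, cfg.fat_fraction_mean, cfg.fat_fraction_sd,
                                 cfg.fat_fraction_bounds, n)
    tdee = _truncated_normal(rng, cfg.tdee_mean, cfg.tdee_sd, cfg.tdee_bounds, n)
    smoker = rng.random(n) < cfg.smoker_rate
    probs = np.asarray(cfg.activity_probs) / np.sum(cfg.activity_probs)
    bands = rng.choice(len(cohort_io.ACTIVITY_BANDS), size=n, p=probs)
    bias_app = rng.normal(cfg.app_bias[0], cfg.app_bias[1], n)
    bias_recall = rng.normal(cfg.recall_bias[0], cfg.recall_bias[1], n)
    imbalance = (rng.normal(0.0, cfg.imbalance_sd, n)
                 if cfg.energy_balance else np.zeros(n))
    dsr = rng.uniform(1.005, 1.035, n)
    err = rng.uniform(1.193, 1.366, n)
    day_mult = _lognormal_unit_mean(rng, cfg.within_cv, n * int(STUDY_DAYS)
                                    ).reshape(n, int(STUDY_DAYS))

    es_cfg = EnergyStoresConfig()
    participants: list[Participant] = []
    truths: list[TrueParameters] = []
    for i in range(n):
        pid = f"P{i + 1:02d}"
        ffm = (1.0 - fat_frac[i]) * weight[i]
        fm = fat_frac[i] * weight[i]
        tbw = 0.732 * ffm
        mean_intake = tdee[i] + imbalance[i]
        daily = mean_intake * day_mult[i]
        if cfg.energy_balance:
            # energy imbalance realized as body-store change over the week
            es_daily = float(np.mean(daily)) - tdee[i]
            total_kcal = es_daily * STUDY_DAYS
            d_fm_g = total_kcal * cfg.fm_energy_share / es_cfg.kcal_per_g_fm
            d_ffm_g = total_kcal * (1.0 - cfg.fm_energy_share) / es_cfg.kcal_per_g_ffm
        else:
            # stable-weight idealization: stores untouched by day-to-day noise
            d_fm_g = d_ffm_g = 0.0
        dw = (d_fm_g + d_ffm_g) / 1000.0
        participants.append(Participant(
            id=pid, sex="female", age_y=float(age[i]),
            height_cm=float(height[i] * 100.0),
            weight_start_kg=float(weight[i]),
            weight_end_kg=float(weight[i] + dw),
            smoker=bool(smoker[i]),
            activity_band=cohort_io.ACTIVITY_BANDS[bands[i]],
        ))
        truths.append(TrueParameters(
            participant_id=pid, true_tdee=float(tdee[i]), true_tbw_kg=float(tbw),
            true_ffm_kg=float(ffm), true_fm_kg=float(fm),
            true_mean_intake=float(mean_intake), true_daily_intake=daily,
            bias_app=float(bias_app[i]), bias_recall=float(bias_recall[i]),
            within_cv=cfg.within_cv, weight_change_kg=float(dw),
            d_fm_kg=float(d_fm_g / 1000.0), d_ffm_kg=float(d_ffm_g / 1000.0),
            dsr=float(dsr[i]), err=float(err[i]),
        ))
    return participants, truths


def simulate_isotope_kinetics(
    truth: TrueParameters, cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    dlw: DLWConfig | None = None,
) -> IsotopeSampleRow:
    """Invert the two-point chain: enrichments that reproduce the true TDEE.

    The laid-down dilution-space ratio fixes the two tracer spaces around
    the true TBW, the elimination-rate ratio fixes the split of the rate
    difference implied by the true CO2 production, and the plateau/final
    enrichments follow from dose and spaces.  With zero noise the engine
    recovers the truth exactly.
    """
    rng = rng or _substream(cfg.seed, f"isotope:{truth.participant_id}")
    dlw = dlw or DLWConfig(rq=cfg.rq)

    tbw = truth.true_tbw_kg
    r = truth.dsr
    n_o_kg = 2.0 * tbw / (1.0 / dlw.tbw_divisor_o18 + r / dlw.tbw_divisor_d2)
    n_d_kg = r * n_o_kg
    mol_per_kg = 1000.0 / dlw.water_molar_mass_g
    n_o_mol = n_o_kg * mol_per_kg
    n_d_mol = n_d_kg * mol_per_kg
    n_mol = (n_o_mol + n_d_mol) / 2.0

    rco2 = truth.true_tdee / (1.106 + 3.94 / dlw.rq)
    rate_diff = rco2 / (dlw.speakman_coeff * n_mol * dlw.litres_per_mol_co2)
    e = truth.err
    denom = dlw.o_weight * e - dlw.d_weight
    if denom <= 0:
        raise DomainError(f"elimination rate ratio {e} makes the kinetics degenerate")
    k_d = rate_diff / denom
    k_o = e * k_d

    dose_o_g, dose_d_g = dose_grams(tbw)
    e_post_o = (dose_o_g / dlw.water_molar_mass_g) * APE_O18 * 1e4 / n_o_mol
    e_post_d = (dose_d_g / dlw.water_molar_mass_g) * APE_D2 * 1e4 / n_d_mol
    e_final_o = e_post_o * np.exp(-k_o * STUDY_DAYS)
    e_final_d = e_post_d * np.exp(-k_d * STUDY_DAYS)

    if cfg.enrichment_noise > 0:
        noise = rng.normal(1.0, cfg.enrichment_noise, size=4)
        e_post_o *= noise[0]
        e_final_o *= noise[1]
        e_post_d *= noise[2]
        e_final_d *= noise[3]

    return IsotopeSampleRow(
        participant_id=truth.participant_id,
        dose_o18_g=dose_o_g, dose_d2_g=dose_d_g,
        ape_o18=APE_O18, ape_d2=APE_D2,
        E_pre_o18=0.0, E_post_o18=float(e_post_o), E_final_o18=float(e_final_o),
        E_pre_d2=0.0, E_post_d2=float(e_post_d), E_final_d2=float(e_final_d),
        t_post_h=POST_DOSE_HOUR, t_final_h=POST_DOSE_HOUR + STUDY_DAYS * 24.0,
    )


def simulate_daily_reported(
    truth: TrueParameters, cfg: SimulationConfig,
    tool: Literal["app", "recall"],
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Reported daily energy (kcal): biased participant mean × day variation.

    The participant-level bias shifts the mean; lognormal day multipliers at
    the configured within-CV act on the shifted mean, so the CV of reported
    days matches the configured value.  The app reports 7 days, the recall
    one.  A biased mean below the floor is clamped (a participant cannot
    report negative intake).
    """
    rng = rng or _substream(cfg.seed, f"intake:{tool}:{truth.participant_id}")
    bias = truth.bias_app if tool == "app" else truth.bias_recall
    mean = max(cfg.min_reported_kcal, truth.true_mean_intake + bias)
    n_days = int(STUDY_DAYS) if tool == "app" else 1
    return mean * _lognormal_unit_mean(rng, cfg.within_cv, n_days)


def _split_occasions(rng: np.random.Generator, day_kcal: float, n_occ: int) -> np.ndarray:
    shares = rng.dirichlet(np.full(n_occ, 4.0))
    return day_kcal * shares


def _items_for(energy: float, tool: str, name: str) -> list[FoodItem]:
    macros = {k: v * energy for k, v in MACRO_PER_KCAL[tool].items()}
    return [FoodItem(name=name, energy_kcal=energy, **macros)]


def simulate_reported_intake(
    truth: TrueParameters, cfg: SimulationConfig,
    tool: Literal["app", "recall"],
    rng: np.random.Generator | None = None,
):
    """Tool-level records: app eating-occasion images or a single-day recall.

    App days are split into 3–9 occasions; a configurable fraction of
    occasions is closed by an 'after' image with leftovers (the rest by
    'ate_everything'), so the paired before/after energies sum back to the
    reported day exactly.  Returns ``list[EatingOccasion]`` for the app or a
    ``Recall24Record`` for the recall.
    """
    rng = rng or _substream(cfg.seed, f"intake:{tool}:{truth.participant_id}")
    daily = simulate_daily_reported(truth, cfg, tool, rng)

    if tool == "recall":
        kcal = float(daily[0])
        n_occ = int(np.clip(round(rng.normal(cfg.recall_occasions_mean,
                                             cfg.recall_occasions_sd)), 1, 12))
        macros = {k: v * kcal for k, v in MACRO_PER_KCAL["recall"].items()}
        return Recall24Record(participant_id=truth.participant_id,
                              tdei_kcal=kcal, eating_occasions=n_occ, **macros)

    records: list[EatingOccasion] = []
    lo, hi = cfg.occasions_bounds
    for day, kcal in enumerate(daily, start=1):
        n_occ = int(np.clip(round(rng.normal(cfg.occasions_mean, cfg.occasions_sd)),
                            lo, hi))
        energies = _split_occasions(rng, float(kcal), n_occ)
        hours = np.linspace(8.0, 20.0, n_occ)
        for j, consumed in enumerate(energies):
            hh = int(hours[j])
            mm = int(round((hours[j] - hh) * 60))
            stamp = f"2024-03-{day:02d}T{hh:02d}:{mm:02d}:00"
            close_stamp = f"2024-03-{day:02d}T{hh:02d}:{mm + 1 if mm < 59 else mm:02d}:30"
            if rng.random() < cfg.leftover_rate and consumed > 0:
                leftover_frac = rng.uniform(0.05, 0.30)
                before = consumed / (1.0 - leftover_frac)
                after = before - consumed
                records.append(EatingOccasion(
                    participant_id=truth.participant_id, day_index=day,
                    timestamp=stamp, label="before",
                    items=_items_for(float(before), "app", f"meal_d{day}o{j + 1}")))
                records.append(EatingOccasion(
                    participant_id=truth.participant_id, day_index=day,
                    timestamp=close_stamp, label="after",
                    items=_items_for(float(after), "app", f"meal_d{day}o{j + 1}_left")))
            else:
                records.append(EatingOccasion(
                    participant_id=truth.participant_id, day_index=day,
                    timestamp=stamp, label="before",
                    items=_items_for(float(consumed), "app", f"meal_d{day}o{j + 1}")))
                records.append(EatingOccasion(
                    participant_id=truth.participant_id, day_index=day,
                    timestamp=close_stamp, label="ate_everything", items=[]))
    return records


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Full synthetic study: cohort, isotope table, app occasions, recalls."""
    participants, truths = simulate_cohort(cfg)
    isotopes = [simulate_isotope_kinetics(t, cfg) for t in truths]
    occasions: list[EatingOccasion] = []
    for t in truths:
        occasions.extend(simulate_reported_intake(t, cfg, "app"))
    recalls = [simulate_reported_intake(t, cfg, "recall") for t in truths]
    return SimulatedStudy(participants=participants, truths=truths,
                          isotopes=isotopes, occasions=occasions,
                          recalls=recalls, config=cfg)


def write_study(study: SimulatedStudy, out_dir: str | Path) -> None:
    """Write participants.csv, isotopes.csv, occasions.csv, recall24.csv, truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_io.write_participants(study.participants, out / "participants.csv")
    cohort_io.write_isotopes(study.isotopes, out / "isotopes.csv")
    cohort_io.write_occasions(study.occasions, out / "occasions.csv")
    cohort_io.write_recalls(study.recalls, out / "recall24.csv")
    truth_doc = {
        t.participant_id: {
            "true_tdee": t.true_tdee, "true_tbw_kg": t.true_tbw_kg,
            "true_ffm_kg": t.true_ffm_kg, "true_fm_kg": t.true_fm_kg,
            "true_mean_intake": t.true_mean_intake,
            "true_daily_intake": list(map(float, t.true_daily_intake)),
            "bias_app": t.bias_app, "bias_recall": t.bias_recall,
            "within_cv": t.within_cv, "weight_change_kg": t.weight_change_kg,
            "d_fm_kg": t.d_fm_kg, "d_ffm_kg": t.d_ffm_kg,
            "dsr": t.dsr, "err": t.err,
        } for t in study.truths
    }
    write_report(truth_doc, out / "truth.json")
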