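"""Daily intake aggregation and within-subject variation.

Eating-occasion image records ('before' / 'after' / 'ate_everything') are
paired into occasions, consumed energy is the before total minus any
leftover total, and participant-days are summed into daily intakes.  The
day-to-day stability of intake is summarised by per-participant
coefficients of variation (CV_i = 100·SD/mean) pooled across the cohort as
a root mean square, the quantity the Goldberg S factor consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import MACRO_FIELDS, EatingOccasion, Recall24Record
from .errors import DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "DailyIntake",
    "IntakeSeries",
    "aggregate_daily",
    "build_series",
    "within_subject_cv",
    "pooled_cv",
    "tool_summary",
]


@dataclass
class DailyIntake:
    participant_id: str
    day_index: int
    tdei_kcal: float
    carb_g: float = 0.0
    sugar_g: float = 0.0
    fat_g: float = 0.0
    satfat_g: float = 0.0
    protein_g: float = 0.0
    fiber_g: float = 0.0
    occasions_n: int = 0


@dataclass
class IntakeSeries:
    """One participant's per-day intakes with summary statistics."""

    participant_id: str
    days: list[DailyIntake]
    include_zero_days: bool = True

    @property
    def daily_tdei(self) -> np.ndarray:
        values = [d.tdei_kcal for d in self.days
                  if self.include_zero_days or d.tdei_kcal > 0]
        return np.asarray(values, dtype=float)

    @property
    def mean_tdei(self) -> float:
        v = self.daily_tdei
        if v.size == 0:
            raise DomainError(f"participant {self.participant_id}: no usable days")
        return float(np.mean(v))

    @property
    def cv_i(self) -> float:
        return within_subject_cv(self.daily_tdei)

    def macro_mean(self, name: str) -> float:
        return float(np.mean([getattr(d, name) for d in self.days]))

    @property
    def occasions_per_day(self) -> float:
        return float(np.mean([d.occasions_n for d in self.days]))


def aggregate_daily(
    occasions: Iterable[EatingOccasion],
    fill_days: Sequence[int] = range(1, 8),
) -> list[DailyIntake]:
    """Pair image records into occasions and sum them into participant-days.

    Consumed energy per occasion = before total − after total ('ate_everything'
    closes with zero leftovers); a negative consumed energy is floored at 0
    and logged.  Closing records are matched to the most recent open 'before'
    of the same participant-day; unmatched closers are ignored with a log
    entry.  ``occasions_n`` counts distinct occasions, not items.  Days in
    ``fill_days`` with no recorded occasion appear with zero intake.
    """
    records = sorted(occasions,
                     key=lambda r: (r.participant_id, r.day_index, r.timestamp))
    fields = ("energy_kcal",) + MACRO_FIELDS
    totals: dict[tuple[str, int], dict] = {}
    open_stack: dict[tuple[str, int], list[EatingOccasion]] = {}
    participants: list[str] = []

    def day_bucket(key: tuple[str, int]) -> dict:
        if key not in totals:
            totals[key] = {f: 0.0 for f in fields}
            totals[key]["occasions_n"] = 0
        return totals[key]

    def close(before: EatingOccasion, after: EatingOccasion | None) -> None:
        key = (before.participant_id, before.day_index)
        bucket = day_bucket(key)
        bucket["occasions_n"] += 1
        for f in fields:
            b = before.energy_kcal if f == "energy_kcal" else before.macro_total(f)
            a = 0.0
            if after is not None and after.label == "after":
                a = after.energy_kcal if f == "energy_kcal" else after.macro_total(f)
            consumed = b - a
            if consumed < 0:
                logger.warning(
                    "participant %s day %d: leftover %s exceeds the before "
                    "record (%.1f > %.1f); consumed floored at 0",
                    before.participant_id, before.day_index, f, a, b)
                consumed = 0.0
            bucket[f] += consumed

    for rec in records:
        if rec.participant_id not in participants:
            participants.append(rec.participant_id)
        key = (rec.participant_id, rec.day_index)
        if rec.label == "before":
            open_stack.setdefault(key, []).append(rec)
        else:
            stack = open_stack.get(key, [])
            if stack:
                close(stack.pop(), rec if rec.label == "after" else None)
            else:
                logger.warning(
                    "participant %s day %d: %r record without a preceding "
                    "'before'; ignored in aggregation",
                    rec.participant_id, rec.day_index, rec.label)
    # 'before' records never closed: treat as fully consumed, log
    for key, stack in open_stack.items():
        for before in stack:
            logger.warning(
                "participant %s day %d: 'before' record at %s never closed; "
                "counted as fully consumed", key[0], key[1], before.timestamp)
            close(before, None)

    out: list[DailyIntake] = []
    for pid in participants:
        for day in fill_days:
            bucket = totals.get((pid, day), {f: 0.0 for f in fields} | {"occasions_n": 0})
            out.append(DailyIntake(
                participant_id=pid, day_index=day,
                tdei_kcal=bucket["energy_kcal"],
                occasions_n=bucket["occasions_n"],
                **{f: bucket[f] for f in MACRO_FIELDS},
            ))
    return out


def build_series(
    daily: Iterable[DailyIntake], include_zero_days: bool = True
) -> dict[str, IntakeSeries]:
    """Group daily intakes into per-participant series (insertion order kept)."""
    grouped: dict[str, list[DailyIntake]] = {}
    for d in daily:
        grouped.setdefault(d.participant_id, []).append(d)
    return {
        pid: IntakeSeries(pid, sorted(days, key=lambda d: d.day_index),
                          include_zero_days=include_zero_days)
        for pid, days in grouped.items()
    }


def within_subject_cv(series: Sequence[float]) -> float:
    """Per-participant CV: 100 · sample SD / mean, percent."""
    v = np.asarray(series, dtype=float)
    if v.size < 2:
        raise DomainError(f"CV needs at least 2 days, got {v.size}")
    mean = float(np.mean(v))
    if mean <= 0:
        raise DomainError("CV undefined for non-positive mean intake")
    return 100.0 * float(np.std(v, ddof=1)) / mean


def pooled_cv(cv_list: Sequence[float]) -> float:
    """Cohort within-subject CV: root mean square of the individual CVs."""
    v = np.asarray(cv_list, dtype=float)
    if v.size == 0:
        raise DomainError("pooled CV of an empty list is undefined")
    if not np.all(np.isfinite(v)):
        raise DomainError("pooled CV requires finite individual CVs")
    return float(np.sqrt(np.mean(v**2)))


def tool_summary(
    series_by_participant: Mapping[str, IntakeSeries],
    recall_records: Iterable[Recall24Record],
) -> pd.DataFrame:
    """Per-participant paired summary of the app and the single-day recall.

    Columns: mean app TDEI and macronutrients, recall TDEI and macronutrients,
    eating occasions per day for both tools, and the app−recall TDEI
    difference.  Participants missing from either source are excluded with a
    log entry.
    """
    recalls = {r.participant_id: r for r in recall_records}
    common = [pid for pid in series_by_participant if pid in recalls]
    skipped = (set(series_by_participant) | set(recalls)) - set(common)
    for pid in sorted(skipped):
        logger.warning("participant %s missing from one source; excluded "
                       "from the paired summary", pid)
    if skipped:
        logger.warning("%d participant(s) excluded from the paired summary",
                       len(skipped))
    if not common:
        raise DomainError("no participant present in both intake sources")

    rows = []
    for pid in common:
        s = series_by_participant[pid]
        r = recalls[pid]
        row = {"participant_id": pid,
               "app_tdei_kcal": s.mean_tdei,
               "recall_tdei_kcal": r.tdei_kcal,
               "tdei_diff_kcal": s.mean_tdei - r.tdei_kcal,
               "app_occasions_per_day": s.occasions_per_day,
               "recall_occasions_per_day": float(r.eating_occasions)}
        for f in MACRO_FIELDS:
            row[f"app_{f}"] = s.macro_mean(f)
            row[f"recall_{f}"] = getattr(r, f)
        rows.append(row)
    return pd.DataFrame(rows).set_index("participant_id")
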