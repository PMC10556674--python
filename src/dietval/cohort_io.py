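"""Domain types, CSV schemas, config loading, and report serialization.

CSV dialect throughout: comma-separated, UTF-8, '.' decimal, ISO-8601
timestamps.  The energy unit of record is kcal; kJ is derived as
kcal × 4.184.  Readers never drop rows silently: flagged rows are counted
and logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import pandas as pd
import yaml

from .dlw_engine import DLWConfig, IsotopeSampleRow
from .energy_goldberg import GoldbergConfig
from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

KCAL_TO_KJ = 4.184

MACRO_FIELDS = ("carb_g", "sugar_g", "fat_g", "satfat_g", "protein_g", "fiber_g")

ACTIVITY_BANDS = ("none", "1-2 h/wk", "2-6 h/wk", ">6 h/wk")
OCCASION_LABELS = ("before", "after", "ate_everything")


@dataclass
class Participant:
    """One study participant; the unit of analysis."""

    id: str
    sex: str
    age_y: float
    height_cm: float
    weight_start_kg: float
    weight_end_kg: float
    smoker: bool
    activity_band: str

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValidationError(f"participant {self.id}: unknown sex {self.sex!r}")
        for name in ("age_y", "height_cm", "weight_start_kg", "weight_end_kg"):
            if getattr(self, name) <= 0:
                raise ValidationError(
                    f"participant {self.id}: {name} must be strictly positive")
        if self.activity_band not in ACTIVITY_BANDS:
            raise ValidationError(
                f"participant {self.id}: unknown activity band "
                f"{self.activity_band!r}; expected one of {ACTIVITY_BANDS}")

    @property
    def weight_change_kg(self) -> float:
        return self.weight_end_kg - self.weight_start_kg

    @property
    def bmi(self) -> float:
        h_m = self.height_cm / 100.0
        return self.weight_start_kg / h_m**2


@dataclass
class FoodItem:
    name: str
    energy_kcal: float
    carb_g: float = 0.0
    sugar_g: float = 0.0
    fat_g: float = 0.0
    satfat_g: float = 0.0
    protein_g: float = 0.0
    fiber_g: float = 0.0

    def __post_init__(self) -> None:
        for f in ("energy_kcal",) + MACRO_FIELDS:
            if getattr(self, f) < 0:
                raise ValidationError(f"item {self.name!r}: {f} must be non-negative")


@dataclass
class EatingOccasion:
    """One image record: the 'before' snapshot of an eating occasion, or the
    closing 'after' / 'ate_everything' snapshot."""

    participant_id: str
    day_index: int
    timestamp: str
    label: str
    items: list[FoodItem] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in OCCASION_LABELS:
            raise ValidationError(
                f"unknown occasion label {self.label!r}; expected one of {OCCASION_LABELS}")
        if not (1 <= int(self.day_index) <= 7):
            raise ValidationError(f"day_index must be in 1..7, got {self.day_index}")

    @property
    def energy_kcal(self) -> float:
        return sum(i.energy_kcal for i in self.items)

    def macro_total(self, name: str) -> float:
        return sum(getattr(i, name) for i in self.items)


@dataclass
class Recall24Record:
    """Single-day 24-hour-recall totals for one participant."""

    participant_id: str
    tdei_kcal: float
    carb_g: float
    sugar_g: float
    fat_g: float
    satfat_g: float
    protein_g: float
    fiber_g: float
    eating_occasions: int

    def __post_init__(self) -> None:
        if self.tdei_kcal < 0:
            raise ValidationError("tdei_kcal must be non-negative")
        if self.eating_occasions < 0:
            raise ValidationError("eating_occasions must be non-negative")


@dataclass
class StudyConfig:
    """Analysis-wide knobs; nested configs own the DLW and Goldberg constants."""

    kcal_to_kj: float = KCAL_TO_KJ
    rq: float = 0.85
    goldberg: GoldbergConfig = field(default_factory=GoldbergConfig)
    dlw: DLWConfig = field(default_factory=DLWConfig)
    bonferroni_factor: int = 3
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kcal_to_kj <= 0 or self.bonferroni_factor <= 0:
            raise ValidationError("factors must be strictly positive")
        if not (0 < self.alpha < 1):
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        if not (0.67 < self.rq <= 1.3):
            raise ValidationError(f"rq must be in (0.67, 1.3], got {self.rq}")
        # keep the Weir RQ and the DLW engine's RQ in lockstep
        if self.dlw.rq != self.rq:
            object.__setattr__(self, "dlw", dataclasses.replace(self.dlw, rq=self.rq))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "StudyConfig":
        kwargs = dict(raw)
        if "goldberg" in kwargs and isinstance(kwargs["goldberg"], dict):
            kwargs["goldberg"] = GoldbergConfig(**kwargs["goldberg"])
        if "dlw" in kwargs and isinstance(kwargs["dlw"], dict):
            kwargs["dlw"] = DLWConfig(**kwargs["dlw"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# CSV schemas

PARTICIPANT_COLUMNS = [
    "id", "sex", "age_y", "height_cm", "weight_start_kg", "weight_end_kg",
    "smoker", "activity_band",
]
OCCASION_COLUMNS = [
    "participant_id", "day", "timestamp", "label", "item_name", "energy_kcal",
    "carb_g", "sugar_g", "fat_g", "satfat_g", "protein_g", "fiber_g",
]
RECALL_COLUMNS = [
    "participant_id", "tdei_kcal", "carb_g", "sugar_g", "fat_g", "satfat_g",
    "protein_g", "fiber_g", "occasions_n",
]
ISOTOPE_COLUMNS = [
    "participant_id", "dose_o18_g", "dose_d2_g", "ape_o18", "ape_d2",
    "E_pre_o18", "E_post_o18", "E_final_o18", "E_pre_d2", "E_post_d2",
    "E_final_d2", "t_post_h", "t_final_h",
]


def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _num(value: str, column: str, row: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(
            f"row {row}: cannot parse {column}={value!r} as a number") from None


def _bool(value: str, column: str, row: int) -> bool:
    v = value.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise ParseError(f"row {row}: cannot parse {column}={value!r} as a boolean")


def read_participants(path: str | Path) -> list[Participant]:
    """Read participants.csv; one Participant per row, row order preserved."""
    df = _read_csv(path, PARTICIPANT_COLUMNS)
    out = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        out.append(Participant(
            id=str(rec["id"]),
            sex=str(rec["sex"]),
            age_y=_num(rec["age_y"], "age_y", i),
            height_cm=_num(rec["height_cm"], "height_cm", i),
            weight_start_kg=_num(rec["weight_start_kg"], "weight_start_kg", i),
            weight_end_kg=_num(rec["weight_end_kg"], "weight_end_kg", i),
            smoker=_bool(rec["smoker"], "smoker", i),
            activity_band=str(rec["activity_band"]),
        ))
    return out


def read_occasions(path: str | Path) -> list[EatingOccasion]:
    """Read occasions.csv into image records grouped by (participant, day, timestamp).

    Rows sharing participant, day, timestamp and label form one record with
    several food items.  'after' records with no preceding 'before' on the
    same day are kept but logged (pairing happens at aggregation time).
    """
    df = _read_csv(path, OCCASION_COLUMNS)
    records: dict[tuple, EatingOccasion] = {}
    for i, rec in enumerate(df.to_dict("records"), start=1):
        key = (str(rec["participant_id"]), int(_num(rec["day"], "day", i)),
               str(rec["timestamp"]), str(rec["label"]))
        if key not in records:
            records[key] = EatingOccasion(
                participant_id=key[0], day_index=key[1],
                timestamp=key[2], label=key[3])
        if str(rec["item_name"]).strip():
            records[key].items.append(FoodItem(
                name=str(rec["item_name"]),
                energy_kcal=_num(rec["energy_kcal"], "energy_kcal", i),
                carb_g=_num(rec["carb_g"], "carb_g", i),
                sugar_g=_num(rec["sugar_g"], "sugar_g", i),
                fat_g=_num(rec["fat_g"], "fat_g", i),
                satfat_g=_num(rec["satfat_g"], "satfat_g", i),
                protein_g=_num(rec["protein_g"], "protein_g", i),
                fiber_g=_num(rec["fiber_g"], "fiber_g", i),
            ))
    out = sorted(records.values(),
                 key=lambda r: (r.participant_id, r.day_index, r.timestamp))
    _warn_unmatched_after(out)
    return out


def _warn_unmatched_after(records: list[EatingOccasion]) -> int:
    """Count closing records with no open 'before' on the same participant-day."""
    unmatched = 0
    open_count: dict[tuple, int] = {}
    for rec in records:
        key = (rec.participant_id, rec.day_index)
        if rec.label == "before":
            open_count[key] = open_count.get(key, 0) + 1
        else:
            if open_count.get(key, 0) > 0:
                open_count[key] -= 1
            else:
                unmatched += 1
                logger.warning(
                    "unmatched %r record for participant %s day %d at %s (kept)",
                    rec.label, rec.participant_id, rec.day_index, rec.timestamp)
    return unmatched


def read_recalls(path: str | Path) -> list[Recall24Record]:
    df = _read_csv(path, RECALL_COLUMNS)
    out = []
    seen: set[str] = set()
    for i, rec in enumerate(df.to_dict("records"), start=1):
        pid = str(rec["participant_id"])
        if pid in seen:
            raise ValidationError(
                f"row {i}: duplicate 24HR record for participant {pid} "
                "(one record per participant expected)")
        seen.add(pid)
        out.append(Recall24Record(
            participant_id=pid,
            tdei_kcal=_num(rec["tdei_kcal"], "tdei_kcal", i),
            carb_g=_num(rec["carb_g"], "carb_g", i),
            sugar_g=_num(rec["sugar_g"], "sugar_g", i),
            fat_g=_num(rec["fat_g"], "fat_g", i),
            satfat_g=_num(rec["satfat_g"], "satfat_g", i),
            protein_g=_num(rec["protein_g"], "protein_g", i),
            fiber_g=_num(rec["fiber_g"], "fiber_g", i),
            eating_occasions=int(_num(rec["occasions_n"], "occasions_n", i)),
        ))
    return out


def read_isotopes(path: str | Path) -> list[IsotopeSampleRow]:
    df = _read_csv(path, ISOTOPE_COLUMNS)
    out = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        kwargs = {c: _num(rec[c], c, i) for c in ISOTOPE_COLUMNS[1:]}
        out.append(IsotopeSampleRow(participant_id=str(rec["participant_id"]), **kwargs))
    return out


# ---------------------------------------------------------------------------
# CSV writers (round-trip companions of the readers)

def write_participants(participants: Iterable[Participant], path: str | Path) -> None:
    rows = [{
        "id": p.id, "sex": p.sex, "age_y": p.age_y, "height_cm": p.height_cm,
        "weight_start_kg": p.weight_start_kg, "weight_end_kg": p.weight_end_kg,
        "smoker": p.smoker, "activity_band": p.activity_band,
    } for p in participants]
    pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS).to_csv(path, index=False)


def write_occasions(records: Iterable[EatingOccasion], path: str | Path) -> None:
    rows = []
    for rec in records:
        items = rec.items or [FoodItem(name="", energy_kcal=0.0)]
        for item in items:
            rows.append({
                "participant_id": rec.participant_id, "day": rec.day_index,
                "timestamp": rec.timestamp, "label": rec.label,
                "item_name": item.name, "energy_kcal": item.energy_kcal,
                "carb_g": item.carb_g, "sugar_g": item.sugar_g,
                "fat_g": item.fat_g, "satfat_g": item.satfat_g,
                "protein_g": item.protein_g, "fiber_g": item.fiber_g,
            })
    pd.DataFrame(rows, columns=OCCASION_COLUMNS).to_csv(path, index=False)


def write_recalls(records: Iterable[Recall24Record], path: str | Path) -> None:
    rows = [{
        "participant_id": r.participant_id, "tdei_kcal": r.tdei_kcal,
        "carb_g": r.carb_g, "sugar_g": r.sugar_g, "fat_g": r.fat_g,
        "satfat_g": r.satfat_g, "protein_g": r.protein_g, "fiber_g": r.fiber_g,
        "occasions_n": r.eating_occasions,
    } for r in records]
    pd.DataFrame(rows, columns=RECALL_COLUMNS).to_csv(path, index=False)


def write_isotopes(rows_in: Iterable[IsotopeSampleRow], path: str | Path) -> None:
    rows = [{c: getattr(r, "participant_id" if c == "participant_id" else c)
             for c in ISOTOPE_COLUMNS} for r in rows_in]
    pd.DataFrame(rows, columns=ISOTOPE_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Report serialization

def _jsonable(obj: Any, warnings: list[str], crumb: str = "") -> Any:
    """Recursively convert to JSON-safe values; NaN/inf become null with a warning."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name), warnings, f"{crumb}.{f.name}")
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v, warnings, f"{crumb}.{k}") for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v, warnings, f"{crumb}[{i}]") for i, v in enumerate(obj)]
    if isinstance(obj, (bool, str)) or obj is None:
        return obj
    if isinstance(obj, (int, float)) or hasattr(obj, "item"):
        v = obj.item() if hasattr(obj, "item") else obj
        if isinstance(v, float) and not math.isfinite(v):
            warnings.append(crumb or "<root>")
            return None
        return v
    return str(obj)


def report_to_jsonable(report: Any) -> dict[str, Any]:
    warnings: list[str] = []
    doc = _jsonable(report, warnings)
    for crumb in warnings:
        logger.warning("non-finite value at %s serialized as null", crumb)
    return doc


def write_report(report: Any, path: str | Path) -> None:
    """Serialize a report (dataclass or dict) to deterministic JSON.

    Two writes of the same report are byte-identical; numeric fields
    round-trip exactly through ``json.loads``.
    """
    doc = report_to_jsonable(report)
    text = json.dumps(doc, indent=2, sort_keys=True, allow_nan=False)
    Path(path).write_text(text + "\n", encoding="utf-8")


def read_report(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text(encoding="utf-8"))
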