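"""Instrument data model and table I/O.

An :class:`Instrument` is a set of criteria, each with ordered levels
(worst first) and per-level points.  Two level semantics exist:

* ``single_select`` -- the patient sits at exactly one level (e.g. a BMI
  band) and scores that level's points;
* ``additive_subscore`` -- every applicable level contributes its points
  (the comorbidity criterion: each condition present adds its points, up
  to the criterion maximum).

Patient and follow-up records are read from plain CSV with a documented
column dialect (see :data:`PATIENT_COLUMNS`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import ValidationError

logger = logging.getLogger(__name__)

SINGLE_SELECT = "single_select"
ADDITIVE_SUBSCORE = "additive_subscore"

#: Canonical comorbidity identifiers, worst-impact first (matching the
#: ordered levels of the canonical comorbidity criterion).
COMORBIDITIES = (
    "hypertension",
    "dyslipidaemia",
    "nash",
    "albuminuria",
    "joint_pain",
    "reproductive_issues",
    "renal_impairment",
    "osa",
)

#: CSV column -> comorbidity identifier.
COMORBIDITY_COLUMNS = {
    "co_htn": "hypertension",
    "co_dyslip": "dyslipidaemia",
    "co_nash": "nash",
    "co_albuminuria": "albuminuria",
    "co_joint": "joint_pain",
    "co_repro": "reproductive_issues",
    "co_renal": "renal_impairment",
    "co_osa": "osa",
}

PATIENT_COLUMNS = (
    "patient_id",
    "age_years",
    "sex",
    "weight_kg",
    "height_m",
    "bmi",
    "hba1c_pct",
    "on_treatment",
    "diabetes_duration_years",
    "on_insulin",
    "on_oral_meds",
    *COMORBIDITY_COLUMNS,
    "pe_risk",
    "asa_class",
)

#: Columns that must be present in a patient table.  ``weight_kg`` /
#: ``height_m`` / ``bmi`` are conditionally required (one of bmi or the
#: weight+height pair), so they are not listed here.
REQUIRED_PATIENT_COLUMNS = (
    "patient_id",
    "age_years",
    "sex",
    "hba1c_pct",
    "on_treatment",
    "diabetes_duration_years",
    "on_insulin",
    "on_oral_meds",
    "pe_risk",
    "asa_class",
)

FOLLOWUP_COLUMNS = (
    "weight_kg_12m",
    "hba1c_pct_12m",
    "on_insulin_12m",
    "on_oral_meds_12m",
    "aqol_pre",
    "aqol_12m",
    "ae_list",
)


@dataclass(frozen=True)
class CriterionSpec:
    """One scoring attribute with ordered levels, worst first."""

    name: str
    levels: tuple[str, ...]
    mode: str
    level_points: Mapping[str, float]

    def __post_init__(self):
        if self.mode not in (SINGLE_SELECT, ADDITIVE_SUBSCORE):
            raise ValidationError(
                f"criterion {self.name!r}: unknown mode {self.mode!r}"
            )
        object.__setattr__(self, "levels", tuple(self.levels))
        object.__setattr__(self, "level_points", dict(self.level_points))
        if len(self.levels) < 2:
            raise ValidationError(
                f"criterion {self.name!r}: needs at least 2 levels, got "
                f"{len(self.levels)}"
            )
        if len(set(self.levels)) != len(self.levels):
            raise ValidationError(
                f"criterion {self.name!r}: duplicate level labels"
            )
        missing = [lv for lv in self.levels if lv not in self.level_points]
        if missing:
            raise ValidationError(
                f"criterion {self.name!r}: no points for levels {missing}"
            )
        pts = [float(self.level_points[lv]) for lv in self.levels]
        if any(p < 0 for p in pts):
            raise ValidationError(
                f"criterion {self.name!r}: negative level points"
            )
        if pts[0] != 0:
            raise ValidationError(
                f"criterion {self.name!r}: worst level must carry 0 points"
            )
        if self.mode == SINGLE_SELECT and any(
            b < a for a, b in zip(pts, pts[1:])
        ):
            raise ValidationError(
                f"criterion {self.name!r}: single_select points must be "
                f"non-decreasing along the level order"
            )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def points(self, level: str) -> float:
        return float(self.level_points[level])

    @property
    def maximum(self) -> float:
        """Maximum achievable points on this criterion."""
        pts = [float(self.level_points[lv]) for lv in self.levels]
        if self.mode == ADDITIVE_SUBSCORE:
            return float(sum(pts))
        return float(max(pts))


@dataclass(frozen=True)
class Instrument:
    """An ordered collection of criteria forming a points instrument."""

    name: str
    criteria: tuple[CriterionSpec, ...]

    def __post_init__(self):
        object.__setattr__(self, "criteria", tuple(self.criteria))
        names = [c.name for c in self.criteria]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate criterion names")
        if not self.criteria:
            raise ValidationError("instrument needs at least one criterion")

    @property
    def criterion_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.criteria)

    @property
    def criterion_maxima(self) -> dict[str, float]:
        return {c.name: c.maximum for c in self.criteria}

    @property
    def level_counts(self) -> tuple[int, ...]:
        return tuple(c.n_levels for c in self.criteria)

    def criterion(self, name: str) -> CriterionSpec:
        for c in self.criteria:
            if c.name == name:
                return c
        raise KeyError(name)

    def index(self, name: str) -> int:
        for i, c in enumerate(self.criteria):
            if c.name == name:
                return i
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "criteria": [
                {
                    "name": c.name,
                    "mode": c.mode,
                    "levels": [
                        {"label": lv, "points": float(c.level_points[lv])}
                        for lv in c.levels
                    ],
                }
                for c in self.criteria
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Instrument":
        try:
            name = d["name"]
            raw_criteria = d["criteria"]
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"instrument config: missing key {exc}")
        criteria = []
        for rc in raw_criteria:
            for key in ("name", "mode", "levels"):
                if key not in rc:
                    raise ValidationError(
                        f"instrument config: criterion entry missing {key!r}"
                    )
            levels, points = [], {}
            for lv in rc["levels"]:
                if "label" not in lv or "points" not in lv:
                    raise ValidationError(
                        f"criterion {rc['name']!r}: level entries need "
                        f"'label' and 'points'"
                    )
                levels.append(str(lv["label"]))
                points[str(lv["label"])] = float(lv["points"])
            criteria.append(
                CriterionSpec(rc["name"], tuple(levels), rc["mode"], points)
            )
        return cls(name=str(name), criteria=tuple(criteria))


def save_instrument(instrument: Instrument, path: str | Path) -> None:
    """Write an instrument config as JSON (or YAML for .yaml/.yml)."""
    path = Path(path)
    d = instrument.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2) + "\n")


def load_instrument(path: str | Path) -> Instrument:
    """Load an instrument config (JSON or YAML).

    The canonical instrument is available by the reserved name
    ``"bapt_v1"`` without a file on disk.
    """
    if str(path) == "bapt_v1":
        from .canonical import bapt_v1

        return bapt_v1()
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"instrument config not found: {path}")
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return Instrument.from_dict(d)


def _parse_flag(value, *, column: str, row: int) -> bool:
    if isinstance(value, bool):
        return value
    if pd.isna(value):
        raise ValidationError(f"row {row}: missing flag in column {column!r}")
    s = str(value).strip().lower()
    if s in ("1", "true", "yes", "y"):
        return True
    if s in ("0", "false", "no", "n"):
        return False
    try:
        return bool(int(float(s)))
    except ValueError:
        raise ValidationError(
            f"row {row}: unparseable flag {value!r} in column {column!r}"
        )


def _parse_float(value, *, column: str, row: int, required: bool = True):
    if pd.isna(value) or (isinstance(value, str) and not value.strip()):
        if required:
            raise ValidationError(
                f"row {row}: missing value in column {column!r}"
            )
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row}: unparseable numeric {value!r} in column {column!r}"
        )


@dataclass(frozen=True)
class PatientRecord:
    """Referral-time clinical record used for screening and scoring."""

    patient_id: str
    age_years: float
    sex: str
    hba1c_pct: float
    on_treatment: bool
    diabetes_duration_years: float
    on_insulin: bool
    on_oral_meds: bool
    comorbidities: frozenset[str]
    pe_risk: bool
    asa_class: int
    weight_kg: float | None = None
    height_m: float | None = None
    bmi: float | None = None
    contraindication_flags: frozenset[str] = frozenset()
    extras: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "comorbidities", frozenset(self.comorbidities)
        )
        object.__setattr__(
            self,
            "contraindication_flags",
            frozenset(self.contraindication_flags),
        )
        unknown = self.comorbidities - set(COMORBIDITIES)
        if unknown:
            raise ValidationError(
                f"patient {self.patient_id!r}: unknown comorbidities "
                f"{sorted(unknown)}"
            )
        if self.sex not in ("male", "female"):
            raise ValidationError(
                f"patient {self.patient_id!r}: sex must be male/female, got "
                f"{self.sex!r}"
            )
        if self.age_years <= 0:
            raise ValidationError(
                f"patient {self.patient_id!r}: age must be positive"
            )
        if not 3 < self.hba1c_pct < 20:
            raise ValidationError(
                f"patient {self.patient_id!r}: HbA1c {self.hba1c_pct} "
                f"outside the plausible (3, 20)% window"
            )
        if not 1 <= int(self.asa_class) <= 4:
            raise ValidationError(
                f"patient {self.patient_id!r}: ASA class must be 1-4"
            )
        if self.bmi is None:
            if self.weight_kg is None or self.height_m is None:
                raise ValidationError(
                    f"patient {self.patient_id!r}: need bmi or both "
                    f"weight_kg and height_m"
                )
            object.__setattr__(
                self, "bmi", self.weight_kg / self.height_m**2
            )
        elif self.weight_kg is not None and self.height_m is not None:
            derived = self.weight_kg / self.height_m**2
            if abs(derived - self.bmi) > 0.1:
                raise ValidationError(
                    f"patient {self.patient_id!r}: bmi {self.bmi:.2f} "
                    f"inconsistent with weight/height ({derived:.2f})"
                )


@dataclass(frozen=True)
class FollowUpRecord:
    """Twelve-month post-surgery measurements for one patient."""

    patient_id: str
    weight_kg: float
    hba1c_pct: float
    on_insulin: bool
    on_oral_meds: bool
    months: int = 12
    comorbidity_status: Mapping[str, str] = field(default_factory=dict)
    aqol_pre: float | None = None
    aqol_post: float | None = None
    adverse_events: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(
            self, "comorbidity_status", dict(self.comorbidity_status)
        )
        object.__setattr__(
            self, "adverse_events", tuple(self.adverse_events)
        )
        if self.weight_kg <= 0 or self.hba1c_pct <= 0:
            raise ValidationError(
                f"follow-up {self.patient_id!r}: weight and HbA1c must be "
                f"positive"
            )
        for utility, label in (
            (self.aqol_pre, "aqol_pre"),
            (self.aqol_post, "aqol_post"),
        ):
            if utility is not None and not 0.0 <= utility <= 1.0:
                raise ValidationError(
                    f"follow-up {self.patient_id!r}: {label} {utility} "
                    f"outside [0, 1]"
                )
        for como, status in self.comorbidity_status.items():
            if status not in ("unchanged", "improved", "resolved"):
                raise ValidationError(
                    f"follow-up {self.patient_id!r}: bad status {status!r} "
                    f"for {como!r}"
                )


_STATUS_CODES = {"u": "unchanged", "i": "improved", "r": "resolved"}
_STATUS_TO_CODE = {v: k for k, v in _STATUS_CODES.items()}


def _patient_from_row(row: pd.Series, idx: int, extra_cols) -> PatientRecord:
    rownum = idx + 2  # header is line 1
    comorbidities = {
        name
        for col, name in COMORBIDITY_COLUMNS.items()
        if col in row.index and _parse_flag(row[col], column=col, row=rownum)
    }
    weight = _parse_float(
        row.get("weight_kg"), column="weight_kg", row=rownum, required=False
    )
    height = _parse_float(
        row.get("height_m"), column="height_m", row=rownum, required=False
    )
    bmi = _parse_float(
        row.get("bmi"), column="bmi", row=rownum, required=False
    )
    contra = row.get("contraindication_flags")
    flags = (
        frozenset(str(contra).split(";")) - {"", "nan"}
        if contra is not None and not pd.isna(contra) and str(contra).strip()
        else frozenset()
    )
    return PatientRecord(
        patient_id=str(row["patient_id"]),
        age_years=_parse_float(row["age_years"], column="age_years", row=rownum),
        sex=str(row["sex"]).strip().lower(),
        weight_kg=weight,
        height_m=height,
        bmi=bmi,
        hba1c_pct=_parse_float(row["hba1c_pct"], column="hba1c_pct", row=rownum),
        on_treatment=_parse_flag(row["on_treatment"], column="on_treatment", row=rownum),
        diabetes_duration_years=_parse_float(
            row["diabetes_duration_years"],
            column="diabetes_duration_years",
            row=rownum,
        ),
        on_insulin=_parse_flag(row["on_insulin"], column="on_insulin", row=rownum),
        on_oral_meds=_parse_flag(row["on_oral_meds"], column="on_oral_meds", row=rownum),
        comorbidities=frozenset(comorbidities),
        pe_risk=_parse_flag(row["pe_risk"], column="pe_risk", row=rownum),
        asa_class=int(float(row["asa_class"])),
        contraindication_flags=flags,
        extras={c: row[c] for c in extra_cols},
    )


def read_patients(path: str | Path) -> list[PatientRecord]:
    """Read a referral-time patient table (CSV, documented dialect).

    BMI is derived from weight/height when the ``bmi`` column is absent or
    empty.  Unknown columns are preserved on each record's ``extras``.
    """
    try:
        df = pd.read_csv(path, dtype={"patient_id": str})
    except pd.errors.EmptyDataError:
        logger.warning("patient table %s is empty", path)
        return []
    missing = [c for c in REQUIRED_PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"patient table {path}: missing required columns {missing}"
        )
    known = set(PATIENT_COLUMNS) | set(FOLLOWUP_COLUMNS) | {
        "contraindication_flags"
    } | {f"{c}_status" for c in COMORBIDITY_COLUMNS}
    extra_cols = [c for c in df.columns if c not in known]
    records = [
        _patient_from_row(row, i, extra_cols) for i, row in df.iterrows()
    ]
    if not records:
        logger.warning("patient table %s has a header but no rows", path)
    return records


def _followup_from_row(row: pd.Series, idx: int) -> FollowUpRecord | None:
    rownum = idx + 2
    if "hba1c_pct_12m" not in row.index or pd.isna(row.get("hba1c_pct_12m")):
        return None
    status = {}
    for col, name in COMORBIDITY_COLUMNS.items():
        scol = f"{col}_status"
        if scol in row.index and not pd.isna(row[scol]) and str(row[scol]).strip():
            code = str(row[scol]).strip().lower()
            if code not in _STATUS_CODES:
                raise ValidationError(
                    f"row {rownum}: bad status code {code!r} in {scol!r}"
                )
            status[name] = _STATUS_CODES[code]
    ae_raw = row.get("ae_list")
    events = (
        tuple(e for e in str(ae_raw).split(";") if e and e != "nan")
        if ae_raw is not None and not pd.isna(ae_raw)
        else ()
    )
    return FollowUpRecord(
        patient_id=str(row["patient_id"]),
        weight_kg=_parse_float(row["weight_kg_12m"], column="weight_kg_12m", row=rownum),
        hba1c_pct=_parse_float(row["hba1c_pct_12m"], column="hba1c_pct_12m", row=rownum),
        on_insulin=_parse_flag(row["on_insulin_12m"], column="on_insulin_12m", row=rownum),
        on_oral_meds=_parse_flag(row["on_oral_meds_12m"], column="on_oral_meds_12m", row=rownum),
        comorbidity_status=status,
        aqol_pre=_parse_float(row.get("aqol_pre"), column="aqol_pre", row=rownum, required=False),
        aqol_post=_parse_float(row.get("aqol_12m"), column="aqol_12m", row=rownum, required=False),
        adverse_events=events,
    )


def read_cohort(
    path: str | Path,
) -> tuple[list[PatientRecord], dict[str, FollowUpRecord]]:
    """Read a combined referral + 12-month table.

    Returns the patient records plus a mapping patient_id -> follow-up for
    the rows that carry 12-month data.
    """
    patients = read_patients(path)
    if not patients:
        return [], {}
    df = pd.read_csv(path, dtype={"patient_id": str})
    followups: dict[str, FollowUpRecord] = {}
    for i, row in df.iterrows():
        fu = _followup_from_row(row, i)
        if fu is not None:
            followups[fu.patient_id] = fu
    return patients, followups


def patients_to_frame(
    patients: Sequence[PatientRecord],
    followups: Mapping[str, FollowUpRecord] | None = None,
) -> pd.DataFrame:
    """Serialise records back to the CSV dialect (inverse of readers)."""
    rows = []
    followups = followups or {}
    for p in patients:
        row: dict[str, object] = {
            "patient_id": p.patient_id,
            "age_years": p.age_years,
            "sex": p.sex,
            "weight_kg": p.weight_kg,
            "height_m": p.height_m,
            "bmi": p.bmi,
            "hba1c_pct": p.hba1c_pct,
            "on_treatment": int(p.on_treatment),
            "diabetes_duration_years": p.diabetes_duration_years,
            "on_insulin": int(p.on_insulin),
            "on_oral_meds": int(p.on_oral_meds),
            "pe_risk": int(p.pe_risk),
            "asa_class": p.asa_class,
            "contraindication_flags": ";".join(
                sorted(p.contraindication_flags)
            ),
        }
        for col, name in COMORBIDITY_COLUMNS.items():
            row[col] = int(name in p.comorbidities)
        row.update(p.extras)
        fu = followups.get(p.patient_id)
        if fu is not None:
            row.update(
                {
                    "weight_kg_12m": fu.weight_kg,
                    "hba1c_pct_12m": fu.hba1c_pct,
                    "on_insulin_12m": int(fu.on_insulin),
                    "on_oral_meds_12m": int(fu.on_oral_meds),
                    "aqol_pre": fu.aqol_pre,
                    "aqol_12m": fu.aqol_post,
                    "ae_list": ";".join(fu.adverse_events),
                }
            )
            for col, name in COMORBIDITY_COLUMNS.items():
                if name in fu.comorbidity_status:
                    row[f"{col}_status"] = _STATUS_TO_CODE[
                        fu.comorbidity_status[name]
                    ]
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(
    patients: Sequence[PatientRecord],
    path: str | Path,
    followups: Mapping[str, FollowUpRecord] | None = None,
) -> None:
    patients_to_frame(patients, followups).to_csv(path, index=False)
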