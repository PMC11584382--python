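"""Eligibility screening, BAPT scoring and remission classification.

Category boundaries (documented conventions):

* BMI bands are half-open: [35, 40), [40, 45), [45, 50), [50, inf).  The
  top band starts at exactly 50 to stay consistent with the BMI >= 50
  surgical-risk factor.
* Diabetes duration: [0, 4) -> "<4 years", [4, 8] -> "4-8 years",
  (8, inf) -> ">8 years".
* Age bands: [18, 30), [30, 50), [50, inf).  The 45+ risk factor uses
  exact age, so a patient in the 30-49 band may or may not carry it.

Hypertension and age intentionally contribute twice (comorbidity points +
risk factor; age band + 45+ factor) -- that is how the instrument is
printed, not an implementation accident.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import BaptError, ValidationError
from .instrument import ADDITIVE_SUBSCORE, FollowUpRecord, Instrument, PatientRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EligibilityResult:
    eligible: bool
    reasons: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "reasons", tuple(self.reasons))
        if self.eligible != (len(self.reasons) == 0):
            raise ValidationError("eligible flag must match empty reasons")


@dataclass(frozen=True)
class ScoreBreakdown:
    comorbidity_points: int
    duration_points: int
    bmi_points: int
    age_points: int
    risk_points: int
    risk_factor_count: int
    total: int

    def __post_init__(self):
        parts = (
            self.comorbidity_points
            + self.duration_points
            + self.bmi_points
            + self.age_points
            + self.risk_points
        )
        if parts != self.total:
            raise ValidationError("total must equal the sum of its parts")


class IneligiblePatientError(BaptError):
    """Raised when scoring a patient who fails the eligibility screen."""

    def __init__(self, patient_id: str, result: EligibilityResult):
        super().__init__(
            f"patient {patient_id!r} is not eligible "
            f"({', '.join(result.reasons)}); pass force=True to score anyway"
        )
        self.result = result


def check_eligibility(p: PatientRecord) -> EligibilityResult:
    """Apply the referral screen: age 18-65, BMI > 35, HbA1c > 7 despite
    treatment, at least one potentially reversible comorbidity; exclusions
    for ASA class IV and any recorded contraindication flag."""
    reasons = []
    if not 18 <= p.age_years <= 65:
        reasons.append("age")
    if not p.bmi > 35:
        reasons.append("bmi")
    if not (p.hba1c_pct > 7 and p.on_treatment):
        reasons.append("glycaemia")
    if not p.comorbidities:
        reasons.append("comorbidity")
    if p.asa_class == 4:
        reasons.append("asa_iv")
    for flag in sorted(p.contraindication_flags):
        reasons.append(f"contraindication:{flag}")
    return EligibilityResult(eligible=not reasons, reasons=tuple(reasons))


def count_risk_factors(p: PatientRecord) -> int:
    """Surgical-risk factors present (0-5): male sex, age >= 45,
    BMI >= 50, hypertension, pulmonary-embolism risk."""
    return sum(
        (
            p.sex == "male",
            p.age_years >= 45,
            p.bmi >= 50,
            "hypertension" in p.comorbidities,
            bool(p.pe_risk),
        )
    )


def duration_level(years: float) -> str:
    if years < 0:
        raise ValidationError("diabetes duration cannot be negative")
    if years < 4:
        return "lt4y"
    if years <= 8:
        return "4to8y"
    return "gt8y"


def bmi_level(bmi: float) -> str:
    if bmi < 40:
        return "35to40"
    if bmi < 45:
        return "40to45"
    if bmi < 50:
        return "45to50"
    return "ge50"


def age_level(age: float) -> str:
    # the instrument has no band below 18; such patients fail screening and
    # can only be force-scored, in which case the youngest band applies
    if age < 30:
        return "18to29"
    if age < 50:
        return "30to49"
    return "50plus"


def risk_level(n_factors: int) -> str:
    if not 0 <= n_factors <= 5:
        raise ValidationError("risk factor count must be 0-5")
    if n_factors <= 1:
        return "factors_0to1"
    if n_factors <= 3:
        return "factors_2to3"
    return "factors_4to5"


def score_patient(
    p: PatientRecord, instrument: Instrument, *, force: bool = False
) -> ScoreBreakdown:
    """Full per-criterion score breakdown for an eligible patient.

    Comorbidity points add across the conditions present; the other four
    criteria are category lookups.  Ineligible patients raise
    :class:`IneligiblePatientError` unless ``force`` is set.
    """
    if not force:
        res = check_eligibility(p)
        if not res.eligible:
            raise IneligiblePatientError(p.patient_id, res)
    como_crit = instrument.criterion("comorbidity")
    if como_crit.mode != ADDITIVE_SUBSCORE:
        raise ValidationError(
            "instrument's comorbidity criterion must be additive"
        )
    comorbidity_points = sum(
        como_crit.points(c) for c in sorted(p.comorbidities)
    )
    duration_points = instrument.criterion("duration").points(
        duration_level(p.diabetes_duration_years)
    )
    bmi_points = instrument.criterion("bmi").points(bmi_level(p.bmi))
    age_points = instrument.criterion("age").points(age_level(p.age_years))
    n_factors = count_risk_factors(p)
    risk_points = instrument.criterion("risk").points(risk_level(n_factors))
    parts = [
        comorbidity_points,
        duration_points,
        bmi_points,
        age_points,
        risk_points,
    ]
    ints = [int(round(x)) for x in parts]
    if any(abs(i - x) > 1e-9 for i, x in zip(ints, parts)):
        raise ValidationError(
            "score_patient requires an integer-points instrument"
        )
    return ScoreBreakdown(
        comorbidity_points=ints[0],
        duration_points=ints[1],
        bmi_points=ints[2],
        age_points=ints[3],
        risk_points=ints[4],
        risk_factor_count=n_factors,
        total=sum(ints),
    )


def classify_remission(f: FollowUpRecord) -> bool | None:
    """Diabetes remission at follow-up: HbA1c strictly below 6.5% with no
    glucose-lowering medications.  Returns None (indeterminate) when a
    needed field is missing; such records are excluded from denominators.
    """
    if f.hba1c_pct is None or f.on_insulin is None or f.on_oral_meds is None:
        logger.warning(
            "follow-up %s: remission indeterminate (missing field)",
            f.patient_id,
        )
        return None
    return f.hba1c_pct < 6.5 and not f.on_insulin and not f.on_oral_meds
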