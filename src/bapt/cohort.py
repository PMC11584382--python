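"""Seeded synthetic referral cohorts and 12-month outcomes.

The generator emulates the referral cohort's published marginal structure
(age 52 +/- 8.7, 57.1% female, BMI 46.1 +/- 7.0, HbA1c 8.77 +/- 1.5,
hypertension 86.3% / dyslipidaemia 85.2% / sleep apnoea 66.0%) and the
qualitative outcome trends the evaluation relies on: percent weight loss
flat in the priority score, HbA1c improvement and oral-medication
discontinuation increasing with it, insulin discontinuation flat, and a
larger quality-of-life gain above the 40-point line.  Parameters are set,
not fitted; nothing here is an estimate of the clinical data.

All draws are made per patient in a fixed order from one seeded generator,
so a config + seed pair is byte-reproducible.  Truncated quantities are
redrawn up to a bounded number of attempts and the config is rejected as
unsatisfiable beyond that.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ValidationError
from .instrument import COMORBIDITIES, FollowUpRecord, PatientRecord
from .canonical import bapt_v1
from .screening import check_eligibility, score_patient

logger = logging.getLogger(__name__)

_MAX_REJECT = 1000

_AE_LABELS = (
    "readmission_28d",
    "nausea_vomiting",
    "wound_infection",
    "dehydration",
    "anastomotic_leak",
)


@dataclass(frozen=True)
class OutcomeParams:
    """Knobs of the 12-month outcome model."""

    weight_loss_pct_mean: float = 23.0
    weight_loss_pct_sd: float = 9.0
    hba1c_improve_base: float = 1.0
    hba1c_improve_slope_per_point: float = 0.6
    hba1c_improve_noise_sd: float = 8.0
    oral_discontinue_logit_intercept: float = -2.2
    oral_discontinue_logit_slope: float = 0.045
    insulin_discontinue_rate: float = 0.7
    aqol_pre_mean: float = 0.55
    aqol_pre_sd: float = 0.23
    aqol_change_mean_low: float = 0.058
    aqol_change_sd_low: float = 0.277
    aqol_change_mean_high: float = 0.174
    aqol_change_sd_high: float = 0.235
    aqol_split_score: int = 40
    comorbidity_improve_prob: float = 0.4
    comorbidity_resolve_prob: float = 0.4
    adverse_event_rate: float = 0.11


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic referral cohort."""

    n: int = 292
    seed: int = 0
    age_mean: float = 52.0
    age_sd: float = 8.7
    female_frac: float = 0.571
    bmi_mean: float = 46.1
    bmi_sd: float = 7.0
    hba1c_mean: float = 8.77
    hba1c_sd: float = 1.5
    comorbidity_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {
            "hypertension": 0.863,
            "dyslipidaemia": 0.852,
            "osa": 0.660,
            "joint_pain": 0.55,
            "reproductive_issues": 0.22,
            "nash": 0.12,
            "albuminuria": 0.10,
            "renal_impairment": 0.07,
        }
    )
    hypertension_age_coupling: float = 0.006  # extra prevalence per year over the mean age
    duration_intercept: float = -6.0
    duration_slope_per_age_year: float = 0.28
    duration_sd: float = 3.0
    insulin_logit_intercept: float = -1.2
    insulin_logit_slope_per_duration_year: float = 0.2
    oral_meds_frac: float = 0.997
    pe_risk_frac: float = 0.08
    asa3_frac: float = 0.35
    indigenous_frac: float = 0.219
    outcome_params: OutcomeParams = field(default_factory=OutcomeParams)

    def __post_init__(self):
        if self.n < 0:
            raise ValidationError("n must be non-negative")
        for name in ("age_sd", "bmi_sd", "hba1c_sd", "duration_sd"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        probs = dict(self.comorbidity_prevalence)
        unknown = set(probs) - set(COMORBIDITIES)
        if unknown:
            raise ValidationError(f"unknown comorbidities in prevalence: {unknown}")
        for key, p in probs.items():
            if not 0 <= p <= 1:
                raise ValidationError(f"prevalence for {key} outside [0, 1]")
        for name in ("female_frac", "oral_meds_frac", "pe_risk_frac", "asa3_frac", "indigenous_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} outside [0, 1]")
        object.__setattr__(self, "comorbidity_prevalence", probs)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "SynthConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "outcome_params" in raw:
            raw["outcome_params"] = OutcomeParams(**raw["outcome_params"])
        raw.update(overrides)
        return cls(**raw)


def _truncated_normal(rng, mean, sd, lo, hi, what):
    for _ in range(_MAX_REJECT):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    raise ValidationError(
        f"unsatisfiable config: could not draw {what} ~ N({mean}, {sd}) "
        f"inside ({lo}, {hi}) in {_MAX_REJECT} attempts"
    )


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def generate_cohort(cfg: SynthConfig) -> list[PatientRecord]:
    """Draw ``cfg.n`` referral records, all of which pass the eligibility
    screen (truncation to age 18-65, BMI > 35, HbA1c > 7 on treatment,
    at least one comorbidity)."""
    rng = np.random.default_rng(cfg.seed)
    records = []
    forced_comorbidity = 0
    for i in range(cfg.n):
        age = _truncated_normal(rng, cfg.age_mean, cfg.age_sd, 18.0, 65.0, "age")
        female = rng.random() < cfg.female_frac
        height = float(
            np.clip(rng.normal(1.66 if female else 1.76, 0.07), 1.40, 2.10)
        )
        # lower bound leaves headroom so BMI re-derived from the rounded
        # weight/height cannot fall back under the BMI > 35 inclusion line
        bmi = _truncated_normal(rng, cfg.bmi_mean, cfg.bmi_sd, 35.05, 75.0, "bmi")
        # lower bound > 7.005 so the value still exceeds 7% after rounding
        hba1c = _truncated_normal(
            rng, cfg.hba1c_mean, cfg.hba1c_sd, 7.01, 19.0, "hba1c"
        )
        # mild positive hypertension-age coupling; other comorbidities are
        # independent draws at their configured prevalence
        comorbidities: set[str] = set()
        for attempt in range(100):
            comorbidities = set()
            for name in COMORBIDITIES:
                p = cfg.comorbidity_prevalence.get(name, 0.0)
                if name == "hypertension":
                    p = float(
                        np.clip(
                            p + cfg.hypertension_age_coupling * (age - cfg.age_mean),
                            0.0,
                            1.0,
                        )
                    )
                if rng.random() < p:
                    comorbidities.add(name)
            if comorbidities:
                break
        else:
            comorbidities = {"hypertension"}
            forced_comorbidity += 1
        duration = float(
            np.clip(
                rng.normal(
                    cfg.duration_intercept + cfg.duration_slope_per_age_year * age,
                    cfg.duration_sd,
                ),
                0.1,
                40.0,
            )
        )
        on_insulin = rng.random() < _logistic(
            cfg.insulin_logit_intercept
            + cfg.insulin_logit_slope_per_duration_year * duration
        )
        on_oral = rng.random() < cfg.oral_meds_frac
        if not (on_oral or on_insulin):
            on_oral = True  # everyone referred is on some glucose-lowering therapy
        pe = rng.random() < cfg.pe_risk_frac
        asa = 3 if rng.random() < cfg.asa3_frac else 2
        indigenous = rng.random() < cfg.indigenous_frac
        height = round(height, 2)
        weight = bmi * height**2
        record = PatientRecord(
            patient_id=f"SYN-{i + 1:04d}",
            age_years=round(age, 1),
            sex="female" if female else "male",
            weight_kg=round(weight, 1),
            height_m=height,
            bmi=None,  # derived from weight/height
            hba1c_pct=round(hba1c, 2),
            on_treatment=True,
            diabetes_duration_years=round(duration, 1),
            on_insulin=bool(on_insulin),
            on_oral_meds=bool(on_oral),
            comorbidities=frozenset(comorbidities),
            pe_risk=bool(pe),
            asa_class=asa,
            extras={"aboriginal_tsi": int(indigenous)},
        )
        result = check_eligibility(record)
        if not result.eligible:  # pragma: no cover - guarded by construction
            raise ValidationError(
                f"generator produced an ineligible record: {result.reasons}"
            )
        records.append(record)
    if forced_comorbidity:
        logger.warning(
            "forced hypertension onto %d records with no drawn comorbidity",
            forced_comorbidity,
        )
    return records


def generate_outcomes(
    cohort: Sequence[PatientRecord], cfg: SynthConfig
) -> list[FollowUpRecord]:
    """Draw 12-month outcomes for every cohort record.

    Percent weight loss is independent of the priority score; relative
    HbA1c improvement is linear in the score plus noise; oral-medication
    discontinuation follows a logistic curve in the score; insulin
    discontinuation is a flat Bernoulli; quality-of-life change has a
    larger mean at or above the configured split score.
    """
    op = cfg.outcome_params
    rng = np.random.default_rng([cfg.seed, 1])
    instrument = bapt_v1()
    followups = []
    for p in cohort:
        score = score_patient(p, instrument).total
        pwl = float(
            np.clip(
                rng.normal(op.weight_loss_pct_mean, op.weight_loss_pct_sd),
                1.0,
                60.0,
            )
        )
        improve = float(
            np.clip(
                op.hba1c_improve_base
                + op.hba1c_improve_slope_per_point * score
                + rng.normal(0.0, op.hba1c_improve_noise_sd),
                -10.0,
                85.0,
            )
        )
        hba1c_12m = float(np.clip(p.hba1c_pct * (1 - improve / 100.0), 3.2, 19.0))
        oral_stop = rng.random() < _logistic(
            op.oral_discontinue_logit_intercept
            + op.oral_discontinue_logit_slope * score
        )
        insulin_stop = rng.random() < op.insulin_discontinue_rate
        aqol_pre = float(
            np.clip(rng.normal(op.aqol_pre_mean, op.aqol_pre_sd), 0.02, 0.98)
        )
        if score >= op.aqol_split_score:
            change = rng.normal(op.aqol_change_mean_high, op.aqol_change_sd_high)
        else:
            change = rng.normal(op.aqol_change_mean_low, op.aqol_change_sd_low)
        aqol_post = float(np.clip(aqol_pre + change, 0.0, 1.0))
        status = {}
        for name in sorted(p.comorbidities):
            u = rng.random()
            if u < op.comorbidity_resolve_prob:
                status[name] = "resolved"
            elif u < op.comorbidity_resolve_prob + op.comorbidity_improve_prob:
                status[name] = "improved"
            else:
                status[name] = "unchanged"
        n_ae = int(rng.poisson(op.adverse_event_rate))
        events = tuple(
            _AE_LABELS[int(rng.integers(len(_AE_LABELS)))] for _ in range(n_ae)
        )
        followups.append(
            FollowUpRecord(
                patient_id=p.patient_id,
                weight_kg=round(p.weight_kg * (1 - pwl / 100.0), 1),
                hba1c_pct=round(hba1c_12m, 2),
                on_insulin=bool(p.on_insulin and not insulin_stop),
                on_oral_meds=bool(p.on_oral_meds and not oral_stop),
                comorbidity_status=status,
                aqol_pre=round(aqol_pre, 3),
                aqol_post=round(aqol_post, 3),
                adverse_events=events,
            )
        )
    return followups
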