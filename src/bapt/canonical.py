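"""The canonical BAPT v1 instrument and its published elicitation statistics.

The rounded points are shipped as constants rather than recomputed from the
panel means: the development committee deliberately adjusted several values
away from nearest-integer rounding (e.g. the 40-<45 BMI band, normalised
8.63, was rounded to 10, not 9), so the printed instrument is the
instrument.  The panel means/SDs and normalised scores are retained so the
derivation arithmetic (comorbidity rescaling, draft rounding) can be
checked against them.
"""

from __future__ import annotations

from .instrument import (
    ADDITIVE_SUBSCORE,
    COMORBIDITIES,
    SINGLE_SELECT,
    CriterionSpec,
    Instrument,
)

# Per-level statistics from the nine-clinician elicitation panel:
# (mean, sd, normalised score, canonical rounded points), worst level first.
ELICITATION_STATS: dict[str, tuple[tuple[str, float, float, float, int], ...]] = {
    "comorbidity": (
        ("minimal_impact", 0.0, 0.0, 0.0, 0),
        ("hypertension", 8.72, 4.88, 1.96, 2),
        ("dyslipidaemia", 9.93, 4.9, 2.23, 2),
        ("nash", 13.36, 4.54, 3.01, 3),
        ("albuminuria", 15.43, 5.52, 3.47, 3),
        ("joint_pain", 16.06, 5.19, 3.61, 4),
        ("reproductive_issues", 17.41, 4.49, 3.92, 4),
        ("renal_impairment", 23.43, 5.11, 5.27, 5),
        ("osa", 30.28, 7.46, 6.81, 7),
    ),
    "duration": (
        ("gt8y", 0.0, 0.0, 0.0, 0),
        ("4to8y", 11.92, 8.11, 11.92, 12),
        ("lt4y", 19.92, 14.42, 19.92, 20),
    ),
    "bmi": (
        ("35to40", 0.0, 0.0, 0.0, 0),
        ("40to45", 8.63, 4.9, 8.63, 10),
        ("45to50", 11.58, 4.77, 11.58, 13),
        ("ge50", 14.92, 4.54, 14.92, 15),
    ),
    "age": (
        ("50plus", 0.0, 0.0, 0.0, 0),
        ("30to49", 8.76, 3.66, 8.76, 10),
        ("18to29", 15.17, 7.84, 15.17, 15),
    ),
    "risk": (
        ("factors_4to5", 0.0, 0.0, 0.0, 0),
        ("factors_2to3", 11.34, 9.04, 11.34, 10),
        ("factors_0to1", 19.7, 11.62, 19.7, 20),
    ),
}

#: Panel mean weight per comorbidity (the eight non-trivial levels of the
#: nine-level comorbidity attribute), keyed by comorbidity identifier.
COMORBIDITY_MEANS: dict[str, float] = {
    level: mean
    for level, mean, _sd, _norm, _pts in ELICITATION_STATS["comorbidity"]
    if level != "minimal_impact"
}

#: Published normalised (pre-rounding) scores per level.
NORMALISED_SCORES: dict[str, dict[str, float]] = {
    crit: {level: norm for level, _m, _s, norm, _p in rows}
    for crit, rows in ELICITATION_STATS.items()
}

#: Canonical rounded points per level.
CANONICAL_POINTS: dict[str, dict[str, int]] = {
    crit: {level: pts for level, _m, _s, _n, pts in rows}
    for crit, rows in ELICITATION_STATS.items()
}

#: Levels of each criterion, worst first.
CANONICAL_LEVELS: dict[str, tuple[str, ...]] = {
    crit: tuple(level for level, *_ in rows)
    for crit, rows in ELICITATION_STATS.items()
}

assert CANONICAL_LEVELS["comorbidity"][1:] == COMORBIDITIES

#: The five surgical-risk factors counted by the risk criterion.
RISK_FACTORS = ("male", "age_45_plus", "bmi_ge_50", "hypertension", "pe_risk")


def bapt_v1() -> Instrument:
    """Build the canonical instrument (criterion maxima 30/20/15/15/20)."""
    criteria = []
    for crit, rows in ELICITATION_STATS.items():
        mode = ADDITIVE_SUBSCORE if crit == "comorbidity" else SINGLE_SELECT
        criteria.append(
            CriterionSpec(
                name=crit,
                levels=tuple(level for level, *_ in rows),
                mode=mode,
                level_points={level: float(pts) for level, *_, pts in rows},
            )
        )
    return Instrument(name="bapt_v1", criteria=tuple(criteria))


def panel_mean_weights() -> dict[str, tuple[float, ...]]:
    """Panel mean level weights per criterion, worst level first."""
    return {
        crit: tuple(mean for _lv, mean, *_ in rows)
        for crit, rows in ELICITATION_STATS.items()
    }
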