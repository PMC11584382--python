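"""Level-weight derivation and the instrument's derivation arithmetic.

From a respondent's pairwise judgements, per-level values are recovered by
linear programming: non-negative, zero at each criterion's worst level,
non-decreasing along the level order, top levels summing to 100, every
strict judgement honoured with a shared margin ``delta`` that the solver
maximises (max-min margin).  Degenerate optima are resolved by a secondary
pass minimising the sum of all level values at the optimal margin, which
makes the solution deterministic.

Also here: aggregation across respondents, the rescaling that converts the
elicited multi-level comorbidity attribute into additive per-comorbidity
points, nearest-integer draft rounding with canonical comparison, and the
brute-force verification of the instrument's achievable score range.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .elicitation import INDIFFERENT, B_PREFERRED, Judgement, StateVector
from .errors import BaptError, InconsistencyError, ValidationError
from .instrument import ADDITIVE_SUBSCORE, Instrument

_DELTA_CAP = 100.0
#: Minimum strict margin (points out of 100).  Forcing the shared margin
#: strictly positive makes contradictory strict judgements infeasible
#: instead of silently collapsing to a zero margin.
_DELTA_MIN = 1e-6


@dataclass(frozen=True)
class LevelWeights:
    """Per-level values for one respondent, worst level first."""

    respondent_id: str
    values: Mapping[str, tuple[float, ...]]
    margin: float = 0.0
    order: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(
            self, "values", {k: tuple(map(float, v)) for k, v in self.values.items()}
        )
        if not self.order:
            object.__setattr__(self, "order", tuple(self.values.keys()))
        for crit, vals in self.values.items():
            if vals[0] != 0.0:
                raise ValidationError(
                    f"weights for {crit!r}: worst level must be 0"
                )
            if any(b < a - 1e-9 for a, b in zip(vals, vals[1:])):
                raise ValidationError(
                    f"weights for {crit!r}: values must be non-decreasing"
                )
            if any(v < -1e-12 for v in vals):
                raise ValidationError(f"weights for {crit!r}: negative value")

    def state_total(self, state: StateVector) -> float:
        return float(
            sum(self.values[c][lv] for c, lv in zip(self.order, state.levels))
        )

    @property
    def top_sum(self) -> float:
        return float(sum(v[-1] for v in self.values.values()))

    def to_dict(self) -> dict:
        return {
            "respondent": self.respondent_id,
            "margin": self.margin,
            "order": list(self.order),
            "values": {k: list(v) for k, v in self.values.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LevelWeights":
        return cls(
            respondent_id=d["respondent"],
            values={k: tuple(v) for k, v in d["values"].items()},
            margin=float(d.get("margin", 0.0)),
            order=tuple(d.get("order", ())),
        )


@dataclass(frozen=True)
class AggregatedWeights:
    """Across-respondent mean and sample SD per level."""

    mean: Mapping[str, tuple[float, ...]]
    sd: Mapping[str, tuple[float, ...]]
    n_respondents: int

    def to_dict(self) -> dict:
        return {
            "n_respondents": self.n_respondents,
            "mean": {k: list(v) for k, v in self.mean.items()},
            "sd": {k: list(v) for k, v in self.sd.items()},
        }


def _variable_index(instrument: Instrument) -> tuple[dict[tuple[str, int], int], int]:
    idx, k = {}, 0
    for crit in instrument.criteria:
        for lv in range(1, crit.n_levels):
            idx[(crit.name, lv)] = k
            k += 1
    return idx, k


def _pair_row(
    instrument: Instrument,
    idx: Mapping[tuple[str, int], int],
    nvar: int,
    a: StateVector,
    b: StateVector,
) -> np.ndarray:
    """Coefficients of total(a) - total(b) in the level variables."""
    row = np.zeros(nvar)
    for crit, la, lb in zip(instrument.criterion_names, a.levels, b.levels):
        if la > 0:
            row[idx[(crit, la)]] += 1
        if lb > 0:
            row[idx[(crit, lb)]] -= 1
    return row


def derive_level_weights(
    judgements: Sequence[Judgement],
    instrument: Instrument,
    *,
    respondent_id: str | None = None,
    normalise_to: float = 100.0,
) -> LevelWeights:
    """Solve the elicitation LP for one respondent's judgements.

    Raises :class:`InconsistencyError` when the judgement set is mutually
    contradictory (infeasible LP).
    """
    idx, nv = _variable_index(instrument)
    nvar = nv + 1  # + shared strict margin delta
    A_ub: list[np.ndarray] = []
    b_ub: list[float] = []
    A_eq: list[np.ndarray] = []
    b_eq: list[float] = []
    strict_rows: list[np.ndarray] = []
    seen: set[bytes] = set()
    for j in judgements:
        a, b = j.task.a, j.task.b
        if j.verdict == B_PREFERRED:
            a, b = b, a
        row = np.zeros(nvar)
        row[:nv] = _pair_row(instrument, idx, nv, a, b)
        key = bytes([j.verdict == INDIFFERENT]) + row.tobytes()
        if key in seen:
            continue
        seen.add(key)
        if j.verdict == INDIFFERENT:
            A_eq.append(row)
            b_eq.append(0.0)
        else:
            r = -row
            r[nv] = 1.0  # total(a) - total(b) >= delta
            A_ub.append(r)
            b_ub.append(0.0)
            strict_rows.append(row[:nv].copy())
    # level monotonicity (non-strict; ordering is an instrument assumption)
    for crit in instrument.criteria:
        for lv in range(1, crit.n_levels):
            r = np.zeros(nvar)
            r[idx[(crit.name, lv)]] = -1.0
            if lv > 1:
                r[idx[(crit.name, lv - 1)]] = 1.0
            A_ub.append(r)
            b_ub.append(0.0)
    # normalisation: top levels sum to normalise_to
    norm = np.zeros(nvar)
    for crit in instrument.criteria:
        norm[idx[(crit.name, crit.n_levels - 1)]] = 1.0
    A_eq.append(norm)
    b_eq.append(float(normalise_to))

    bounds = [(0.0, None)] * nv + [
        (_DELTA_MIN if strict_rows else 0.0, _DELTA_CAP)
    ]
    c = np.zeros(nvar)
    c[nv] = -1.0  # maximise delta
    res = linprog(
        c,
        A_ub=np.vstack(A_ub),
        b_ub=np.array(b_ub),
        A_eq=np.vstack(A_eq),
        b_eq=np.array(b_eq),
        bounds=bounds,
        method="highs",
    )
    if res.status == 2:
        raise InconsistencyError(
            "judgement set is mutually contradictory: the weight LP is "
            "infeasible"
        )
    if res.status != 0:
        raise BaptError(f"weight LP failed: {res.message}")
    delta = float(res.x[nv]) if strict_rows else 0.0

    # secondary pass: smallest representation at the achieved margin
    bounds2 = list(bounds)
    bounds2[nv] = (max(0.0, delta - 1e-9), _DELTA_CAP)
    c2 = np.ones(nvar)
    c2[nv] = 0.0
    res2 = linprog(
        c2,
        A_ub=np.vstack(A_ub),
        b_ub=np.array(b_ub),
        A_eq=np.vstack(A_eq),
        b_eq=np.array(b_eq),
        bounds=bounds2,
        method="highs",
    )
    if res2.status != 0:
        raise BaptError(f"weight LP (secondary pass) failed: {res2.message}")
    x = res2.x
    values = {}
    for crit in instrument.criteria:
        vals = [0.0] + [
            max(0.0, float(x[idx[(crit.name, lv)]]))
            for lv in range(1, crit.n_levels)
        ]
        # snap tiny downward numerical wiggles so monotonicity holds exactly
        for k in range(1, len(vals)):
            if vals[k] < vals[k - 1]:
                vals[k] = vals[k - 1]
        values[crit.name] = tuple(vals)
    w = LevelWeights(
        respondent_id=respondent_id
        or (judgements[0].respondent_id if judgements else "anonymous"),
        values=values,
        margin=delta,
        order=instrument.criterion_names,
    )
    _verify_solution(w, judgements, delta)
    return w


def _verify_solution(
    w: LevelWeights, judgements: Sequence[Judgement], delta: float
) -> None:
    tol = 1e-6
    for j in judgements:
        a, b = j.task.a, j.task.b
        diff = w.state_total(a) - w.state_total(b)
        if j.verdict == INDIFFERENT:
            if abs(diff) > tol:
                raise BaptError(
                    f"post-solve check failed: indifference {a.levels} ~ "
                    f"{b.levels} violated (diff {diff:.3g})"
                )
        else:
            if j.verdict == B_PREFERRED:
                diff = -diff
            if diff < delta - tol:
                raise BaptError(
                    f"post-solve check failed: strict judgement on "
                    f"{a.levels} vs {b.levels} has slack {diff:.3g} < "
                    f"margin {delta:.3g}"
                )


def normalise_respondent(
    w: LevelWeights, *, target: float = 100.0
) -> LevelWeights:
    """Rescale so the criterion top levels sum to ``target``."""
    total = w.top_sum
    if total <= 0:
        raise ValidationError("cannot normalise all-zero weights")
    f = target / total
    return LevelWeights(
        respondent_id=w.respondent_id,
        values={k: tuple(x * f for x in v) for k, v in w.values.items()},
        margin=w.margin * f,
        order=w.order,
    )


def aggregate(respondents: Sequence[LevelWeights]) -> AggregatedWeights:
    """Arithmetic mean and sample SD per level across respondents."""
    if not respondents:
        raise ValidationError("need at least one respondent")
    ref = respondents[0]
    shape = {k: len(v) for k, v in ref.values.items()}
    for w in respondents[1:]:
        if {k: len(v) for k, v in w.values.items()} != shape or w.order != ref.order:
            raise ValidationError(
                "respondents were elicited on different instruments"
            )
    mean, sd = {}, {}
    for crit in ref.order:
        arr = np.array([w.values[crit] for w in respondents], dtype=float)
        mean[crit] = tuple(arr.mean(axis=0))
        if len(respondents) == 1:
            sd[crit] = tuple(0.0 for _ in mean[crit])
        else:
            sd[crit] = tuple(arr.std(axis=0, ddof=1))
    return AggregatedWeights(mean=mean, sd=sd, n_respondents=len(respondents))


def rescale_comorbidities(means: Mapping[str, float]) -> dict[str, float]:
    """Convert per-comorbidity attribute means into additive sub-scores.

    Each mean is multiplied by ``max(means) / sum(means)`` so the rescaled
    values sum to the comorbidity criterion's weight (its largest mean).
    """
    if not means:
        raise ValidationError("no comorbidity means given")
    vals = {k: float(v) for k, v in means.items()}
    total = sum(vals.values())
    if total <= 0 or any(v <= 0 for v in vals.values()):
        raise ValidationError("comorbidity means must be positive")
    factor = max(vals.values()) / total
    return {k: v * factor for k, v in vals.items()}


@dataclass(frozen=True)
class DraftRound:
    draft_points: int
    matches_canonical: bool | None = None


def round_half_away(x: float) -> int:
    """Nearest integer, halves away from zero (2.5 -> 3)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


def draft_rounding(
    normalised: Mapping[str, float],
    canonical: Mapping[str, float] | None = None,
) -> dict[str, DraftRound]:
    """Nearest-integer draft of the normalised scores.

    The committee that finalised the canonical instrument adjusted several
    values away from the arithmetic draft; the optional ``canonical``
    mapping lets callers flag which entries diverge.
    """
    out = {}
    for key, val in normalised.items():
        draft = round_half_away(float(val))
        match = None
        if canonical is not None and key in canonical:
            match = draft == int(canonical[key])
        out[key] = DraftRound(draft_points=draft, matches_canonical=match)
    return out


# -- score range verification ------------------------------------------

#: Representative values used by the constrained enumeration; each hits a
#: distinct category/risk-factor combination of its variable.
RANGE_AGES = (25.0, 40.0, 47.0, 55.0)
RANGE_BMIS = (37.0, 42.0, 47.0, 55.0)
RANGE_DURATIONS = (2.0, 6.0, 10.0)


def _coupled_profiles():
    from .instrument import COMORBIDITIES, PatientRecord

    subsets = []
    for r in range(1, len(COMORBIDITIES) + 1):
        subsets.extend(itertools.combinations(COMORBIDITIES, r))
    pid = 0
    for age, bmi, sex, pe, duration, combo in itertools.product(
        RANGE_AGES, RANGE_BMIS, ("male", "female"), (False, True),
        RANGE_DURATIONS, subsets,
    ):
        pid += 1
        yield PatientRecord(
            patient_id=f"range-{pid}",
            age_years=age,
            sex=sex,
            bmi=bmi,
            hba1c_pct=8.5,
            on_treatment=True,
            diabetes_duration_years=duration,
            on_insulin=False,
            on_oral_meds=True,
            comorbidities=frozenset(combo),
            pe_risk=pe,
            asa_class=2,
        )


def score_range(
    instrument: Instrument, *, coupled: bool = True, with_witnesses: bool = False
):
    """Extreme achievable totals of the instrument.

    With ``coupled=True`` (default) the enumeration walks internally
    consistent *eligible* patient profiles, honouring the cross-criterion
    couplings baked into the instrument: hypertension counts as both a
    comorbidity and a surgical-risk factor, BMI >= 50 fills the top BMI
    band and a risk factor, age drives both its band and the 45+ factor,
    and eligibility requires at least one comorbidity.  With
    ``coupled=False`` all level combinations are scored freely (and the
    comorbidity subset may be empty), giving the unconstrained envelope.
    """
    if coupled:
        from .screening import score_patient

        lo, hi = None, None
        lo_p = hi_p = None
        for p in _coupled_profiles():
            total = score_patient(p, instrument).total
            if lo is None or total < lo:
                lo, lo_p = total, p
            if hi is None or total > hi:
                hi, hi_p = total, p
        if with_witnesses:
            return (lo, hi), (lo_p, hi_p)
        return (lo, hi)

    per_criterion: list[list[float]] = []
    for crit in instrument.criteria:
        pts = [crit.points(lv) for lv in crit.levels]
        if crit.mode == ADDITIVE_SUBSCORE:
            nonzero = pts[1:]
            totals = set()
            for r in range(len(nonzero) + 1):
                for combo in itertools.combinations(nonzero, r):
                    totals.add(sum(combo))
            per_criterion.append(sorted(totals))
        else:
            per_criterion.append(sorted(set(pts)))
    lo = round(sum(min(v) for v in per_criterion))
    hi = round(sum(max(v) for v in per_criterion))
    if with_witnesses:
        return (lo, hi), (None, None)
    return (lo, hi)


# -- persistence --------------------------------------------------------

def save_weights(w: LevelWeights, path: str | Path) -> None:
    Path(path).write_text(json.dumps(w.to_dict(), indent=2) + "\n")


def load_weights(path: str | Path) -> LevelWeights:
    return LevelWeights.from_dict(json.loads(Path(path).read_text()))


def save_aggregated(agg: AggregatedWeights, path: str | Path) -> None:
    Path(path).write_text(json.dumps(agg.to_dict(), indent=2) + "\n")
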