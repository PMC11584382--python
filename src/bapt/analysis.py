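"""Outcome evaluation over a scored cohort table.

Mirrors the evaluation machinery used to pilot the instrument: score-bin
stratification with chi-square / one-way ANOVA group tests, two-group
cut-point comparisons for age and BMI (Welch t-test for means, Pearson
chi-square without continuity correction for proportions), remission
rates split at a score threshold, and quality-of-life change against the
0.06 minimum important difference (met on ``>=``).

Missing follow-up is handled by complete-case analysis with explicit
exclusion counts.  Every function is a pure function of its input frame.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import BaptError, ValidationError
from .instrument import (
    COMORBIDITIES,
    FollowUpRecord,
    Instrument,
    PatientRecord,
)
from .screening import classify_remission, duration_level, score_patient

logger = logging.getLogger(__name__)

#: Score bins used by the published stratification (inclusive ends).
DEFAULT_BINS: tuple[tuple[int, int], ...] = tuple(
    (lo, lo + 9) for lo in range(10, 80, 10)
)

AGE_CUTOFFS = (50.0, 55.0, 60.0)
BMI_CUTOFFS = (40.0, 45.0, 50.0)


def pct_change(baseline: float, followup: float) -> float:
    """Percent decrease from baseline: 100 * (baseline - followup) / baseline."""
    if baseline <= 0:
        raise ValidationError("pct_change needs a positive baseline")
    return 100.0 * (baseline - followup) / baseline


def cohort_frame(
    patients: Sequence[PatientRecord],
    followups: Mapping[str, FollowUpRecord],
    instrument: Instrument,
) -> pd.DataFrame:
    """Tidy per-patient frame: referral fields, score breakdown, and the
    derived 12-month outcome columns where follow-up exists."""
    rows = []
    for p in patients:
        b = score_patient(p, instrument, force=True)
        row: dict[str, object] = {
            "patient_id": p.patient_id,
            "age_years": p.age_years,
            "sex": p.sex,
            "weight_kg": p.weight_kg,
            "bmi": p.bmi,
            "hba1c_pct": p.hba1c_pct,
            "on_insulin": p.on_insulin,
            "on_oral_meds": p.on_oral_meds,
            "duration_cat": duration_level(p.diabetes_duration_years),
            "score": b.total,
            "risk_points": b.risk_points,
        }
        for c in COMORBIDITIES:
            row[f"co_{c}"] = c in p.comorbidities
        fu = followups.get(p.patient_id)
        if fu is not None:
            row["pct_weight_decrease"] = (
                pct_change(p.weight_kg, fu.weight_kg)
                if p.weight_kg
                else np.nan
            )
            row["pct_hba1c_improvement"] = pct_change(p.hba1c_pct, fu.hba1c_pct)
            row["no_meds_12m"] = not (fu.on_insulin or fu.on_oral_meds)
            row["oral_discontinued"] = p.on_oral_meds and not fu.on_oral_meds
            row["insulin_discontinued"] = p.on_insulin and not fu.on_insulin
            remission = classify_remission(fu)
            row["remission"] = remission if remission is not None else np.nan
            if fu.aqol_pre is not None and fu.aqol_post is not None:
                row["aqol_pre"] = fu.aqol_pre
                row["aqol_change"] = fu.aqol_post - fu.aqol_pre
            row["n_adverse_events"] = len(fu.adverse_events)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StrataTable:
    bins: tuple[tuple[int, int], ...]
    table: pd.DataFrame  # one row per non-empty bin
    tests: Mapping[str, tuple[float, float]]  # variable -> (statistic, p)
    n_unbinned: int
    empty_bins: tuple[tuple[int, int], ...] = ()


def _bin_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}"


def assign_bins(
    scores: pd.Series, bins: Sequence[tuple[int, int]]
) -> pd.Series:
    """Bin label per score (inclusive integer intervals), NaN if unbinned."""
    out = pd.Series(pd.NA, index=scores.index, dtype="object")
    for lo, hi in bins:
        mask = (scores >= lo) & (scores <= hi)
        out[mask] = _bin_label(lo, hi)
    return out


def stratify(
    df: pd.DataFrame,
    bins: Sequence[tuple[int, int]] = DEFAULT_BINS,
) -> StrataTable:
    """Per-bin descriptives plus across-bin tests (ANOVA for means,
    chi-square for proportions).  Empty bins are dropped from the table
    and from every test, with a warning."""
    bins = tuple((int(lo), int(hi)) for lo, hi in bins)
    df = df.copy()
    df["bin"] = assign_bins(df["score"], bins)
    n_unbinned = int(df["bin"].isna().sum())
    if n_unbinned:
        logger.warning("%d scores fall outside the bin grid", n_unbinned)
    binned = df.dropna(subset=["bin"])
    present = [b for b in bins if _bin_label(*b) in set(binned["bin"])]
    empty = tuple(b for b in bins if b not in present)
    if empty:
        logger.warning("empty score bins: %s", empty)

    rows = []
    for lo, hi in present:
        g = binned[binned["bin"] == _bin_label(lo, hi)]
        row: dict[str, object] = {
            "bin": _bin_label(lo, hi),
            "n": len(g),
        }
        for var in ("age_years", "weight_kg", "bmi", "hba1c_pct"):
            row[f"{var}_mean"] = g[var].mean()
            row[f"{var}_sd"] = g[var].std(ddof=1)
        row["female_prop"] = (g["sex"] == "female").mean()
        row["insulin_prop"] = g["on_insulin"].mean()
        row["oral_meds_prop"] = g["on_oral_meds"].mean()
        for cat in ("lt4y", "4to8y", "gt8y"):
            row[f"duration_{cat}_prop"] = (g["duration_cat"] == cat).mean()
        for c in COMORBIDITIES:
            row[f"co_{c}_prop"] = g[f"co_{c}"].mean()
        for out in (
            "pct_weight_decrease",
            "pct_hba1c_improvement",
            "oral_discontinued",
            "insulin_discontinued",
            "remission",
            "aqol_change",
        ):
            if out in g.columns:
                vals = g[out].dropna()
                row[f"{out}_mean"] = (
                    float(np.mean(vals.astype(float))) if len(vals) else np.nan
                )
                row[f"{out}_n"] = len(vals)
        rows.append(row)
    table = pd.DataFrame(rows)

    tests: dict[str, tuple[float, float]] = {}
    groups = [
        binned[binned["bin"] == _bin_label(lo, hi)] for lo, hi in present
    ]
    testable = [g for g in groups if len(g) >= 2]
    if len(testable) >= 2:
        cont_vars = ["age_years", "weight_kg", "bmi", "hba1c_pct"]
        for out in ("pct_weight_decrease", "pct_hba1c_improvement", "aqol_change"):
            if out in binned.columns:
                cont_vars.append(out)
        for var in cont_vars:
            samples = [
                g[var].dropna().astype(float) for g in testable
            ]
            samples = [s for s in samples if len(s) >= 2]
            if len(samples) >= 2:
                stat, p = stats.f_oneway(*samples)
                tests[var] = (float(stat), float(p))
        cat_vars = [("sex", lambda g: (g["sex"] == "female"))]
        for flag in ("on_insulin", "on_oral_meds", "oral_discontinued", "remission"):
            if flag in binned.columns:
                cat_vars.append((flag, lambda g, f=flag: g[f].dropna().astype(bool)))
        for c in COMORBIDITIES:
            cat_vars.append((f"co_{c}", lambda g, f=f"co_{c}": g[f]))
        for name, getter in cat_vars:
            contingency = []
            for g in testable:
                vals = getter(g)
                contingency.append([int(vals.sum()), int((~vals).sum())])
            ct = np.array([r for r in contingency if sum(r) > 0])
            if len(ct) >= 2 and ct.sum(axis=0).min() > 0:
                try:
                    stat, p = stats.chi2_contingency(ct, correction=False)[:2]
                    tests[name] = (float(stat), float(p))
                except ValueError:
                    pass
    return StrataTable(
        bins=bins,
        table=table,
        tests=tests,
        n_unbinned=n_unbinned,
        empty_bins=empty,
    )


@dataclass(frozen=True)
class CutpointResult:
    variable: str
    cutoff: float
    group_stats: pd.DataFrame  # rows: below / above
    p_values: Mapping[str, float | None]
    tests_skipped: bool = False


def cutpoint_analysis(
    df: pd.DataFrame,
    variable: str,
    cutoffs: Sequence[float],
) -> list[CutpointResult]:
    """Two-group outcome comparison at each cutoff: group [min, cut) vs
    [cut, inf).  Means compared by Welch t-test, the no-medications
    proportion by Pearson chi-square without continuity correction."""
    col = {"age": "age_years", "bmi": "bmi"}.get(variable)
    if col is None:
        raise ValidationError("cutpoint variable must be 'age' or 'bmi'")
    needed = ["pct_weight_decrease", "pct_hba1c_improvement", "no_meds_12m"]
    cc = df.dropna(subset=[c for c in needed if c in df.columns])
    results = []
    for cut in cutoffs:
        below = cc[cc[col] < cut]
        above = cc[cc[col] >= cut]
        rows = []
        for label, g in (("below", below), ("above", above)):
            rows.append(
                {
                    "group": label,
                    "n": len(g),
                    "pct_bmi_decrease_mean": g["pct_weight_decrease"].mean(),
                    "pct_bmi_decrease_sd": g["pct_weight_decrease"].std(ddof=1),
                    "pct_hba1c_improvement_mean": g["pct_hba1c_improvement"].mean(),
                    "pct_hba1c_improvement_sd": g["pct_hba1c_improvement"].std(ddof=1),
                    "no_meds_n": int(g["no_meds_12m"].sum()),
                    "no_meds_pct": 100.0 * g["no_meds_12m"].mean()
                    if len(g)
                    else np.nan,
                }
            )
        skipped = len(below) < 2 or len(above) < 2
        p_values: dict[str, float | None] = {}
        if skipped:
            logger.warning(
                "%s cutoff %s: a group has n < 2, tests skipped", variable, cut
            )
            p_values = {
                "pct_bmi_decrease": None,
                "pct_hba1c_improvement": None,
                "no_meds": None,
            }
        else:
            for key, c in (
                ("pct_bmi_decrease", "pct_weight_decrease"),
                ("pct_hba1c_improvement", "pct_hba1c_improvement"),
            ):
                _, p = stats.ttest_ind(
                    below[c].dropna(), above[c].dropna(), equal_var=False
                )
                p_values[key] = float(p)
            ct = np.array(
                [
                    [int(below["no_meds_12m"].sum()), int((~below["no_meds_12m"].astype(bool)).sum())],
                    [int(above["no_meds_12m"].sum()), int((~above["no_meds_12m"].astype(bool)).sum())],
                ]
            )
            if ct.sum(axis=0).min() > 0:
                _, p = stats.chi2_contingency(ct, correction=False)[:2]
                p_values["no_meds"] = float(p)
            else:
                p_values["no_meds"] = None
        results.append(
            CutpointResult(
                variable=variable,
                cutoff=float(cut),
                group_stats=pd.DataFrame(rows),
                p_values=p_values,
                tests_skipped=skipped,
            )
        )
    return results


def remission_report(df: pd.DataFrame, threshold: int = 50) -> dict:
    """Remission proportions overall and split at a score threshold."""
    if "remission" not in df.columns:
        raise BaptError("no remission outcomes in the cohort table")
    cc = df.dropna(subset=["remission"])
    if cc.empty:
        raise BaptError("no classifiable remission records")
    above = cc[cc["score"] >= threshold]
    below = cc[cc["score"] < threshold]

    def _prop(g):
        return {
            "n": int(len(g)),
            "remissions": int(g["remission"].astype(bool).sum()),
            "proportion": float(g["remission"].astype(bool).mean())
            if len(g)
            else None,
        }

    return {
        "threshold": int(threshold),
        "overall": _prop(cc),
        "above": _prop(above),
        "below": _prop(below),
        "n_indeterminate": int(df["remission"].isna().sum()),
    }


MID_AQOL = 0.06


def aqol_summary(df: pd.DataFrame, split_score: int = 40) -> dict:
    """Quality-of-life change by score group versus the 0.06 minimum
    important difference (group mean >= MID counts as met)."""
    if "aqol_change" not in df.columns:
        raise BaptError("no quality-of-life utilities in the cohort table")
    cc = df.dropna(subset=["aqol_change", "aqol_pre"])
    n_excluded = int(len(df) - len(cc))
    low = cc[cc["score"] < split_score]
    high = cc[cc["score"] >= split_score]

    def _grp(g):
        return {
            "n": int(len(g)),
            "pre_mean": float(g["aqol_pre"].mean()) if len(g) else None,
            "change_mean": float(g["aqol_change"].mean()) if len(g) else None,
            "change_sd": float(g["aqol_change"].std(ddof=1))
            if len(g) > 1
            else None,
            "mid_met": bool(g["aqol_change"].mean() >= MID_AQOL)
            if len(g)
            else None,
        }

    p = None
    if len(low) >= 2 and len(high) >= 2:
        _, p = stats.ttest_ind(
            low["aqol_change"], high["aqol_change"], equal_var=False
        )
        p = float(p)
    return {
        "split_score": int(split_score),
        "mid": MID_AQOL,
        "below": _grp(low),
        "above": _grp(high),
        "p": p,
        "n_excluded_missing": n_excluded,
    }


def analyze(
    df: pd.DataFrame,
    out_dir: str | Path,
    *,
    bins: Sequence[tuple[int, int]] = DEFAULT_BINS,
    remission_threshold: int = 50,
    aqol_split: int = 40,
) -> dict:
    """Run the full evaluation and write strata.csv, cutpoints.csv,
    remission.json, aqol.json and summary.txt into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    strata = stratify(df, bins=bins)
    strata.table.to_csv(out / "strata.csv", index=False)

    cut_rows = []
    cut_results = []
    for variable, cutoffs in (("age", AGE_CUTOFFS), ("bmi", BMI_CUTOFFS)):
        for res in cutpoint_analysis(df, variable, cutoffs):
            cut_results.append(res)
            for _, row in res.group_stats.iterrows():
                r = {"variable": res.variable, "cutoff": res.cutoff}
                r.update(row.to_dict())
                for key, p in res.p_values.items():
                    r[f"p_{key}"] = p
                cut_rows.append(r)
    pd.DataFrame(cut_rows).to_csv(out / "cutpoints.csv", index=False)

    remission = remission_report(df, threshold=remission_threshold)
    (out / "remission.json").write_text(json.dumps(remission, indent=2) + "\n")
    aqol = aqol_summary(df, split_score=aqol_split)
    (out / "aqol.json").write_text(json.dumps(aqol, indent=2) + "\n")

    lines = [
        f"cohort n = {len(df)}",
        f"score range observed: {int(df['score'].min())}-{int(df['score'].max())}",
        f"unbinned scores: {strata.n_unbinned}",
        "",
        "across-bin tests (statistic, p):",
    ]
    for var, (stat, p) in sorted(strata.tests.items()):
        lines.append(f"  {var}: {stat:.3f}, p={p:.4g}")
    lines += [
        "",
        f"remission overall: {remission['overall']['proportion']:.3f} "
        f"(>= {remission['threshold']}: {remission['above']['proportion']}, "
        f"< {remission['threshold']}: {remission['below']['proportion']})",
        f"AQoL change mean: below {aqol['below']['change_mean']} / "
        f"above {aqol['above']['change_mean']} (MID {MID_AQOL})",
    ]
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return {
        "strata": strata,
        "cutpoints": cut_results,
        "remission": remission,
        "aqol": aqol,
    }
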