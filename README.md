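# bapt

Toolkit around an additive points instrument for assessing and
prioritising bariatric-surgery referrals in patients with type 2
diabetes.  It covers the instrument's whole lifecycle:

* **instrument** — data model for criteria / ordered levels / points,
  config and patient-table I/O, plus the canonical shipped instrument
  (`bapt_v1`, criterion maxima 30/20/15/15/20).
* **elicitation** — adaptive pairwise (PAPRIKA-style) preference
  elicitation over the 972-state health-state space: dominance pruning,
  two-criterion trade-off questions, additive-consistency propagation and
  transitive closure, with contradiction detection and replayable JSONL
  session logs.
* **weights** — max-margin linear-programming recovery of per-level
  weights from a respondent's judgements, across-respondent aggregation,
  the comorbidity rescaling that turns the elicited 9-level attribute
  into additive per-comorbidity points, draft rounding against the
  canonical table, and brute-force verification of the instrument's
  achievable score range.
* **screening** — eligibility screen (age 18–65, BMI > 35, HbA1c > 7%
  despite treatment, ≥ 1 reversible comorbidity, ASA IV exclusion),
  per-criterion score breakdowns, surgical-risk factor counting and
  diabetes-remission classification (HbA1c < 6.5% off all
  glucose-lowering medication).
* **cohort** — seeded synthetic referral cohorts and 12-month outcomes
  emulating the published marginal structure and qualitative outcome
  trends, so the whole pipeline is exercisable without clinical data.
* **analysis** — score-bin stratification with chi-square / one-way
  ANOVA, age and BMI cut-point comparisons (Welch t-test; Pearson
  chi-square without continuity correction), remission rates split at a
  score threshold, and quality-of-life change against the 0.06 minimum
  important difference.

## Command line

```bash
# simulate an elicitation session against known weights, then derive them back
bapt elicit --respondent r1 --simulate truth.json --out session.jsonl
bapt derive-weights --session session.jsonl --out weights.json
bapt aggregate --weights w1.json --weights w2.json --out agg.json

# the instrument's achievable range (brute-force enumeration)
bapt score-range                # couplings honoured: 2-98
bapt score-range --uncoupled    # free level combinations: 0-100

# synthetic cohort -> screening/scoring -> full outcome report
bapt simulate-cohort --seed 1 --n 292 --out cohort.csv
bapt eligibility --patients cohort.csv
bapt score --patients cohort.csv --out scores.csv
bapt analyze --cohort cohort.csv --out report/
```

`bapt elicit --interactive` asks the trade-off questions at the
terminal instead of simulating a respondent.

## Notes on reconstructed conventions

* The canonical rounded points are shipped as constants: the development
  committee deliberately moved several values away from nearest-integer
  rounding (e.g. the 40–<45 BMI band, normalised 8.63, is printed as 10),
  so recomputing them would produce a different instrument.
  `bapt.weights.draft_rounding` reports exactly which rows diverge.
* The 2–98 score range holds only under cross-criterion couplings that
  an internally consistent patient cannot escape: hypertension counts as
  both comorbidity and risk factor, BMI ≥ 50 fills the top BMI band and
  a risk factor, age drives its band and the 45+ factor, and eligibility
  requires at least one comorbidity.  `score_range` proves both this and
  the uncoupled 0–100 envelope by enumeration; the enumeration is
  inference, shipped with its verification test.
* Category boundaries (half-open BMI bands, duration [0,4) / [4,8] /
  (8,∞), age bands at 30 and 50 with an exact-age 45+ risk factor) are
  documented in `bapt.screening`.
* The original tool's question-ordering heuristic is proprietary; the
  replacement (greedy undecided-degree, lexicographic tie-break) is
  documented in `bapt.elicitation` and swappable.
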