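import itertools

import numpy as np
import pytest

from bapt.elicitation import (
    A_PREFERRED,
    B_PREFERRED,
    INDIFFERENT,
    PROV_JUDGED,
    PROV_TRANSITIVITY,
    ChoiceTask,
    Judgement,
    PreferenceStore,
    StateVector,
    candidate_tasks,
    dominates,
    enumerate_states,
    next_task,
    read_session,
    run_session,
    simulate_respondent,
)
from bapt.canonical import panel_mean_weights
from bapt.errors import InconsistencyError, ValidationError
from bapt.instrument import SINGLE_SELECT, CriterionSpec, Instrument
from bapt.weights import LevelWeights

from conftest import make_truth


def _task(instrument, a, b):
    names = instrument.criterion_names
    differing = frozenset(
        names[c] for c in range(len(names)) if a[c] != b[c]
    )
    return ChoiceTask(a=StateVector(a), b=StateVector(b), differing=differing)


@pytest.fixture(scope="module")
def canonical_session(canonical):
    """One full simulated session on the canonical instrument (reused)."""
    truth = make_truth(canonical, seed=123)
    result = run_session(
        canonical,
        lambda t: simulate_respondent(truth, t),
        respondent_id="sim",
    )
    return truth, result


class TestEnumerateStates:
    def test_canonical_has_972_states(self, canonical):
        assert len(enumerate_states(canonical)) == 972

    def test_two_binary_has_4_states(self, two_binary):
        states = enumerate_states(two_binary)
        assert [s.levels for s in states] == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_single_criterion(self):
        inst = Instrument(
            "one",
            (CriterionSpec("c", ("l0", "l1", "l2"), SINGLE_SELECT,
                           {"l0": 0, "l1": 1, "l2": 2}),),
        )
        assert len(enumerate_states(inst)) == 3

    def test_lexicographic_order(self, small):
        states = [s.levels for s in enumerate_states(small)]
        assert states == sorted(states)


class TestDominates:
    def test_all_best_dominates_all_worst(self, canonical):
        states = enumerate_states(canonical)
        assert dominates(states[-1], states[0], canonical)
        assert not dominates(states[0], states[-1], canonical)

    def test_strictness(self, canonical):
        s = enumerate_states(canonical)[5]
        assert not dominates(s, s, canonical)

    def test_mixed_not_dominating(self, two_binary):
        a, b = StateVector((1, 0)), StateVector((0, 1))
        assert not dominates(a, b, two_binary)
        assert not dominates(b, a, two_binary)

    def test_mismatched_criteria_error(self, two_binary):
        with pytest.raises(ValidationError):
            dominates(StateVector((1, 0, 0)), StateVector((0, 1)), two_binary)


class TestCandidateTasks:
    def test_two_binary_single_task(self, two_binary):
        tasks = candidate_tasks(two_binary)
        assert len(tasks) == 1
        assert {tasks[0].a.levels, tasks[0].b.levels} == {(0, 1), (1, 0)}
        assert tasks[0].differing == {"x", "y"}

    def test_single_criterion_empty(self):
        inst = Instrument(
            "one",
            (CriterionSpec("c", ("l0", "l1"), SINGLE_SELECT, {"l0": 0, "l1": 1}),),
        )
        assert candidate_tasks(inst) == []

    def test_canonical_count_matches_brute_force(self, canonical):
        # independent O(n^2) oracle: scan every unordered state pair
        states = enumerate_states(canonical)
        count = 0
        for a, b in itertools.combinations(states, 2):
            n_diff = sum(x != y for x, y in zip(a.levels, b.levels))
            if n_diff != 2:
                continue
            if dominates(a, b, canonical) or dominates(b, a, canonical):
                continue
            count += 1
        assert len(candidate_tasks(canonical)) == count

    def test_no_task_is_dominating(self, small):
        for t in candidate_tasks(small):
            assert not dominates(t.a, t.b, small)
            assert not dominates(t.b, t.a, small)
            assert len(t.differing) == 2


class TestRecordJudgement:
    def test_transitivity_provenance(self, small):
        store = PreferenceStore(small)
        # three pairwise-incomparable states: (2,0,0), (0,1,0), (0,0,2)
        A, B, C = StateVector((2, 0, 0)), StateVector((0, 1, 0)), StateVector((0, 0, 2))
        store.record_judgement(
            Judgement(_task(small, A.levels, B.levels), A_PREFERRED, sequence_no=1)
        )
        store.record_judgement(
            Judgement(_task(small, B.levels, C.levels), A_PREFERRED, sequence_no=2)
        )
        assert store.relation(A, C) == "a_strict"
        assert store.provenance(A, C) == PROV_TRANSITIVITY

    def test_direct_cycle_raises(self, small):
        store = PreferenceStore(small)
        A, B = (2, 0, 0), (0, 1, 0)
        store.record_judgement(
            Judgement(_task(small, A, B), A_PREFERRED, sequence_no=1)
        )
        with pytest.raises(ValidationError):
            # same pair again is rejected as already decided
            store.record_judgement(
                Judgement(_task(small, A, B), B_PREFERRED, sequence_no=2)
            )

    def _contradictory_setup(self, small):
        """Two judgements implying (via transitivity) that the a0->a1 gap
        beats the b gap in the c=1 context; judging the same trade-off the
        other way in the c=0 context then contradicts its propagation."""
        store = PreferenceStore(small)
        store.record_judgement(  # a-gap beats the upper c-gap
            Judgement(_task(small, (1, 0, 1), (0, 0, 2)), A_PREFERRED, sequence_no=1)
        )
        store.record_judgement(  # the upper c-gap beats the b-gap
            Judgement(_task(small, (0, 0, 2), (0, 1, 1)), A_PREFERRED, sequence_no=2)
        )
        return store

    def test_cycle_through_propagation_raises_with_chain(self, small):
        store = self._contradictory_setup(small)
        with pytest.raises(InconsistencyError) as exc:
            store.record_judgement(
                Judgement(_task(small, (1, 0, 0), (0, 1, 0)), B_PREFERRED,
                          sequence_no=3)
            )
        assert len(exc.value.chain) >= 2  # the offending preference chain

    def test_store_rolled_back_after_inconsistency(self, small):
        store = self._contradictory_setup(small)
        before = store.P.copy()
        with pytest.raises(InconsistencyError):
            store.record_judgement(
                Judgement(_task(small, (1, 0, 0), (0, 1, 0)), B_PREFERRED,
                          sequence_no=3)
            )
        assert np.array_equal(store.P, before)
        assert store.n_judged == 2

    def test_indifference_chains_into_strict(self, small):
        store = PreferenceStore(small)
        A, B, C = (2, 0, 0), (0, 1, 0), (0, 0, 2)
        store.record_judgement(Judgement(_task(small, A, B), INDIFFERENT, sequence_no=1))
        store.record_judgement(Judgement(_task(small, B, C), A_PREFERRED, sequence_no=2))
        assert store.relation(StateVector(A), StateVector(C)) == "a_strict"

    def test_mixed_closure_matches_floyd_warshall(self, small, truth_factory):
        """Pure-transitivity closure equals an independent Floyd-Warshall."""
        truth = truth_factory(small, seed=7)
        states = enumerate_states(small)
        n = len(states)
        store = PreferenceStore(small)
        # seed oracle with dominance
        W = np.zeros((n, n), dtype=bool)
        np.fill_diagonal(W, True)
        for i, a in enumerate(states):
            for j, b in enumerate(states):
                if dominates(a, b, small):
                    W[i, j] = True
        rng = np.random.default_rng(3)
        tasks = candidate_tasks(small)
        order = rng.permutation(len(tasks))
        applied = 0
        for k in order[:10]:
            t = tasks[k]
            if store.decided(t.a, t.b):
                continue
            verdict = simulate_respondent(truth, t)
            store.record_judgement(
                Judgement(t, verdict, sequence_no=applied + 1), propagate=False
            )
            i, j = store.index[t.a.levels], store.index[t.b.levels]
            if verdict == A_PREFERRED:
                W[i, j] = True
            elif verdict == B_PREFERRED:
                W[j, i] = True
            else:
                W[i, j] = W[j, i] = True
            applied += 1
        # Floyd-Warshall closure of the oracle
        for k in range(n):
            W |= np.outer(W[:, k], W[k, :])
        assert np.array_equal(store.P, W)


class TestNextTask:
    def test_fresh_two_binary_returns_the_trade_off(self, two_binary):
        store = PreferenceStore(two_binary)
        task = next_task(store)
        assert {task.a.levels, task.b.levels} == {(0, 1), (1, 0)}

    def test_done_after_all_decided(self, two_binary):
        store = PreferenceStore(two_binary)
        task = next_task(store)
        store.record_judgement(Judgement(task, A_PREFERRED, sequence_no=1))
        assert next_task(store) is None

    def test_never_returns_decided_task(self, small, truth_factory):
        truth = truth_factory(small, seed=11)
        store = PreferenceStore(small)
        seq = 0
        while True:
            task = next_task(store)
            if task is None:
                break
            assert not store.decided(task.a, task.b)
            seq += 1
            store.record_judgement(
                Judgement(task, simulate_respondent(truth, task), sequence_no=seq)
            )

    def test_conservation_on_canonical_session(self, canonical_session):
        _truth, result = canonical_session
        cov = result.store.candidate_coverage()
        assert cov["undecided"] == 0
        decided = (
            cov["judged"] + cov["dominance"] + cov["consistency"]
            + cov["transitivity"]
        )
        assert decided == cov["total_candidates"] == 24786
        assert cov["judged"] == result.n_questions

    def test_question_efficiency(self, canonical_session):
        _truth, result = canonical_session
        cov = result.store.candidate_coverage()
        assert result.n_questions <= 0.2 * cov["total_candidates"]

    def test_decided_pairs_agree_with_truth(self, canonical_session):
        truth, result = canonical_session
        store = result.store
        rng = np.random.default_rng(0)
        states = store.states
        for _ in range(2000):
            i, j = rng.integers(len(states), size=2)
            if i == j:
                continue
            rel = store.relation(states[i], states[j])
            if rel is None:
                continue
            diff = truth.state_total(states[i]) - truth.state_total(states[j])
            if rel == "a_strict":
                assert diff > 0
            elif rel == "b_strict":
                assert diff < 0


class TestSimulateRespondent:
    def test_dominant_preference(self, two_binary, truth_factory):
        truth = truth_factory(two_binary, seed=1)
        task = ChoiceTask(
            a=StateVector((1, 1)), b=StateVector((0, 0)),
            differing=frozenset({"x", "y"}),
        )
        assert simulate_respondent(truth, task) == A_PREFERRED

    def test_equal_totals_indifferent(self, two_binary):
        w = LevelWeights(
            "flat", {"x": (0.0, 50.0), "y": (0.0, 50.0)}, order=("x", "y")
        )
        task = ChoiceTask(
            a=StateVector((1, 0)), b=StateVector((0, 1)),
            differing=frozenset({"x", "y"}),
        )
        assert simulate_respondent(w, task, tie_tol=0.0) == INDIFFERENT

    def test_panel_mean_weights_trade_off(self, canonical):
        # OSA with long-standing diabetes vs hypertension with recent onset:
        # (30.28 - 8.72) - (19.92 - 0) = +1.64 favours the OSA state
        w = LevelWeights(
            "panel", panel_mean_weights(), order=canonical.criterion_names
        )
        a = StateVector((8, 0, 0, 0, 0))  # osa, >8y
        b = StateVector((1, 2, 0, 0, 0))  # hypertension, <4y
        task = ChoiceTask(a=a, b=b, differing=frozenset({"comorbidity", "duration"}))
        assert simulate_respondent(w, task) == A_PREFERRED
        assert w.state_total(a) - w.state_total(b) == pytest.approx(1.64)


class TestSessionDeterminism:
    def test_same_seed_identical_transcript(self, small):
        def transcript(seed):
            truth = make_truth(small, seed=seed)
            res = run_session(small, lambda t: simulate_respondent(truth, t))
            return [
                (j.task.a.levels, j.task.b.levels, j.verdict)
                for j in res.judgements
            ]

        assert transcript(5) == transcript(5)
        assert transcript(5) != transcript(6)

    def test_session_log_round_trip(self, small, tmp_path):
        truth = make_truth(small, seed=9)
        log = tmp_path / "session.jsonl"
        res = run_session(
            small, lambda t: simulate_respondent(truth, t),
            respondent_id="r9", log_path=log,
        )
        judgements = read_session(log, small)
        assert len(judgements) == res.n_questions
        for orig, back in zip(res.judgements, judgements):
            assert back.task.a == orig.task.a
            assert back.task.b == orig.task.b
            assert back.verdict == orig.verdict
            assert back.respondent_id == "r9"

    def test_forced_choice_has_no_indifference(self, small):
        w = LevelWeights(
            "tied",
            {"a": (0.0, 1.0, 2.0), "b": (0.0, 1.0), "c": (0.0, 1.0, 2.0)},
            order=("a", "b", "c"),
        )
        res = run_session(
            small, lambda t: simulate_respondent(w, t), forced_choice=True
        )
        assert all(j.verdict != INDIFFERENT for j in res.judgements)
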