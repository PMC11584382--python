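"""Adaptive pairwise elicitation over the instrument's health-state space.

The engine enumerates all health states (one level per criterion), seeds a
preference relation with Pareto dominance, and repeatedly asks the
respondent to rank two states that differ on exactly two criteria and are
not mutually dominating.  Each answer is propagated two ways:

* *additive consistency* -- a trade-off between two criteria is context
  free under an additive value model, so the same verdict is applied to
  the same level swap in every context of the remaining criteria;
* *transitivity* -- the preference relation is kept reflexively and
  transitively closed after every accepted judgement.

Contradictory judgements are rejected with the offending preference chain;
the store is never left in an inconsistent state.

Question selection (the published tool's heuristic is proprietary) is a
documented greedy rule: ask the undecided candidate pair whose two states
touch the largest number of currently undecided candidate pairs, breaking
ties by lexicographic state order.  It is deterministic and swappable via
the ``selector`` argument of :func:`next_task`.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import InconsistencyError, ValidationError
from .instrument import Instrument

A_PREFERRED = "a_preferred"
B_PREFERRED = "b_preferred"
INDIFFERENT = "indifferent"
VERDICTS = (A_PREFERRED, B_PREFERRED, INDIFFERENT)

PROV_JUDGED = "judged"
PROV_DOMINANCE = "dominance"
PROV_CONSISTENCY = "consistency"
PROV_TRANSITIVITY = "transitivity"


@dataclass(frozen=True)
class StateVector:
    """One level index per criterion, instrument order, 0 = worst."""

    levels: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(int(x) for x in self.levels))

    def as_mapping(self, instrument: Instrument) -> dict[str, int]:
        return dict(zip(instrument.criterion_names, self.levels))

    @classmethod
    def from_mapping(
        cls, instrument: Instrument, mapping: dict[str, int]
    ) -> "StateVector":
        return cls(tuple(mapping[c] for c in instrument.criterion_names))


@dataclass(frozen=True)
class ChoiceTask:
    """A pairwise question: which of states ``a`` and ``b`` ranks higher?"""

    a: StateVector
    b: StateVector
    differing: frozenset[str]

    def __post_init__(self):
        if self.a == self.b:
            raise ValidationError("choice task states must differ")
        object.__setattr__(self, "differing", frozenset(self.differing))


@dataclass(frozen=True)
class Judgement:
    task: ChoiceTask
    verdict: str
    respondent_id: str = "anonymous"
    sequence_no: int = 0

    def __post_init__(self):
        if self.verdict not in VERDICTS:
            raise ValidationError(f"unknown verdict {self.verdict!r}")


def enumerate_states(instrument: Instrument) -> list[StateVector]:
    """Full Cartesian product of level indices, lexicographic order."""
    ranges = [range(n) for n in instrument.level_counts]
    return [StateVector(t) for t in itertools.product(*ranges)]


def _check_same_shape(instrument: Instrument, *states: StateVector) -> None:
    n = len(instrument.criteria)
    for s in states:
        if len(s.levels) != n:
            raise ValidationError(
                f"state {s.levels} does not match the instrument's "
                f"{n} criteria"
            )
        for lv, count in zip(s.levels, instrument.level_counts):
            if not 0 <= lv < count:
                raise ValidationError(f"level index out of range in {s.levels}")


def dominates(a: StateVector, b: StateVector, instrument: Instrument) -> bool:
    """Pareto dominance: ``a`` at least as good everywhere, better somewhere."""
    _check_same_shape(instrument, a, b)
    ge = all(x >= y for x, y in zip(a.levels, b.levels))
    return ge and a.levels != b.levels


def _state_matrix(instrument: Instrument) -> np.ndarray:
    return np.array(
        [s.levels for s in enumerate_states(instrument)], dtype=np.int16
    )


def _candidate_index_pairs(instrument: Instrument) -> np.ndarray:
    """(k, 2) array of state-index pairs (i < j) differing on exactly two
    criteria with neither state dominating the other."""
    S = _state_matrix(instrument)
    n = len(S)
    neq = S[:, None, :] != S[None, :, :]
    diffcount = neq.sum(axis=2)
    ge = (S[:, None, :] >= S[None, :, :]).all(axis=2)
    dom_either = ge | ge.T  # one weakly dominates the other
    cand = (diffcount == 2) & ~dom_either
    iu = np.triu_indices(n, k=1)
    mask = cand[iu]
    return np.column_stack([iu[0][mask], iu[1][mask]])


def candidate_tasks(instrument: Instrument) -> list[ChoiceTask]:
    """All primary choice tasks, in deterministic lexicographic state order."""
    states = enumerate_states(instrument)
    names = instrument.criterion_names
    pairs = _candidate_index_pairs(instrument)
    tasks = []
    for i, j in pairs:
        a, b = states[i], states[j]
        differing = frozenset(
            names[c] for c in range(len(names)) if a.levels[c] != b.levels[c]
        )
        tasks.append(ChoiceTask(a=a, b=b, differing=differing))
    return tasks


class PreferenceStore:
    """Transitively closed preference relation over all health states.

    Internals: ``P`` is the reflexive-transitive closure of the
    at-least-as-good relation; ``C`` marks strict commitments (ordered
    pairs that must never be reversed: dominance, strict judgements and
    their consistency propagations).  The relation is consistent iff no
    strict commitment's reverse is in ``P``.
    """

    def __init__(self, instrument: Instrument):
        self.instrument = instrument
        self.states = enumerate_states(instrument)
        self.index = {s.levels: i for i, s in enumerate(self.states)}
        n = len(self.states)
        S = _state_matrix(instrument)
        ge = (S[:, None, :] >= S[None, :, :]).all(axis=2)
        self.P = ge.copy()  # dominance (incl. diagonal) is transitively closed
        self.C = ge & ~ge.T  # strict dominance commitments
        self._dom = self.C.copy()
        # base edges for chain reconstruction (judged + propagated only;
        # dominance edges are queried from self._dom on demand)
        self._adj: dict[int, set[int]] = {}
        self.judged_strict: dict[tuple[int, int], int] = {}
        self.judged_indiff: dict[frozenset[int], int] = {}
        self.propagated_strict: set[tuple[int, int]] = set()
        self.propagated_indiff: set[frozenset[int]] = set()
        self._cand = _candidate_index_pairs(instrument)

    # -- queries ---------------------------------------------------------

    def _idx(self, s: StateVector) -> int:
        _check_same_shape(self.instrument, s)
        return self.index[s.levels]

    def relation(self, a: StateVector, b: StateVector) -> str | None:
        """'a_strict', 'b_strict', 'indifferent' or None (undecided)."""
        i, j = self._idx(a), self._idx(b)
        fwd, bwd = self.P[i, j], self.P[j, i]
        if fwd and bwd:
            return INDIFFERENT if i != j else INDIFFERENT
        if fwd:
            return "a_strict"
        if bwd:
            return "b_strict"
        return None

    def decided(self, a: StateVector, b: StateVector) -> bool:
        return self.relation(a, b) is not None

    def provenance(self, a: StateVector, b: StateVector) -> str | None:
        """How the (a, b) pair came to be decided."""
        i, j = self._idx(a), self._idx(b)
        if not (self.P[i, j] or self.P[j, i]):
            return None
        if (i, j) in self.judged_strict or (j, i) in self.judged_strict:
            return PROV_JUDGED
        if frozenset((i, j)) in self.judged_indiff:
            return PROV_JUDGED
        if self._dom[i, j] or self._dom[j, i]:
            return PROV_DOMINANCE
        if (i, j) in self.propagated_strict or (j, i) in self.propagated_strict:
            return PROV_CONSISTENCY
        if frozenset((i, j)) in self.propagated_indiff:
            return PROV_CONSISTENCY
        return PROV_TRANSITIVITY

    @property
    def n_judged(self) -> int:
        return len(self.judged_strict) + len(self.judged_indiff)

    # -- closure mechanics ----------------------------------------------

    def _add_weak_edge(self, u: int, v: int) -> None:
        if self.P[u, v]:
            return
        anc = self.P[:, u]
        desc = self.P[v, :]
        self.P[np.ix_(anc, desc)] = True

    def _consistent(self) -> tuple[int, int] | None:
        """Return a violated strict commitment (x, y) with y >= x in P."""
        bad = self.C & self.P.T
        if not bad.any():
            return None
        x, y = np.argwhere(bad)[0]
        return int(x), int(y)

    def _record_base_edge(self, u: int, v: int, both: bool) -> None:
        self._adj.setdefault(u, set()).add(v)
        if both:
            self._adj.setdefault(v, set()).add(u)

    def _chain(self, src: int, dst: int) -> list[StateVector]:
        """Shortest preference chain src >= ... >= dst over base + dominance
        edges, for inconsistency reporting."""
        if src == dst:
            return [self.states[src]]
        parent = {src: None}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                neighbours = set(self._adj.get(u, ()))
                neighbours.update(np.flatnonzero(self._dom[u]).tolist())
                for v in neighbours:
                    if v in parent:
                        continue
                    parent[v] = u
                    if v == dst:
                        path, node = [], v
                        while node is not None:
                            path.append(node)
                            node = parent[node]
                        return [self.states[k] for k in reversed(path)]
                    nxt.append(v)
            frontier = nxt
        return [self.states[src], self.states[dst]]

    def _contexts(self, task: ChoiceTask) -> list[tuple[int, int]]:
        """Index pairs for the task's level swap in every context of the
        non-differing criteria (additive-consistency propagation)."""
        names = self.instrument.criterion_names
        diff_idx = [c for c in range(len(names)) if names[c] in task.differing]
        fixed_idx = [c for c in range(len(names)) if c not in diff_idx]
        out = []
        ranges = [range(self.instrument.level_counts[c]) for c in fixed_idx]
        a, b = list(task.a.levels), list(task.b.levels)
        for combo in itertools.product(*ranges):
            xa, xb = a[:], b[:]
            for c, lv in zip(fixed_idx, combo):
                xa[c] = lv
                xb[c] = lv
            out.append((self.index[tuple(xa)], self.index[tuple(xb)]))
        return out

    # -- mutation --------------------------------------------------------

    def record_judgement(
        self, judgement: Judgement, *, propagate: bool = True
    ) -> "PreferenceStore":
        """Add a judgement, propagate and re-close; raise on contradiction.

        On :class:`InconsistencyError` the store is rolled back to its
        state before the call.
        """
        task = judgement.task
        i, j = self._idx(task.a), self._idx(task.b)
        if i == j:
            raise ValidationError("cannot judge a state against itself")
        if self.P[i, j] or self.P[j, i]:
            raise ValidationError(
                "task already decided in the store; ask next_task() for an "
                "undecided one"
            )
        contexts = self._contexts(task) if propagate else [(i, j)]

        P_snap, C_snap = self.P.copy(), self.C.copy()
        adj_snap = {k: set(v) for k, v in self._adj.items()}
        ps_snap = set(self.propagated_strict)
        pi_snap = set(self.propagated_indiff)
        try:
            if judgement.verdict == INDIFFERENT:
                self.judged_indiff[frozenset((i, j))] = judgement.sequence_no
                for u, v in contexts:
                    if (u, v) != (i, j):
                        self.propagated_indiff.add(frozenset((u, v)))
                    self._record_base_edge(u, v, both=True)
                    self._add_weak_edge(u, v)
                    self._add_weak_edge(v, u)
            else:
                if judgement.verdict == B_PREFERRED:
                    contexts = [(v, u) for u, v in contexts]
                    i, j = j, i
                self.judged_strict[(i, j)] = judgement.sequence_no
                for u, v in contexts:
                    if (u, v) != (i, j):
                        self.propagated_strict.add((u, v))
                    self.C[u, v] = True
                    self._record_base_edge(u, v, both=False)
                    self._add_weak_edge(u, v)
            bad = self._consistent()
            if bad is not None:
                x, y = bad
                chain = self._chain(y, x)
                raise InconsistencyError(
                    f"judgement {judgement.verdict!r} on states "
                    f"{task.a.levels} vs {task.b.levels} contradicts the "
                    f"existing preference chain "
                    f"{' >= '.join(str(s.levels) for s in chain)} "
                    f"(while {self.states[x].levels} must rank strictly "
                    f"above {self.states[y].levels})",
                    chain=chain,
                )
        except InconsistencyError:
            self.P, self.C = P_snap, C_snap
            self._adj = adj_snap
            self.propagated_strict = ps_snap
            self.propagated_indiff = pi_snap
            self.judged_strict.pop((i, j), None)
            self.judged_indiff.pop(frozenset((i, j)), None)
            raise
        return self

    # -- candidate bookkeeping ------------------------------------------

    def undecided_candidates(self) -> np.ndarray:
        ii, jj = self._cand[:, 0], self._cand[:, 1]
        undecided = ~(self.P[ii, jj] | self.P[jj, ii])
        return self._cand[undecided]

    def candidate_coverage(self) -> dict[str, int]:
        """Provenance tally over all candidate (two-criterion) pairs."""
        counts = {
            PROV_JUDGED: 0,
            PROV_DOMINANCE: 0,
            PROV_CONSISTENCY: 0,
            PROV_TRANSITIVITY: 0,
            "undecided": 0,
        }
        for i, j in self._cand:
            prov = self.provenance(self.states[i], self.states[j])
            counts[prov if prov is not None else "undecided"] += 1
        counts["total_candidates"] = len(self._cand)
        return counts

    def make_task(self, i: int, j: int) -> ChoiceTask:
        names = self.instrument.criterion_names
        a, b = self.states[i], self.states[j]
        differing = frozenset(
            names[c] for c in range(len(names)) if a.levels[c] != b.levels[c]
        )
        return ChoiceTask(a=a, b=b, differing=differing)


def _greedy_degree_selector(
    store: PreferenceStore, undecided: np.ndarray
) -> int:
    """Pick the undecided pair maximising undecided-pair degree of its two
    states; ties resolve to the lexicographically first pair."""
    n = len(store.states)
    deg = np.bincount(undecided.ravel(), minlength=n)
    score = deg[undecided[:, 0]] + deg[undecided[:, 1]]
    return int(np.argmax(score))


def next_task(
    store: PreferenceStore,
    selector: Callable[[PreferenceStore, np.ndarray], int] | None = None,
) -> ChoiceTask | None:
    """The next informative question, or None when everything is decided."""
    undecided = store.undecided_candidates()
    if len(undecided) == 0:
        return None
    pick = (selector or _greedy_degree_selector)(store, undecided)
    i, j = undecided[pick]
    return store.make_task(int(i), int(j))


def simulate_respondent(
    true_weights, task: ChoiceTask, tie_tol: float = 0.0
) -> str:
    """Verdict of an additive-value respondent with known level weights."""
    va = true_weights.state_total(task.a)
    vb = true_weights.state_total(task.b)
    if va - vb > tie_tol:
        return A_PREFERRED
    if vb - va > tie_tol:
        return B_PREFERRED
    return INDIFFERENT


@dataclass
class SessionResult:
    store: PreferenceStore
    judgements: list[Judgement]
    respondent_id: str

    @property
    def n_questions(self) -> int:
        return len(self.judgements)


def run_session(
    instrument: Instrument,
    answer: Callable[[ChoiceTask], str],
    *,
    respondent_id: str = "anonymous",
    forced_choice: bool = False,
    propagate: bool = True,
    max_questions: int | None = None,
    log_path: str | Path | None = None,
) -> SessionResult:
    """Drive a full adaptive session until no candidate pair is undecided.

    ``answer`` maps a :class:`ChoiceTask` to a verdict (an interactive
    prompt, or :func:`simulate_respondent` bound to truth weights).  With
    ``forced_choice`` an indifferent answer is coerced to ``a_preferred``,
    mirroring elicitation designs that forbid ties.
    """
    store = PreferenceStore(instrument)
    judgements: list[Judgement] = []
    writer = _SessionWriter(log_path) if log_path else None
    seq = 0
    while True:
        if max_questions is not None and seq >= max_questions:
            break
        task = next_task(store)
        if task is None:
            break
        verdict = answer(task)
        if forced_choice and verdict == INDIFFERENT:
            verdict = A_PREFERRED
        seq += 1
        judgement = Judgement(
            task=task,
            verdict=verdict,
            respondent_id=respondent_id,
            sequence_no=seq,
        )
        store.record_judgement(judgement, propagate=propagate)
        judgements.append(judgement)
        if writer:
            writer.write(judgement, store)
    if writer:
        writer.close()
    return SessionResult(store=store, judgements=judgements, respondent_id=respondent_id)


class _SessionWriter:
    """Append-only JSONL session log with a chained provenance hash."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._fh = open(self.path, "w")
        self._hash = hashlib.sha256(b"bapt-session-v1").hexdigest()

    def write(self, judgement: Judgement, store: PreferenceStore) -> None:
        core = {
            "seq": judgement.sequence_no,
            "respondent": judgement.respondent_id,
            "state_a": list(judgement.task.a.levels),
            "state_b": list(judgement.task.b.levels),
            "verdict": judgement.verdict,
        }
        payload = json.dumps(core, sort_keys=True) + self._hash
        self._hash = hashlib.sha256(payload.encode()).hexdigest()
        core["provenance_snapshot_hash"] = self._hash
        self._fh.write(json.dumps(core, sort_keys=True) + "\n")

    def close(self) -> None:
        self._fh.close()


def read_session(
    path: str | Path, instrument: Instrument
) -> list[Judgement]:
    """Replay a JSONL session log into judgement objects."""
    names = instrument.criterion_names
    judgements = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        a = StateVector(tuple(rec["state_a"]))
        b = StateVector(tuple(rec["state_b"]))
        differing = frozenset(
            names[c] for c in range(len(names)) if a.levels[c] != b.levels[c]
        )
        judgements.append(
            Judgement(
                task=ChoiceTask(a=a, b=b, differing=differing),
                verdict=rec["verdict"],
                respondent_id=rec.get("respondent", "anonymous"),
                sequence_no=int(rec["seq"]),
            )
        )
    return judgements
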