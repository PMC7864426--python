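"""Transfer as completion: free M-sets and information-trial inference.

Once the monoid underlying a task series has been induced, a new task is
learned not by rote but by completion: a single observed cue-target feedback
event (an information trial) propagates through the monoid's multiplication
to predict unseen cue-targets.  Formally the completion device is the free
M-set on the new stimulus set — the left adjoint of the forgetful functor —
and the learner's remaining uncertainty is a set of hypotheses about which
cue shape denotes which monoid element and how the fresh stimuli are ordered
on the carrier.  Trials eliminate hypotheses; a cue-target is *determined*
when every surviving hypothesis predicts the same target for it.

The combinatorial analyses here are exhaustive: every hypothesis, every
trial subset, and (in effect) every cue ordering is enumerated, so the
reported minimum/maximum information-trial counts are exact.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .finite_algebra import Monoid
from .mset import MSetRep, SizeCapError

__all__ = [
    "FreeMSet",
    "InformationTrial",
    "Hypothesis",
    "HypothesisSet",
    "TrialAnalysis",
    "InconsistentTrialsError",
    "free_mset",
    "unit_embedding",
    "infer",
    "hypothesis_table",
    "trials_to_determination",
    "expected_first_trial_errors",
]

#: Cap on the hypothesis space enumerated by :func:`infer`.
DEFAULT_MAX_HYPOTHESES = 200_000
#: Largest cue set for which the full ordering distribution is computed.
DEFAULT_MAX_CUES = 12


class InconsistentTrialsError(ValueError):
    """Raised when a trial contradicts every remaining hypothesis."""

    def __init__(self, trial: "InformationTrial", position: int):
        self.trial = trial
        self.position = position
        super().__init__(
            f"trial {position} ({trial.shape!r}, {trial.stimulus!r}) -> "
            f"{trial.target!r} contradicts every remaining hypothesis"
        )


@dataclass(frozen=True)
class InformationTrial:
    """One observed cue-target feedback event."""

    shape: object
    stimulus: object
    target: object


@dataclass(frozen=True)
class FreeMSet:
    """The free M-set on a base set: carrier M x S, action by left multiplication.

    The unit row ``(e, s)`` embeds the base; the action
    ``a . (b, s) = (a*b, s)`` is how one observed assignment propagates:
    knowing that some cue acts as ``b`` on ``s`` yields the target of every
    composite ``a*b`` on ``s`` for free.
    """

    monoid: Monoid
    base: tuple
    rep: MSetRep

    @property
    def carrier(self) -> tuple:
        return self.rep.carrier


def free_mset(m: Monoid, base: Sequence) -> FreeMSet:
    base = tuple(base)
    if not base:
        raise ValueError("the base set of a free M-set must be non-empty")
    carrier = tuple((a, s) for a in m.elements for s in base)
    action = tuple(
        tuple((m.mul(a, b), s) for (b, s) in carrier) for a in m.elements
    )
    return FreeMSet(m, base, MSetRep(m, carrier, action))


def unit_embedding(fm: FreeMSet) -> dict:
    """The adjunction unit: each base element to its unit-row pair."""
    return {s: (fm.monoid.unit, s) for s in fm.base}


@dataclass(frozen=True)
class Hypothesis:
    """One candidate reading of a new task.

    ``assignment`` maps each cue shape to the monoid element it denotes;
    ``realization`` maps each stimulus to the carrier position (monoid
    element) it occupies in the regular representation.
    """

    assignment: tuple  # sorted (shape, element) pairs
    realization: tuple  # (stimulus, element) pairs in stimulus order

    def assignment_dict(self) -> dict:
        return dict(self.assignment)

    def realization_dict(self) -> dict:
        return dict(self.realization)


@dataclass(frozen=True)
class HypothesisSet:
    """Hypotheses consistent with the observed trials, plus what they pin down.

    ``determined_cues`` maps each (shape, stimulus) cue on which *all*
    surviving hypotheses agree to the common predicted target; it grows
    monotonically as trials are added.
    """

    monoid: Monoid
    shapes: tuple
    stimuli: tuple
    hypotheses: tuple
    determined_cues: dict

    def __len__(self) -> int:
        return len(self.hypotheses)


def hypothesis_table(
    m: Monoid, shapes: Sequence, stimuli: Sequence, assignment: Mapping, realization: Mapping
) -> dict:
    """The full cue-target table a hypothesis predicts.

    ``target(shape, s) = r^-1(assignment(shape) * r(s))`` — the regular
    action read through the stimulus ordering ``r``.
    """
    inv = {e: s for s, e in realization.items()}
    return {
        (sh, s): inv[m.mul(assignment[sh], realization[s])]
        for sh in shapes
        for s in stimuli
    }


def _normalize_constraints(m: Monoid, shapes: tuple, constraints) -> list[tuple]:
    if constraints is None:
        return [m.elements for _ in shapes]
    if isinstance(constraints, Mapping):
        out = []
        for sh in shapes:
            pool = constraints.get(sh)
            out.append(m.elements if pool is None else tuple(pool))
        return out
    pool = tuple(constraints)
    return [pool for _ in shapes]


def _enumerate_hypotheses(
    m: Monoid,
    shapes: tuple,
    stimuli: tuple,
    constraints,
    max_hypotheses: int,
) -> list[Hypothesis]:
    if len(stimuli) != len(m.elements):
        raise ValueError(
            f"need exactly {len(m.elements)} stimuli to order the carrier, got {len(stimuli)}"
        )
    allowed = _normalize_constraints(m, shapes, constraints)
    for sh, pool in zip(shapes, allowed):
        for e in pool:
            m.index(e)  # raises on unknown element
    union = set().union(*map(set, allowed)) if allowed else set()
    # distinct shapes denote distinct actions whenever the cue vocabulary
    # is as large as the candidate action pool (the paradigm's full tasks
    # and stated-subset partial tasks); smaller vocabularies leave
    # injectivity open
    injective = len(shapes) == len(union)
    n_assign = math.prod(len(pool) for pool in allowed) if allowed else 1
    total = n_assign * math.factorial(len(m.elements))
    if total > max_hypotheses:
        raise SizeCapError(
            f"{total} candidate hypotheses exceed cap {max_hypotheses}"
        )
    out = []
    for values in itertools.product(*allowed) if allowed else [()]:
        if injective and len(set(values)) != len(values):
            continue
        assignment = tuple(zip(shapes, values))
        for perm in itertools.permutations(m.elements):
            out.append(Hypothesis(assignment, tuple(zip(stimuli, perm))))
    return out


def infer(
    m: Monoid,
    shapes: Sequence,
    stimuli: Sequence,
    trials: Sequence[InformationTrial],
    constraints=None,
    max_hypotheses: int = DEFAULT_MAX_HYPOTHESES,
) -> HypothesisSet:
    """Eliminate hypotheses against observed trials and collect determinations.

    ``constraints`` restricts which monoid elements the shapes may denote:
    an iterable applies one pool to every shape, a mapping gives per-shape
    pools (use singletons when cue meanings carry over from earlier tasks).
    Contradictory trials raise :class:`InconsistentTrialsError` naming the
    first contradicted trial — under the paradigm's consistent condition a
    realizable task always admits at least one hypothesis.
    """
    shapes, stimuli = tuple(shapes), tuple(stimuli)
    vocab = set(stimuli)
    for k, t in enumerate(trials):
        if t.shape not in shapes:
            raise ValueError(f"trial {k} uses unknown shape {t.shape!r}")
        if t.stimulus not in vocab or t.target not in vocab:
            raise ValueError(f"trial {k} uses a symbol outside the stimulus vocabulary")
    survivors = _enumerate_hypotheses(m, shapes, stimuli, constraints, max_hypotheses)
    tables = {h: hypothesis_table(m, shapes, stimuli, h.assignment_dict(), h.realization_dict()) for h in survivors}
    for k, t in enumerate(trials):
        survivors = [h for h in survivors if tables[h][(t.shape, t.stimulus)] == t.target]
        if not survivors:
            raise InconsistentTrialsError(t, k)
    determined = {}
    for cue in ((sh, s) for sh in shapes for s in stimuli):
        predictions = {tables[h][cue] for h in survivors}
        if len(predictions) == 1:
            determined[cue] = next(iter(predictions))
    return HypothesisSet(m, shapes, stimuli, tuple(survivors), determined)


@dataclass(frozen=True)
class TrialAnalysis:
    """Exact information-trial statistics for one task shape.

    For the ``all-orderings`` policy, ``histogram[k]`` counts the cue
    orderings (out of ``n_cues!``) whose full table first becomes determined
    after exactly ``k`` trials; ``min_trials``/``max_trials`` bound that
    count.  For ``distinct-shapes``, the pair fields report how many
    two-trial combinations with distinct cue shapes determine the table.
    """

    policy: str
    n_cues: int
    min_trials: Optional[int] = None
    max_trials: Optional[int] = None
    histogram: Optional[dict] = None
    n_orderings: Optional[int] = None
    n_pairs: Optional[int] = None
    n_pairs_determined: Optional[int] = None
    all_pairs_determine: Optional[bool] = None
    determined_at: Optional[int] = None


def _cue_tables(m: Monoid, task, constraints, max_hypotheses: int):
    shapes, stimuli = tuple(task.shapes), tuple(task.stimuli)
    cues = [(sh, s) for sh in shapes for s in stimuli]
    hyps = _enumerate_hypotheses(m, shapes, stimuli, constraints, max_hypotheses)
    tables = []
    for h in hyps:
        t = hypothesis_table(m, shapes, stimuli, h.assignment_dict(), h.realization_dict())
        tables.append(tuple(t[c] for c in cues))
    truth = tuple(task.table[c] for c in cues)
    if truth not in tables:
        raise ValueError("task table is not realizable under the given constraints")
    return cues, tables, truth


def _full_determination(tables, truth, n_cues):
    """Bitmask lookup: is the whole table pinned down by each trial subset?"""
    det = [False] * (1 << n_cues)
    for mask in range(1 << n_cues):
        sel = [i for i in range(n_cues) if mask >> i & 1]
        survivor_tables = {
            tab for tab in tables if all(tab[i] == truth[i] for i in sel)
        }
        det[mask] = len(survivor_tables) == 1
    return det


def trials_to_determination(
    m: Monoid,
    task,
    policy: str = "all-orderings",
    constraints=None,
    sequence: Optional[Sequence] = None,
    max_cues: int = DEFAULT_MAX_CUES,
    max_hypotheses: int = DEFAULT_MAX_HYPOTHESES,
) -> TrialAnalysis:
    """How many without-replacement information trials pin down a task.

    ``task`` supplies the cue/stimulus vocabularies and the ground-truth
    table from which trial feedback is read.  Policies:

    - ``all-orderings``: the exact distribution, over every permutation of
      the cue set, of the prefix length after which the full table is
      determined (counted by enumerating trial subsets, which carry all the
      ordering information).
    - ``distinct-shapes``: every two-trial combination whose cues use two
      different shapes, reporting how many determine the full table.
    - ``given-sequence``: the determination point of one explicit cue
      sequence.
    - ``min-subset``: smallest determining trial set only, by growing
      subset search (usable above the all-orderings cue cap).
    """
    cues, tables, truth = _cue_tables(m, task, constraints, max_hypotheses)
    n = len(cues)
    cue_index = {c: i for i, c in enumerate(cues)}

    if policy == "min-subset":
        for k in range(n + 1):
            for combo in itertools.combinations(range(n), k):
                sel = set(combo)
                survivor_tables = {
                    tab
                    for tab in tables
                    if all(tab[i] == truth[i] for i in sel)
                }
                if len(survivor_tables) == 1:
                    return TrialAnalysis(policy=policy, n_cues=n, min_trials=k)
        raise RuntimeError("unreachable: the full cue set always determines")

    if policy == "given-sequence":
        if sequence is None:
            raise ValueError("given-sequence policy requires a cue sequence")
        seen: set = set()
        det = None
        survivor_tables = set(tables)
        if len(survivor_tables) == 1:
            det = 0
        for k, cue in enumerate(sequence, start=1):
            i = cue_index[cue]
            seen.add(i)
            survivor_tables = {t for t in survivor_tables if t[i] == truth[i]}
            if det is None and len(survivor_tables) == 1:
                det = k
        return TrialAnalysis(policy=policy, n_cues=n, determined_at=det)

    if n > max_cues:
        raise SizeCapError(
            f"{n} cues exceed the ordering-analysis cap {max_cues}; use min-subset"
        )
    det = _full_determination(tables, truth, n)

    if policy == "distinct-shapes":
        n_pairs = n_det = 0
        for i, j in itertools.combinations(range(n), 2):
            if cues[i][0] == cues[j][0]:
                continue
            n_pairs += 1
            if det[(1 << i) | (1 << j)]:
                n_det += 1
        return TrialAnalysis(
            policy=policy,
            n_cues=n,
            n_pairs=n_pairs,
            n_pairs_determined=n_det,
            all_pairs_determine=(n_det == n_pairs),
        )

    if policy != "all-orderings":
        raise ValueError(f"unknown policy {policy!r}")

    if det[0]:
        return TrialAnalysis(
            policy=policy,
            n_cues=n,
            min_trials=0,
            max_trials=0,
            histogram={0: math.factorial(n)},
            n_orderings=math.factorial(n),
        )
    # an ordering determines at exactly k when its k-prefix set is
    # determined but the (k-1)-prefix is not; counting over subsets gives
    # the exact per-ordering histogram
    histogram: dict[int, int] = {}
    min_trials = None
    max_undet = 0
    for mask in range(1 << n):
        k = mask.bit_count()
        if det[mask]:
            if min_trials is None or k < min_trials:
                min_trials = k
            ways = sum(1 for i in range(n) if mask >> i & 1 and not det[mask & ~(1 << i)])
            if ways:
                histogram[k] = histogram.get(k, 0) + ways * math.factorial(k - 1) * math.factorial(n - k)
        else:
            max_undet = max(max_undet, k)
    max_trials = max_undet + 1
    assert sum(histogram.values()) == math.factorial(n)
    return TrialAnalysis(
        policy=policy,
        n_cues=n,
        min_trials=min_trials,
        max_trials=max_trials,
        histogram=dict(sorted(histogram.items())),
        n_orderings=math.factorial(n),
    )


def expected_first_trial_errors(
    m: Monoid,
    task,
    assumption: str = "chance",
    constraints=None,
    max_hypotheses: int = DEFAULT_MAX_HYPOTHESES,
) -> float:
    """Expected first-pass response errors on one task.

    ``chance``: every cue is answered uniformly at random over the stimulus
    vocabulary, giving ``n_cues * (1 - 1/n_stimuli)`` (two-thirds of nine
    trials for a 3x3 task).

    ``ideal-learner``: exact expectation over uniformly random
    without-replacement cue orderings for a learner who knows the monoid,
    answers a cue correctly as soon as it is determined by the trials seen
    so far, and guesses uniformly otherwise.
    """
    n_stim = len(task.stimuli)
    n_cues = len(task.shapes) * n_stim
    chance_p = 1.0 - 1.0 / n_stim
    if assumption == "chance":
        return n_cues * chance_p
    if assumption != "ideal-learner":
        raise ValueError(f"unknown assumption {assumption!r}")
    cues, tables, truth = _cue_tables(m, task, constraints, max_hypotheses)
    n = len(cues)
    if n > DEFAULT_MAX_CUES:
        raise SizeCapError(f"{n} cues exceed the ordering-analysis cap")
    expected = 0.0
    for mask in range(1 << n):
        k = mask.bit_count()
        if k == n:
            continue
        sel = [i for i in range(n) if mask >> i & 1]
        survivors = [tab for tab in tables if all(tab[i] == truth[i] for i in sel)]
        weight = 1.0 / (math.comb(n, k) * (n - k))
        for c in range(n):
            if mask >> c & 1:
                continue
            if len({tab[c] for tab in survivors}) > 1:
                expected += weight * chance_p
    return expected
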