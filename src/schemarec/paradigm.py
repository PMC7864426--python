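"""Experiment-shaped task series and the end-to-end ideal-learner simulation.

Generates consistent-condition series: every task instantiates the same
monoid on a fresh cue and stimulus vocabulary (shape symbols and CVC
trigrams), with the shape-to-element assignment hidden from the learner.
The simulator then plays an ideal relational learner through the series:
the first task is answered at chance, later tasks reuse the monoid
reconstructed from all earlier tasks (component closure + the end of the
task diagram) and answer each cue correctly as soon as the information
trials seen so far determine it.
"""

from __future__ import annotations

import math
import random
import statistics
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .finite_algebra import (
    Endomap,
    Monoid,
    close_under_composition,
    find_isomorphism,
    make_cyclic_monoid,
)
from .mset import MSetRep, validate_action
from .reconstruction import EndResult, build_task_diagram, compute_end
from .transfer import hypothesis_table, _enumerate_hypotheses, DEFAULT_MAX_HYPOTHESES

__all__ = [
    "TaskInstance",
    "ExperimentSeries",
    "SimulationReport",
    "generate_series",
    "task_components",
    "task_to_mset",
    "reconstruct_schema",
    "simulate_ideal_learner",
    "match_to_sample_variant",
]

SHAPE_POOL = tuple(
    "△☐♡♠♣★⊕♢⊡◼●⋈☼▲▽◇○◎✦✧✚☾♯♭⊗⊘⊙⊚⊞⊟⊠◐◑◒◓⬟⬠⬡⬢◻◈◉⟡⟐"
)
_CONSONANTS = "BCDFGHJKLMNPQRSTVWXZ"
_VOWELS = "AEIOU"


class VocabularyExhaustedError(RuntimeError):
    """Raised when the symbol pools cannot supply fresh vocabulary."""


@dataclass(frozen=True)
class TaskInstance:
    """One cue-target learning task as the participant sees it.

    ``table[(shape, stimulus)]`` is the target stimulus.  The hidden
    assignment (which monoid element each shape denotes) and the element
    pool it was drawn from are ground truth withheld from learners.
    """

    shapes: tuple
    stimuli: tuple
    table: dict = field(hash=False)
    hidden_assignment: Optional[dict] = field(default=None, hash=False)
    element_pool: Optional[tuple] = None


@dataclass(frozen=True)
class ExperimentSeries:
    """An ordered consistent-condition task series over one monoid."""

    monoid: Monoid
    tasks: tuple
    condition: str = "consistent"


@dataclass(frozen=True)
class SimulationReport:
    """Per-task first-trial error statistics of the simulated learner."""

    seed: int
    n_replicates: int
    errors: tuple  # errors[k] = list of error counts per replicate for task k
    means: tuple
    sds: tuple
    schema_sizes: tuple  # |apex| of the schema available entering each task


def _fresh_trigrams(rng: random.Random, n: int, used: set) -> list[str]:
    pool_size = len(_CONSONANTS) * len(_VOWELS) * len(_CONSONANTS)
    if len(used) + n > pool_size:
        raise VocabularyExhaustedError("trigram vocabulary exhausted")
    out: list[str] = []
    while len(out) < n:
        t = (
            rng.choice(_CONSONANTS) + rng.choice(_VOWELS) + rng.choice(_CONSONANTS)
        )
        if t not in used:
            used.add(t)
            out.append(t)
    return out


def generate_series(
    m: Monoid,
    n_tasks: int,
    shapes_per_task: int,
    stimuli_per_task: int,
    element_subset: Optional[Sequence] = None,
    seed: int = 0,
    shared_shapes: bool = False,
) -> ExperimentSeries:
    """Build a reproducible consistent-condition series.

    Each task realizes the regular representation of ``m`` on fresh
    trigram stimuli through a random carrier ordering, with cue shapes
    assigned (injectively, uniformly) to elements of ``element_subset``
    (default: all elements).  ``shared_shapes=True`` reuses the same shape
    symbols *and* the same assignment in every task — the learning-set
    variant where only the stimulus ordering is new.
    """
    pool = tuple(element_subset) if element_subset is not None else m.elements
    for e in pool:
        m.index(e)
    if shapes_per_task > len(pool):
        raise ValueError(
            f"{shapes_per_task} shapes cannot denote distinct elements of a pool of {len(pool)}"
        )
    if stimuli_per_task != len(m.elements):
        raise ValueError(
            f"regular-representation tasks need exactly {len(m.elements)} stimuli per task"
        )
    rng = random.Random(seed)
    used_trigrams: set = set()
    shape_cursor = 0
    tasks = []
    shared: Optional[tuple] = None
    shared_assignment: Optional[dict] = None
    for _ in range(n_tasks):
        if shared_shapes and shared is not None:
            shapes, assignment = shared, dict(shared_assignment)
        else:
            if shape_cursor + shapes_per_task > len(SHAPE_POOL):
                raise VocabularyExhaustedError("shape symbol pool exhausted")
            shapes = tuple(SHAPE_POOL[shape_cursor : shape_cursor + shapes_per_task])
            shape_cursor += shapes_per_task
            assignment = dict(zip(shapes, rng.sample(pool, shapes_per_task)))
            if shared_shapes:
                shared, shared_assignment = shapes, dict(assignment)
        stimuli = tuple(_fresh_trigrams(rng, stimuli_per_task, used_trigrams))
        realization = dict(zip(stimuli, rng.sample(m.elements, len(m.elements))))
        table = hypothesis_table(m, shapes, stimuli, assignment, realization)
        tasks.append(
            TaskInstance(shapes, stimuli, table, dict(assignment), pool)
        )
    return ExperimentSeries(m, tuple(tasks))


def task_components(task: TaskInstance) -> dict:
    """The observed stimulus transformations, one endomap per cue shape."""
    return {
        sh: Endomap(task.stimuli, tuple(task.table[(sh, s)] for s in task.stimuli))
        for sh in task.shapes
    }


def task_to_mset(task: TaskInstance, monoid: Monoid) -> MSetRep:
    """The lawful M-set a task realizes through its hidden assignment."""
    if task.hidden_assignment is None:
        raise ValueError("task carries no hidden assignment")
    inv = {e: s for s, e in _realization_from_truth(task, monoid).items()}
    action = {
        a: {s: inv[monoid.mul(a, _realization_from_truth(task, monoid)[s])] for s in task.stimuli}
        for a in monoid.elements
    }
    return MSetRep.from_mapping(monoid, task.stimuli, action)


def _realization_from_truth(task: TaskInstance, monoid: Monoid) -> dict:
    # recover the carrier ordering from the hidden assignment and the table
    comps = task_components(task)
    hyps = _enumerate_hypotheses(
        monoid, task.shapes, task.stimuli, None, DEFAULT_MAX_HYPOTHESES
    )
    for h in hyps:
        if h.assignment_dict() != task.hidden_assignment:
            continue
        table = hypothesis_table(
            monoid, task.shapes, task.stimuli, h.assignment_dict(), h.realization_dict()
        )
        if table == task.table:
            return h.realization_dict()
    raise ValueError("task table does not realize its hidden assignment")


def reconstruct_schema(
    series: ExperimentSeries, upto: int
) -> tuple[EndResult, tuple]:
    """Learner-side schema induction from the first ``upto`` tasks.

    Each task's observed components are closed under composition into a
    transformation monoid; the monoids are aligned (they are isomorphic
    under the consistent condition) onto the first task's labels, the full
    diagram of equivariant maps is built, and its end is computed.  Also
    returns, for each apex element, whether some task presented it as an
    explicit cue — the pool of actions a new task's shapes may denote.
    """
    if upto < 1:
        raise ValueError("schema reconstruction needs at least one learned task")
    learned = series.tasks[:upto]
    closures = [close_under_composition(task_components(t)) for t in learned]
    base_monoid = closures[0][0]
    reps = []
    for k, (mon, assignment) in enumerate(closures):
        iso = find_isomorphism(base_monoid, mon)
        if iso is None:
            raise ValueError(
                f"task {k} does not instantiate the same schema as task 0"
            )
        action = tuple(assignment[iso[a]].images for a in base_monoid.elements)
        reps.append(MSetRep(base_monoid, learned[k].stimuli, action))
    end = compute_end(build_task_diagram(reps))
    shape_endos = [
        {c.images for c in task_components(t).values()} for t in learned
    ]
    denoted = tuple(
        d
        for d in end.wedge.apex
        if any(
            end.tuples[d][i].images in shape_endos[i] for i in range(len(learned))
        )
    )
    return end, denoted


def simulate_ideal_learner(
    series: ExperimentSeries, seed: int = 0, n_replicates: int = 200
) -> SimulationReport:
    """First-trial errors per task for a perfect-memory relational learner.

    Task 1 is answered at chance (uniform over that task's stimuli).  Before
    each later task the learner reconstructs the monoid from all earlier
    tasks; within the task, cues arrive in a random without-replacement
    order, each response is the determined target if the trials so far pin
    it down and a uniform guess otherwise, and feedback is retained
    perfectly.  Identical seeds give identical reports.
    """
    rng = random.Random(seed)
    all_errors: list[list[int]] = []
    schema_sizes: list[int] = []
    for k, task in enumerate(series.tasks):
        cues = [(sh, s) for sh in task.shapes for s in task.stimuli]
        truth = task.table
        if k == 0:
            schema_sizes.append(0)
            errs = []
            for _ in range(n_replicates):
                e = sum(
                    1
                    for cue in cues
                    if rng.choice(task.stimuli) != truth[cue]
                )
                errs.append(e)
            all_errors.append(errs)
            continue
        end, denoted = reconstruct_schema(series, k)
        schema = end.induced_monoid
        pool = denoted if task.element_pool is not None and len(
            task.element_pool
        ) < len(schema) else None
        hyps = _enumerate_hypotheses(
            schema, task.shapes, task.stimuli, pool, DEFAULT_MAX_HYPOTHESES
        )
        tables = [
            hypothesis_table(
                schema, task.shapes, task.stimuli, h.assignment_dict(), h.realization_dict()
            )
            for h in hyps
        ]
        schema_sizes.append(len(schema))
        errs = []
        for _ in range(n_replicates):
            order = list(cues)
            rng.shuffle(order)
            survivors = list(tables)
            e = 0
            for cue in order:
                predictions = {t[cue] for t in survivors}
                if len(predictions) == 1:
                    response = next(iter(predictions))
                else:
                    response = rng.choice(task.stimuli)
                if response != truth[cue]:
                    e += 1
                survivors = [t for t in survivors if t[cue] == truth[cue]]
                if not survivors:
                    raise RuntimeError("learner schema inconsistent with task feedback")
            errs.append(e)
        all_errors.append(errs)
    means = tuple(statistics.fmean(e) for e in all_errors)
    sds = tuple(statistics.pstdev(e) for e in all_errors)
    return SimulationReport(
        seed, n_replicates, tuple(tuple(e) for e in all_errors), means, sds, tuple(schema_sizes)
    )


def match_to_sample_variant(seed: int = 0, n_tasks: int = 4) -> ExperimentSeries:
    """Sameness/difference as a cyclic-2 schema with stable cue symbols.

    The sameness cue acts as the identity on any stimulus pair and the
    difference cue as the swap; the same two cue symbols denote the same
    actions in every task, so only the fresh stimuli change.
    """
    return generate_series(
        make_cyclic_monoid(2),
        n_tasks,
        shapes_per_task=2,
        stimuli_per_task=2,
        seed=seed,
        shared_shapes=True,
    )
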