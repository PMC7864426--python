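"""Free M-sets, information-trial inference, and exact trial combinatorics."""

import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from schemarec import (
    InconsistentTrialsError,
    InformationTrial as Trial,
    build_task_diagram,
    compute_end,
    free_mset,
    infer,
    make_cyclic_monoid,
    make_klein_monoid,
    regular_representation,
    unit_embedding,
)
from schemarec.mset import enumerate_equivariant_maps, validate_action
from schemarec.paradigm import TaskInstance, generate_series
from schemarec.transfer import (
    expected_first_trial_errors,
    hypothesis_table,
    trials_to_determination,
)


def _task(m, shapes, stimuli, assignment, realization, pool=None):
    table = hypothesis_table(m, shapes, stimuli, assignment, realization)
    return TaskInstance(tuple(shapes), tuple(stimuli), table, dict(assignment), pool)


class TestFreeMSet:
    @pytest.mark.parametrize("n_base", [1, 2, 3])
    def test_free_action_is_lawful(self, c2, c3, c4, klein, n_base):
        base = tuple(f"s{i}" for i in range(n_base))
        for m in (c2, c3, c4, klein):
            fm = free_mset(m, base)
            assert len(fm.carrier) == len(m) * n_base
            assert validate_action(fm.rep) == []

    def test_free_on_a_point_is_the_regular_representation(self, c3):
        fm = free_mset(c3, ("DOH",))
        reg = regular_representation(c3)
        assert [p[0] for p in fm.carrier] == list(reg.carrier)
        for a in c3.elements:
            for b, s in fm.carrier:
                assert fm.rep.act(a, (b, s)) == (reg.act(a, b), s)

    def test_one_observation_propagates_through_composites(self, c3):
        # knowing the rotation sends DOH "one step" yields the two-step
        # composite's target for free: act(1, act(1, (e, DOH))) = (2, DOH)
        fm = free_mset(c3, ("DOH",))
        eta = unit_embedding(fm)
        one_step = fm.rep.act(1, eta["DOH"])
        assert one_step == (1, "DOH")
        assert fm.rep.act(1, one_step) == (2, "DOH") == fm.rep.act(2, eta["DOH"])

    def test_empty_base_rejected(self, c3):
        with pytest.raises(ValueError):
            free_mset(c3, ())

    def test_free_forgetful_unique_factorization(self, c2, c3, klein):
        """For every g: S -> R there is exactly one equivariant map from the
        free M-set on S agreeing with g along the unit embedding."""
        for m in (c2, c3, klein):
            for base in (("u",), ("u", "v")):
                fm = free_mset(m, base)
                eta = unit_embedding(fm)
                rep = regular_representation(m, tuple(f"r{i}" for i in range(len(m))))
                hom = enumerate_equivariant_maps(fm.rep, rep)
                for g_images in itertools.product(rep.carrier, repeat=len(base)):
                    g = dict(zip(base, g_images))
                    factoring = [
                        h for h in hom.maps if all(h[eta[s]] == g[s] for s in base)
                    ]
                    assert len(factoring) == 1


class TestInfer:
    def test_unit_cue_identified_from_a_fixed_point(self, c3):
        shapes, stimuli = ("P", "D", "B"), ("DOH", "MUV", "RIY")
        hs = infer(c3, shapes, stimuli, [Trial("P", "DOH", "DOH")])
        assert all(dict(h.assignment)["P"] == 0 for h in hs.hypotheses)
        assert hs.determined_cues[("P", "MUV")] == "MUV"
        assert hs.determined_cues[("P", "RIY")] == "RIY"

    def test_one_rotation_trial_determines_that_row_and_then_the_rest(self, c3):
        shapes, stimuli = ("P", "D", "B"), ("DOH", "MUV", "RIY")
        hs = infer(c3, shapes, stimuli, [Trial("D", "DOH", "MUV")])
        assert hs.determined_cues[("D", "MUV")] == "RIY"
        assert hs.determined_cues[("D", "RIY")] == "DOH"
        assert ("B", "DOH") not in hs.determined_cues
        both = infer(
            c3, shapes, stimuli, [Trial("P", "DOH", "DOH"), Trial("D", "DOH", "MUV")]
        )
        assert len(both.determined_cues) == 9
        assert both.determined_cues[("B", "DOH")] == "RIY"

    def test_two_distinct_rotation_trials_determine_the_full_table(self, c3):
        shapes, stimuli = ("C", "S", "T"), ("HUQ", "KES", "NIZ")
        hs = infer(
            c3, shapes, stimuli, [Trial("S", "KES", "NIZ"), Trial("T", "HUQ", "NIZ")]
        )
        assert len(hs.determined_cues) == 9
        non_zero = {dict(h.assignment)["S"] for h in hs.hypotheses} | {
            dict(h.assignment)["T"] for h in hs.hypotheses
        }
        assert 0 not in non_zero
        assert all(dict(h.assignment)["C"] == 0 for h in hs.hypotheses)

    def test_zero_trials_leave_everything_open(self, c3):
        hs = infer(c3, ("A", "B", "C"), ("x", "y", "z"), [])
        assert len(hs) == 36 and hs.determined_cues == {}

    def test_configural_single_trial_determines_other_three_cues(self, c2):
        shapes, stimuli = ("yellow", "brown"), ("circle", "cross")
        hs = infer(c2, shapes, stimuli, [Trial("yellow", "circle", "circle")])
        assert len(hs.determined_cues) == 4
        assert hs.determined_cues[("yellow", "cross")] == "cross"
        assert hs.determined_cues[("brown", "circle")] == "cross"

    def test_contradictory_trials_raise_naming_the_trial(self, c3):
        trials = [Trial("A", "x", "x"), Trial("A", "y", "x")]
        with pytest.raises(InconsistentTrialsError) as err:
            infer(c3, ("A", "B", "C"), ("x", "y", "z"), trials)
        assert err.value.position == 1

    def test_constraints_restrict_the_denoted_elements(self, c4):
        shapes, stimuli = ("F", "G"), ("a", "b", "c", "d")
        hs = infer(c4, shapes, stimuli, [], constraints=[1, 3])
        assigned = {dict(h.assignment)["F"] for h in hs.hypotheses}
        assert assigned == {1, 3}
        assert all(
            dict(h.assignment)["F"] != dict(h.assignment)["G"] for h in hs.hypotheses
        )

    def test_determination_agrees_under_the_reconstructed_monoid(self, c3):
        """The end's induced monoid supports the same inferences as the
        generating monoid, as universality promises."""
        end = compute_end(
            build_task_diagram(
                [
                    regular_representation(c3, ("BEH", "FUT", "PEJ")),
                    regular_representation(c3, ("HUQ", "KES", "NIZ")),
                ]
            )
        )
        induced = end.induced_monoid
        shapes, stimuli = ("P", "D", "B"), ("DOH", "MUV", "RIY")
        trials = [Trial("P", "DOH", "DOH"), Trial("D", "DOH", "MUV")]
        via_truth = infer(c3, shapes, stimuli, trials)
        via_induced = infer(induced, shapes, stimuli, trials)
        assert via_truth.determined_cues == via_induced.determined_cues


class TestSoundnessAndMonotonicity:
    def test_determined_cues_always_match_the_hidden_truth_configural(self, c2):
        """Exhaustive: every ground truth x every cue ordering of the 2x2 task."""
        shapes, stimuli = ("Y", "W"), ("o", "x")
        cues = [(sh, s) for sh in shapes for s in stimuli]
        for values in itertools.permutations(c2.elements):
            assignment = dict(zip(shapes, values))
            for perm in itertools.permutations(c2.elements):
                realization = dict(zip(stimuli, perm))
                table = hypothesis_table(c2, shapes, stimuli, assignment, realization)
                for order in itertools.permutations(cues):
                    prev: set = set()
                    for k in range(len(order) + 1):
                        trials = [
                            Trial(sh, s, table[(sh, s)]) for sh, s in order[:k]
                        ]
                        hs = infer(c2, shapes, stimuli, trials)
                        assert all(
                            hs.determined_cues[c] == table[c]
                            for c in hs.determined_cues
                        )
                        assert prev <= set(hs.determined_cues)
                        prev = set(hs.determined_cues)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.randoms(use_true_random=False))
    def test_determined_cues_sound_and_monotone_cyclic3(self, rnd):
        m = make_cyclic_monoid(3)
        shapes, stimuli = ("A", "B", "C"), ("x", "y", "z")
        assignment = dict(zip(shapes, rnd.sample(m.elements, 3)))
        realization = dict(zip(stimuli, rnd.sample(m.elements, 3)))
        table = hypothesis_table(m, shapes, stimuli, assignment, realization)
        cues = [(sh, s) for sh in shapes for s in stimuli]
        rnd.shuffle(cues)
        prev: set = set()
        for k in range(5):
            trials = [Trial(sh, s, table[(sh, s)]) for sh, s in cues[:k]]
            hs = infer(m, shapes, stimuli, trials)
            assert all(hs.determined_cues[c] == table[c] for c in hs.determined_cues)
            assert prev <= set(hs.determined_cues)
            prev = set(hs.determined_cues)


class TestTrialCombinatorics:
    def test_cyclic3_full_task_needs_two_to_four_trials(self, c3):
        task = generate_series(c3, 1, 3, 3, seed=5).tasks[0]
        a = trials_to_determination(c3, task)
        assert (a.min_trials, a.max_trials) == (2, 4)
        assert sum(a.histogram.values()) == math.factorial(9)
        assert set(a.histogram) == {2, 3, 4}

    def test_every_distinct_shape_pair_determines_the_other_seven(self, c3):
        task = generate_series(c3, 1, 3, 3, seed=6).tasks[0]
        a = trials_to_determination(c3, task, policy="distinct-shapes")
        assert a.all_pairs_determine and a.n_pairs == 27
        # spot-check the claim at the cue level: 2 observed + 7 inferred
        cues = [(sh, s) for sh in task.shapes for s in task.stimuli]
        c1, c2_ = cues[0], cues[4]
        hs = infer(
            c3,
            task.shapes,
            task.stimuli,
            [Trial(*c1, task.table[c1]), Trial(*c2_, task.table[c2_])],
        )
        assert len(hs.determined_cues) == 9

    def test_partial_quarter_turn_task_min_two_trials(self, c4):
        task = generate_series(c4, 1, 2, 4, element_subset=[1, 3], seed=7).tasks[0]
        a = trials_to_determination(c4, task, constraints=[1, 3])
        assert a.min_trials == 2
        b = trials_to_determination(c4, task, policy="min-subset", constraints=[1, 3])
        assert b.min_trials == 2

    def test_partial_reflection_task_min_two_trials(self, klein):
        task = generate_series(klein, 1, 2, 4, element_subset=[1, 2], seed=8).tasks[0]
        a = trials_to_determination(klein, task, constraints=[1, 2])
        assert a.min_trials == 2

    def test_configural_task_single_trial_always_suffices(self, c2):
        task = generate_series(c2, 1, 2, 2, seed=9).tasks[0]
        a = trials_to_determination(c2, task)
        assert (a.min_trials, a.max_trials) == (1, 1)
        assert a.histogram == {1: math.factorial(4)}

    def test_shared_cue_rotation_task_needs_one_trial(self, c3):
        """When cue symbols keep their meanings only the stimulus order is
        open: a single non-unit trial settles it."""
        series = generate_series(c3, 2, 3, 3, seed=10, shared_shapes=True)
        task = series.tasks[1]
        pinned = {sh: [e] for sh, e in task.hidden_assignment.items()}
        a = trials_to_determination(c3, task, constraints=pinned)
        assert a.min_trials == 1

    def test_shared_cue_sameness_difference_needs_no_trials(self, c2):
        """Sameness/difference on a stimulus pair is realization-invariant,
        so known cue meanings determine the table with no feedback at all."""
        series = generate_series(c2, 2, 2, 2, seed=11, shared_shapes=True)
        task = series.tasks[1]
        pinned = {sh: [e] for sh, e in task.hidden_assignment.items()}
        a = trials_to_determination(c2, task, constraints=pinned)
        assert (a.min_trials, a.max_trials) == (0, 0)

    def test_given_sequence_policy(self, c3):
        task = generate_series(c3, 1, 3, 3, seed=12).tasks[0]
        cues = [(sh, s) for sh in task.shapes for s in task.stimuli]
        a = trials_to_determination(c3, task, policy="given-sequence", sequence=cues)
        assert 2 <= a.determined_at <= 4


class TestExpectedErrors:
    def test_chance_level_is_two_thirds_of_nine(self, c3):
        task = generate_series(c3, 1, 3, 3, seed=13).tasks[0]
        assert expected_first_trial_errors(c3, task, "chance") == pytest.approx(6.0)

    def test_degenerate_single_stimulus_task_has_no_errors(self):
        m = make_cyclic_monoid(1)
        task = generate_series(m, 1, 1, 1, seed=14).tasks[0]
        assert expected_first_trial_errors(m, task, "chance") == 0.0

    def test_ideal_learner_expectation_within_information_trial_bounds(self, c3):
        task = generate_series(c3, 1, 3, 3, seed=15).tasks[0]
        value = expected_first_trial_errors(c3, task, "ideal-learner")
        assert 2 * (2 / 3) - 1e-9 <= value <= 4 * (2 / 3) + 1e-9
        # exactly two undetermined trials per ordering for this task shape
        assert value == pytest.approx(2 * (2 / 3))
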