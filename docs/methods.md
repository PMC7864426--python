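# Methods

## Model

A learning task is an M-set representation (*S*, σ): a finite monoid *M*
acting on a stimulus set *S*, with each action component σ_a the
stimulus-to-stimulus map of one cue shape. The schemas covered by the
built-in constructors are the cyclic groups Z/nZ (rotations; n = 2 doubles
as sameness/difference and configural colour-as-action tasks), the Klein
four-group (reflections), and arbitrary transformation monoids obtained by
closing observed components under composition (used when a task presents
only a subset of the schema's actions, e.g. the two quarter-turns of a
cyclic-4 task).

Induction is modelled as computing the end of the bivariate forgetful
hom-functor over the finite diagram of learned tasks. A wedge is an apex
set that selects, per apex element, one endomap on each task's carrier;
dinaturality requires every equivariant map between tasks to commute with
the selected endomaps. The end is the universal wedge: its apex elements
are exactly the distinct consistent tuples, and componentwise composition
of tuples gives the induced monoid. Transfer is modelled as completion:
given the induced monoid, the learner entertains every hypothesis
(cue-to-element assignment, stimulus-to-carrier ordering), eliminates those
contradicted by observed information trials, and answers a cue as soon as
all surviving hypotheses agree on its target.

## Conventions and design choices

- **Composition bookkeeping.** `close_under_composition` uses the
  left-action convention `table(a, b) = endomap(a) ∘ endomap(b)` (apply b,
  then a), which makes the element-to-endomap assignment a monoid
  homomorphism and matches the action compatibility law
  σ(a·b, s) = σ(a, σ(b, s)). On the end's apex, the tuples are *right*
  multiplications when a task is a regular representation, so apex
  composition is taken in diagrammatic order (apply d1's tuple, then d2's);
  this makes the induced monoid isomorphic to *M* itself rather than its
  opposite. The two conventions coincide on every commutative fixture; the
  distinction is exercised by a non-abelian transformation-monoid test
  (the symmetric group on three stimuli).

- **Two readings of "equivariant map".** `enumerate_equivariant_maps`
  defaults to the strict definition, indexed by literal monoid elements:
  between two cyclic-3 regular tasks there are exactly three such maps, and
  a task's strict self-maps number |M|. With `up_to_automorphism=True` it
  instead returns the candidate analogies available to a learner who has
  not yet resolved which cue of one task corresponds to which cue of the
  other — functions equivariant under *some* automorphism reindexing — six
  for the cyclic-3 pair. The end is computed over the strict hom-sets:
  admitting the automorphism-twisted maps to the dinaturality test would
  collapse the apex below the monoid (the twisted and untwisted constraints
  are jointly satisfiable only by the identity tuple), so the candidate
  pool is a description of the learner's search space, not of the category
  the end ranges over. A `single_map` variant of the end computation tests
  dinaturality against one fixed analogy per task pair instead of all of
  them; for diagrams of faithful group tasks the two variants provably
  agree and this is asserted in the tests.

- **Finite diagrams and faithfulness.** The end is taken over the finite
  diagram of supplied tasks, not the whole (infinite) category of M-sets.
  The reconstruction guarantee is asserted only when at least one task is a
  faithful representation (the experiments' regular-representation tasks
  are); otherwise the result is flagged as a diagram-relative end and
  `check_reconstruction` reports failure with that reason. This restriction
  is an implementation commitment of the package.

- **Search order and determinism.** Candidate components are drawn from the
  full endomap space, pruned per task by the equivariant self-maps first
  (cheapest constraint) and then joined across tasks under the cross-task
  maps, in lexicographic carrier order. Apex identifiers are 0, 1, 2, … in
  discovery order; each acceptance strictly adds one new consistent tuple,
  so the search walks the inclusion preorder of wedges monotonically from
  the empty wedge (no prior knowledge) to the terminal one. Every
  enumeration in the package iterates in a fixed order, and all stochastic
  components (fixture generation, simulation) flow through explicit integer
  seeds, so identical inputs give identical outputs.

- **Hypothesis space for transfer.** Stimulus orderings range over all
  bijections from the new task's stimuli to the monoid's elements (tasks
  are regular-representation shaped: as many stimuli as elements).
  Cue assignments range over a constraint pool — all elements by default, a
  stated subset for partial tasks, singletons when cue meanings carry over
  from earlier tasks — and are required to be injective exactly when the
  cue vocabulary is as large as the pool, mirroring the paradigm's use of
  distinct shapes for distinct actions while leaving injectivity open for
  genuinely smaller vocabularies. Contradictory trials raise an error
  naming the first contradicted trial rather than silently emptying the
  space, since consistent-condition tasks are always realizable.

- **Information-trial counting.** A trial is counted whether or not it is
  informative (cues are drawn without replacement), and determination is
  assessed at each prefix of the trial sequence. The per-ordering
  distribution is computed exactly by enumerating trial *subsets* (2^n for
  n cues) and counting, combinatorially, the orderings whose prefix first
  determines the table at each length; this is arithmetic over the same
  brute force as iterating all n! orderings, at a fraction of the cost. The
  ordering analysis is capped at 12 cues; a growing-subset search
  (`min-subset`) covers larger tasks for the minimum only.

- **Response model for expected errors.** Chance responding is uniform over
  the task's stimuli, giving n_cues · (1 − 1/n_stimuli) expected errors
  (6 for a 3×3 task). The ideal learner answers a determined cue correctly
  and guesses uniformly otherwise; its expectation is computed exactly over
  uniformly random cue orderings. This is the simplest response model
  consistent with the chance-level arithmetic; no explicit human response
  process is claimed. For the 3×3 rotation task every ordering contains
  exactly two undetermined trials (the first trial, and the first trial of
  a second shape), so the exact expectation is 2 · 2/3 = 4/3.

- **Shared-cue variants.** When the same cue symbols keep their meanings
  across tasks, only the stimulus ordering of a new task is unknown. For a
  cyclic-3 task one non-unit trial settles it (minimum 1). For the
  cyclic-2 sameness/difference pair the identity and swap actions on two
  stimuli are invariant under both orderings, so the minimum is 0 — known
  cue meanings transfer with no information trials at all. Both facts are
  computed and tested rather than assumed.

## Synthetic data

`generate_series` emulates the experiments' structure: per task, fresh
consonant–vowel–consonant trigram stimuli (sampled without replacement from
a 2000-trigram pool), fresh cue symbols from a fixed shape pool, a
uniformly random injective assignment of cues to the (possibly restricted)
element pool, and a uniformly random carrier ordering. Defaults follow the
experimental designs: four tasks; 3 shapes × 3 stimuli (9 cues) for
cyclic-3; 2 shapes × 4 stimuli (8 cues) for the partial cyclic-4 and
Klein-4 tasks; 2 × 2 for configural cyclic-2. What the generator does *not*
emulate: perceptual confusability of stimuli, memory decay, response
latencies, or within-task trial blocking (orderings are uniform without
replacement, as the learner model assumes). Passing tests therefore
establish the algebraic and combinatorial claims of the theory, not
quantitative fits to human error rates — the observed human means on later
tasks are empirical data the model only brackets (the ideal learner is a
lower bound, chance an upper one).

The ideal-learner simulation gives the learner perfect retention, chance
responding throughout the first task, and, from the second task on, the
schema reconstructed from all earlier tasks via component closure, monoid
alignment, and the end computation; cue-assignment constraints for partial
tasks are read off the apex elements that carried cues in earlier tasks.

## Problem sizes and numerical notes

All computations are exact integer/rational arithmetic over exhaustive
enumerations; there are no tolerances, iterative solvers, or floating-point
sensitivities anywhere in the core. Scales used by the tests and the
acceptance script: hom-set enumeration filters up to 6^6 = 46 656 candidate
functions (cyclic-6 regular pairs); the natural-transformation oracle
brute-forces up to 46 656 endomap tuples per diagram; ordering analyses
cover 9! = 362 880 orderings via 512 subsets; hypothesis spaces hold at
most a few thousand members; the simulation uses 200–1000 replicates.
Everything runs in seconds on one core. Degenerate inputs are defined
rather than special-cased: the empty wedge is dinatural, a one-point
carrier admits one endomap, a single-stimulus task has chance error 0, and
an empty trial list leaves every hypothesis alive.

## Known limitations

- Only left actions of finite monoids; no multi-object categories
  (the fibre-functor generalization is an extension point, not implemented).
- Exhaustive enumeration caps carriers at 8 by default; the package is a
  desk-scale model, not a combinatorics engine.
- No probabilistic or forgetful learner; the inconsistent condition can be
  generated but no behavioural predictions are made for it.
- Human error means on later tasks are not fitted; see the synthetic-data
  section for what the simulation does and does not claim.
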