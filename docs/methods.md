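# Methods

## The model

The Naive Generalization Model (NGM) treats learning the meaning of a novel
noun as forming a category representation from labeled exemplars, with no
probabilistic inference over a hypothesis space.  Three mechanisms carry all
of the behaviour:

**Salience-weighted feature storage.**  An object is a bundle of binary
features.  When a word is heard, the learner samples a salience value for
every feature present — basic-tier features (the "dog" level of
dalmatian < dog < animal) from `Normal(mu_high, sigma)`, everything else from
`Normal(mu_low, sigma)`, draws clipped to `[0, 1]`.  The stored weight of a
feature is its sampled salience summed once per co-present exemplar
possessing it, clipped at a ceiling of 1.0:

    R_w[f] = min(1, sum_{t in T, f in t} S(f)).

Salience is drawn **once per feature per word per participant** and cached on
the representation; repeated exposures never redraw it.  A feature sampled
above the *semantic incompatibility threshold* blocks features in conflict
with it (a dalmatian-feature versus a poodle-feature) from entering the
representation.  Features are processed in descending sampled salience, ties
broken by feature order; since the generator's conflict graphs are disjoint
cliques this reduces to "if the top present member of a clique exceeds the
threshold, keep only it", which is how the vectorized path computes it (the
literal sequential rule is retained for arbitrary graphs and as a test
oracle).

**Asymmetric distance membership.**  A test object `t` is compared with the
representation `r` by

    D(r, t) = sum_n max(0, r_n - t_n):

representation mass the object lacks is penalized; object features absent
from the representation cost nothing (representations are abstractions,
objects are arbitrarily rich).  Membership is `D <= distance_threshold`, with
a **non-strict** inequality: the worked reference example (cutoff 1.0 against
distances 1.1 / 0.0 / 0.3 / 1.4) does not discriminate the boundary, so the
choice is documented here rather than silent.

**Presentation dynamics.**  Simultaneous presentation extracts one
representation from all co-present exemplars (narrow, feature-rich —
the suspicious coincidence).  Sequential presentation extracts a
representation from the first exemplar only; each later exposure is checked
for consistency with the *stored representation* (the exemplar itself is
gone — transient input must be computed over as it occurs).  A consistent
exposure (distance within the same `distance_threshold`; the source text
never names a separate consistency parameter) changes nothing but a
confidence counter.  An inconsistent exposure triggers a revision: the
cached salience draws are re-applied over the intersection of the old
support with the new exemplar's features, confidence resetting to 1.  This
yields the broader, sparser representations sequential training is known
for.  Training runs the item sequence twice (`n_loops = 2`); the
representation is frozen when the loops end — the convergence point — and
confidence plays no role in selection.

## The synthetic world

No external stimuli exist, so the package generates them.  The default
taxonomy is 3 superordinate classes x 3 basic categories x 3 subordinates
(the smallest shape supporting all seven training configurations), each
object carrying exactly one feature per taxonomic tier plus 2 idiosyncratic
features unique to it, drawn from a seed-permuted pool.  Sibling subordinate
features are mutually incompatible, as are distinct basic-category features.
The test grid is fixed across trials: 3 classes x 8 objects, with 2
subordinate matches, 2 basic-only matches and 4 superordinate-only matches
relative to the anchor training exemplar; selections are scored per level
against those fixed denominators (2 / 2 / 4).  Cross-class objects are
evaluated for membership but never scored.

What the generator does **not** emulate: photographic stimuli, perceptual
feature extraction, item prototypicality gradients, participant-level
response noise beyond salience sampling, and block-order/task-adaptation
effects.  A green simulation test therefore establishes internal consistency
of the mechanism under the stated feature geometry, not fidelity to any
particular picture set.

Two consequences of the per-object idiosyncratic features are worth knowing:

- In the reference worked example, same-subordinate objects are featurally
  identical (training and test dalmatian at distance 0.0); with per-object
  idiosyncratic features they are not, and the closed-form trace "three
  simultaneous subordinates select exactly the subordinate matches" only
  holds in a world with `n_idiosyncratic = 0` (that is how it is tested).
- With the default 2 features per object, simultaneous 3-exemplar training
  accumulates six idiosyncratic weights into the representation; at typical
  parameters their mass alone exceeds any threshold <= 1, so simultaneous
  conditions often select nothing at all — the suspicious coincidence
  "narrows past" the subordinate level.  The qualitative suspicious-
  coincidence / presentation-style contrast survives (basic-level selection
  still drops from single to simultaneous and rises under sequential), but
  subordinate-level selection under simultaneous training does not match the
  near-ceiling rates humans show.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `mu_high` | mean salience, basic-tier features | 0.8 | elevated prominence driving the basic-level bias |
| `mu_low` | mean salience, all other features | 0.3 | low enough that one exemplar's non-basic mass stays under threshold |
| `sigma` | shared salience SD | 0.1 | participant variability; 0 gives deterministic traces |
| `distance_threshold` | category cutoff | 1.0 | the worked example's cutoff |
| `incompatibility_threshold` | salience above which a feature blocks conflicts | 0.8 | engages rarely at default salience |
| `n_loops` | sequential passes through the items | 2 | the paradigm repeats the sequence in full twice |
| grid bounds | 4 step-0.1 values per parameter | 4^5 = 1024 configs | the published search size and step; exact bounds were never printed, these are this package's choice and are overridable |

## Evaluation machinery

`check_qualitative` declares the suspicious coincidence present when the
basic-level mean under simultaneous 3-subordinate training is at least 0.15
below the single-exemplar baseline, and the presentation-style effect when
sequential exceeds simultaneous by at least 0.15 (0.15 being the typical
empirical SD in this paradigm); comparisons are non-strict at the margin.
`divergence` is the summed absolute difference of the three level means for
one condition (a premetric in `[0, 3]`).  `grid_search` fits on three of the
seven conditions (single, 3-basic parallel, 3-basic sequential), ties broken
by enumeration order, and reports held-out per-condition divergence plus the
fraction of the 21 means within one empirical SD.  The human means of the
original studies were published only as figures; `synthetic_empirical_profiles`
is an explicitly synthetic stand-in built from the few printed numbers
(superordinate-training declination 0.91 → 0.75, ~0.15 superordinate
generalization after simultaneous basic training, SDs up to ~0.3) and the
qualitative shape of the paradigm.  Users holding the real means supply them
as a CSV (`condition, level, mean, sd[, n]`).

## Numerical choices

- Distances for binary objects use the closed form `sum(w) - W @ X^T`
  (exact, since weights <= 1); the generic relu-sum path remains for
  gradient objects and is cross-checked in tests.
- Per-participant simulation is vectorized as `(participants x features)`
  arrays; the scalar API and the scikit-learn estimator are the P = 1 slice
  of the same code, so there is no second implementation to drift.
- Profile SDs are sample SDs (ddof = 1), reported as 0 for a single
  participant.
- All randomness flows from `numpy.random.Generator`; suites and grid
  searches give every condition/configuration an independent spawned
  substream, so runs are reproducible bit-for-bit given a seed and
  conditions are statistically independent.
- Degenerate inputs: `sigma = 0` is legal (deterministic limit);
  `mu_low = 0` empties all non-basic weights; empty training sets, mismatched
  feature spaces, exhausted idiosyncratic pools and malformed configs raise.

## Known limitations

- The incompatibility threshold is close to epiphenomenal under the default
  world and fitting conditions: conflict cliques engage only in multi-basic
  training, where per-object idiosyncratic mass already dominates the
  distances, so the parameter moves the 21 output means by roughly the
  Monte-Carlo noise floor at 1000 participants.  Grid search consequently
  recovers the other four parameters reliably but not this one.
- At high `mu_low` combined with a low distance threshold the
  single-exemplar basic-level bias disappears (the anchor's non-basic mass
  alone exceeds the threshold), so the suspicious-coincidence margin cannot
  be met in that corner of the default grid (~13% of the 1024
  configurations).
- Sequential timing (seconds on/off screen) is not modeled; only exposure
  order and loop count matter, because the mechanism depends on co-presence,
  not duration.
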