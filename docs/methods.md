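# Methods

This note documents the models, conventions and design choices behind
`paleoweb`, in the order the pipeline applies them. It states no
empirical result; all numbers reported by the package are computed at run
time by the code described here.

## Trait space and guilds

Every taxon carries a categorical trait profile:

| axis | levels | notes |
|---|---|---|
| motility | fast, slow, facultative, non-motile | speed rank fast > slow > facultative > non-motile |
| tiering | pelagic, erect, surficial, semi-infaunal, shallow-infaunal, deep-infaunal | coarsened to pelagic / epifaunal / infaunal for scenarios |
| feeding | predator, suspension-feeder, deposit-feeder, mining, grazer | |
| size class | tiny ≤10 mm, small >10–50, medium >50–100, large >100–300, very-large >300–500, gigantic >500 mm | longest axis; `size_class_from_mm` is a helper, inputs supply the class directly |
| calcification | light, moderate, heavy | optional — trace fossils and fish may lack it |

Vocabularies are closed; inputs are case/diacritic-normalised and
anything outside the vocabulary is rejected with its row number. A
*guild* is the set of species sharing one exact profile; guild identity
is the profile, so the same guild id denotes the same node across time
intervals. Any row with a full profile becomes a node source — fish and
trace-fossil occurrences are not treated specially.

## Feeding rules and feasible webs

A feeding link resource → consumer exists iff all four per-trait rules
pass (conjunction), and the producer node links to every guild whose
feeding mode passes the producer rule. The default `RuleSet` encodes:

* **feeding** — predators take animal food only; suspension feeders and
  grazers take the producer; deposit and mining feeders take the producer
  (standing in for detritus).
* **tiering** — pelagic consumers reach pelagic/erect/surficial
  resources; epifaunal consumers (erect, surficial) reach everything but
  the deep infauna; infaunal consumers reach the infaunal tiers.
* **motility** — fast consumers catch any motility class; other classes
  catch only equal-or-slower resources.
* **size** — a consumer takes resources up to one size class larger than
  itself and anything smaller.

These defaults are a *reconstructed semantics* for the rule family this
model class uses: the engine is deliberately agnostic, every table cell
is data (YAML-editable), and the tests check engine properties
(conjunction, monotonicity under rule relaxation, determinism) rather
than any particular matrix. Cannibalism (self-loops) is off by default.
Only the feasible web is built — every permitted link, no subsampling
toward observed link-distributions — because feasible webs are directly
comparable across time intervals and already encode prey-switching
capacity for the cascade simulations. Consumers left with zero prey are
allowed but reported (`preyless_report`).

## Structural metrics

* Richness S excludes the producer (an including variant is reported);
  connectance C = L/S² uses S *including* the producer by default
  (directed convention, self-loops in the denominator); S(S−1) is
  available by flag.
* Generality = mean in-degree over nodes with prey; vulnerability = mean
  out-degree over nodes with predators; population SDs.
* Trophic level is prey-averaged — TL(producer)=1, TL(c) = 1 + mean TL of
  c's prey — solved as a linear system, so loops are handled. Preyless
  consumers, and nodes whose prey chains never reach the producer, have
  undefined level (NaN, warned) and are excluded from mean/max. Because
  "maximum trophic level" can also mean longest chain, a longest-chain
  variant (computed on the strongly-connected-component condensation) is
  reported alongside; the prey-averaged value is the headline.
* Motifs: every unordered triple whose induced subgraph is connected is
  classified into one of the 13 connected directed-triad classes via a
  canonical-form lookup (bidirectional edges form their own classes). S1
  = chain (A→B→C), S2 = omnivory (chain + A→C), S4 = apparent competition
  (A→C←B), S5 = direct competition (B←A→C); the other nine classes are
  kept internally so the census can be conservation-checked against the
  number of connected triples. The producer participates in the census by
  default (switchable): it is a real resource whose shared consumers are
  real exploitative competition.

The nine structural metrics plus the four motif counts form the default
13-metric comparison vector.

## Extinction cascades

A scenario fixes ordered trait levels: coarse tiering (3 levels), size (6
classes), motility (4), calcification (3, guilds without a value forming
a final tier), generality/vulnerability (in-/out-degree binned by exact
value), each in both directions, plus uniform random — 13 scenarios.
Each replicate shuffles guilds within levels, then removes them in order;
after every removal, any consumer with zero remaining prey goes extinct,
iterated to a fixpoint (the fixpoint is order-independent, which the
tests probe by randomising propagation order). Guilds whose only
resource is the producer can never be lost secondarily; the producer
itself is immune to both kinds of removal — it anchors the web.

Conventions, where the procedure leaves freedom:

* **Stopping.** The cascade stops at the first state with richness ≤ the
  stop value (guild count, producer excluded). A primary removal and its
  secondary fallout are atomic, so the final richness may undershoot; the
  result records the stop reason, and exhausting the sequence before the
  stop is flagged rather than raised.
* **Degree orderings** are computed once on the intact web — a scenario
  is a fixed primary *sequence* — with an optional mode that re-ranks
  survivors after every removal.
* **RNG.** Replicate r of scenario s under master seed m uses the stream
  `default_rng([m, s, r])`, so ensembles are reproducible, replicate
  order-independent, and parallelisable.

## Scenario comparison

* **TSS universe** = the pre-extinction guild set, because primary and
  secondary extinction only operate on pre-extinction nodes; guilds
  appearing only post-extinction (immigrants) are excluded from the
  confusion matrix. TP = survives in both, TN = extinct in both, FP =
  survives only in simulation, FN = survives only in the observation
  (the TP-as-survival convention is arbitrary for the TSS value, which is
  invariant under the joint label swap). Degenerate margins
  ((TP+FN)(FP+TN) = 0) yield NaN, flagged rather than raised.
* **Metric distance** = mean over the 13 metrics of |sim − emp|/|emp|,
  falling back to an absolute difference on a unit scale where the
  empirical value is 0; relative normalisation because the metrics live
  on very different scales. The metric list is user-overridable.
* Rankings report mean and SD of both scores per scenario; rank 1 =
  highest mean TSS, respectively lowest mean distance.

## Robustness

One uniform permutation of the non-producer guilds per replicate, reused
across the whole gradient (nested removals — a "deletion sequence" spans
the gradient and makes each replicate's curve monotone by construction).
For x = 1..99, the first ⌈xS/100⌉ guilds are removed with cascade
propagation and the fraction of the original community remaining
(producer excluded from the denominator) is recorded; 500 replicates by
default. R_x is read off the mean curve by inverse linear interpolation:
the smallest primary-removal fraction whose mean total loss reaches x%,
flagged unattained when a producer-anchored remnant persists. An exact
full-permutation enumerator (`exact_robustness_curve`) serves as a
reference for small webs. Loess-style smoothing is presentation-only and
deliberately outside the computational core.

## Synthetic community generator

The generator emulates the *shape* of a four-interval extinction-and-
recovery series, not any real basin's species counts, abundances or
stratigraphic pacing. Defaults: richness 36 / 21 / 27 / 38
(pre/post/early/late) — a diverse pre-extinction community, a
post-extinction community at the canonical stop richness of 21, partial
then full recovery — with per-interval trait frequency tables that shift
toward surficial suspension feeders and pelagic predators immediately
after the extinction, a pelagic-heavy early recovery, and a re-diversified
late recovery.

Communities are sampled as distinct trait combinations (guild uniqueness
by construction); a connectivity guarantee rejects draws that would leave
a consumer with no feasible resource, so generated webs have no preyless
consumers. Requesting more guilds than the distinct combinations with
nonzero probability raises an explicit error.

The post-extinction community is produced from the pre-extinction web by
*killing* guilds one at a time until the target richness: with
probability `bias` the victim comes from the earliest non-empty level of
the kill trait (default: coarse tiering, infaunal first), otherwise
uniformly — and every kill propagates secondary extinctions, exactly as
the cascade simulator does. This is a deliberate choice: at bias 0 the
ground-truth process *is* the random scenario, and at bias 1 it is the
infaunal-first tiering scenario, so parameter-recovery tests have a
well-defined target at both ends. A consequence is that at bias 1 a few
infaunal guilds can survive if cascades reach the target richness before
the infaunal pool is exhausted; the deterministic "all infaunal gone"
limit holds whenever the death count exceeds the infaunal pool. If
cascades overshoot the target, immigrant guilds (absent from
pre-extinction, excluded from TSS) top the community back up. Recovery
intervals re-admit extinct pre-extinction guilds at random, then sample
new guilds.

What passing tests on synthetic data do **not** show: real occurrence
data have detection/sampling biases, trait assignments carry literature
uncertainty, and real extinction selectivity is never a single-trait
level ordering. The generator validates the machinery and its
inferential logic, not any empirical claim about a particular basin. The
bundled `data/synthetic_toarcian_occurrences.csv` is such a synthetic
table, sized to a published compilation's summary shape (162 species,
post-extinction guild richness 21) so the ingestion path is exercised
realistically; it contains no real specimens.

## Numerical and engineering choices

* Trophic-level solve: dense `numpy.linalg.solve` on the supported
  subweb; webs here are small (S ≲ 100).
* Motif census: O(S³) triple enumeration with a precomputed 64-pattern
  canonical lookup; exact, no sampling.
* Cascade engine: adjacency sets with in-degree counters, built once per
  web and reused across replicates.
* Simulation sizes (50 cascade replicates, 500 robustness replicates,
  richness ≈ 20–40) are the package defaults; all are parameters, and the
  test suite's statistical checks use 3-standard-error bands against
  exact enumeration where feasible (webs with ≤ 6 guilds).
* Determinism: every stochastic routine takes a seed and derives
  per-replicate streams; pipeline reruns are byte-identical.

## Known limitations

* The default rule matrix is a documented reconstruction of the model
  family's semantics, not a transcription of any published matrix; users
  with a specific matrix should supply it as YAML.
* Webs are presence-based: no abundances, interaction strengths or
  probabilistic links, and no rewiring beyond what the feasible web
  already encodes.
* Secondary extinction is purely topological (all-prey-lost); no partial
  or dose-dependent extinction.
* Whether a "species-count" stop richness should count guilds or species
  is data-dependent; the simulator counts guilds, and the stop value is
  an explicit parameter.
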