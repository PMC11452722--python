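# paleoweb

Trait-rule food-web reconstruction, secondary-extinction cascade
simulation and robustness analysis for fossil (and fossil-like)
communities of trophic guilds.

`paleoweb` is aimed at palaeoecologists and community ecologists who want
to go from a table of taxon occurrences with categorical ecological
traits — motility, tiering, feeding mode, body-size class, calcification
— to a quantitative account of how a community's trophic structure
responds to an extinction event: which trait-targeted extinction scenario
best explains an observed post-event community, and how robust each
community is to cascading secondary loss.

## The model

**Guilds and feasible webs.** Species sharing an identical trait
combination form a *trophic guild*, the node unit of every analysis. A
directed link from resource guild *r* to consumer guild *c* (edges point
prey → predator, the direction of energy flow) is *feasible* iff **all**
per-trait rules pass:

    link(r → c)  ⇔  feeding(c) ∧ tiering(c, r) ∧ motility(c, r) ∧ size(c, r)

A single producer node anchors each web; producer-feeding modes
(suspension, deposit, grazing, mining) link to it. The feasible web
contains *every* permitted link, with no subsampling toward empirical
link distributions. The rule tables are a first-class, editable input
(`RuleSet`, YAML round-trippable); the shipped default encodes standard
reachability/speed/size-window semantics documented in
`docs/methods.md`.

**Structure.** Nine structural metrics (richness S, links L, connectance
C = L/S², generality and vulnerability with their SDs, mean and max
prey-averaged trophic level) plus an exhaustive three-node motif census:
S1 linear chains, S2 omnivory, S4 apparent competition, S5 direct
competition, embedded in the full 13-class connected-triad partition so
counts are conservation-checked.

**Extinction cascades.** Thirteen primary-extinction scenarios — random,
plus six traits in two directions each (size, tiering, motility,
calcification, generality, vulnerability) — remove guilds level by level
(shuffled within levels), propagating a secondary extinction whenever a
consumer has lost all of its prey, until the community reaches a target
richness.

**Comparison.** Each simulated post-extinction community is scored
against the observed one by the True Skill Statistic on a guild
presence/absence confusion matrix over the pre-extinction universe,

    TSS = (TP·TN − FP·FN) / ((TP+FN)(FP+TN)) ∈ [−1, 1],

and by the mean relative difference across 13 metrics (9 structural + 4
motif counts).

**Robustness.** R_x is the proportion of guilds that must be removed
primarily for x% of the community to be lost in total (primary +
secondary), estimated from 500 random deletion sequences over the whole
x = 1–99% gradient.

A synthetic community generator produces four-interval series
(pre-extinction → post-extinction → early recovery → late recovery) with
a *known* trait-biased extinction target, so the entire inference chain
can be validated against ground truth.

## Worked example

Rank all 13 scenarios on a synthetic series generated with a fully
infaunal-targeted extinction (`examples/03_extinction_scenarios.py`):

```text
        scenario  tss_mean  tss_std  metric_distance_mean  rank_tss
      tiering_IP    0.9006   0.0334                0.0106       1.0
calcification_HL    0.3171   0.1139                0.2462       2.0
vulnerability_LH    0.3143   0.0000                0.4667       3.0
     motility_FN    0.1474   0.0930                0.3476       4.0
             ...
          random   -0.0190   0.1560                0.3310       8.0
             ...
      tiering_PI   -0.7143   0.0000                0.3773      13.0
```

The infaunal-to-pelagic tiering scenario recovers the generator's kill
trait: its simulated survivor sets agree with the "observed"
post-extinction community at mean TSS ≈ 0.90 (1 = perfect identity
match) and the smallest 13-metric structural mismatch, while random
removal sits near 0 and the reversed ordering near −1.

Robustness of the four webs (`examples/04_robustness_gradient.py`):

```text
interval           S  rem@25%  rem@50%    R50
pre               36    0.750    0.498  0.479
post              21    0.714    0.475  0.475
early_recovery    27    0.741    0.478  0.484
late_recovery     38    0.737    0.500  0.480
```

R50 < 0.5 means secondary cascades amplify primary removals: less than
half the community must be deleted for half of it to disappear.

The other examples cover ingestion/reconstruction (`01`), metric and
motif tables (`02`) and the end-to-end pipeline with provenance (`05`).
The same stages are available from the shell:

```bash
paleoweb all --seed 1 --outdir run1        # or reconstruct/metrics/...
```

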