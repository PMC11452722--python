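import numpy as np
import pytest

from paleoweb import (
    SCENARIO_NAMES,
    Guild,
    GuildSet,
    Scenario,
    TraitProfile,
    order_primary_sequence,
    run_cascade,
    run_scenario_ensemble,
)

from _oracles import cascade_oracle
from conftest import make_web


class TestScenarioDefinitions:
    def test_thirteen_canonical_scenarios(self):
        assert len(SCENARIO_NAMES) == 13
        assert SCENARIO_NAMES[0] == "random"

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            Scenario("tiering_sideways")


def _tiering_web():
    profiles = {
        "inf1": TraitProfile("slow", "shallow-infaunal", "deposit-feeder", "small"),
        "inf2": TraitProfile("facultative", "deep-infaunal", "mining", "tiny"),
        "pel": TraitProfile("fast", "pelagic", "suspension-feeder", "medium"),
    }
    return make_web_from(profiles)


def make_web_from(profiles, edges=None):
    guilds = [Guild(guild_id=k, traits=p) for k, p in profiles.items()]
    gs = GuildSet(interval="pre", guilds=guilds)
    if edges is None:
        edges = [("producer", k) for k in profiles]
    from paleoweb import FoodWeb

    return FoodWeb.from_guilds(gs, edges)


class TestOrderPrimarySequence:
    def test_infaunal_precede_pelagic(self):
        web = _tiering_web()
        rng = np.random.default_rng(0)
        seq = order_primary_sequence(web, Scenario("tiering_IP"), rng)
        assert set(seq[:2]) == {"inf1", "inf2"} and seq[2] == "pel"

    def test_pelagic_first_when_reversed(self):
        web = _tiering_web()
        seq = order_primary_sequence(
            web, Scenario("tiering_PI"), np.random.default_rng(0)
        )
        assert seq[0] == "pel"

    def test_random_scenario_reproducible_uniform_permutation(self):
        web = _tiering_web()
        s1 = order_primary_sequence(web, Scenario("random"), np.random.default_rng(5))
        s2 = order_primary_sequence(web, Scenario("random"), np.random.default_rng(5))
        assert s1 == s2 and sorted(s1) == ["inf1", "inf2", "pel"]

    def test_producer_never_in_sequence(self, random_feasible_web):
        web = random_feasible_web(1)
        for name in SCENARIO_NAMES:
            seq = order_primary_sequence(
                web, Scenario(name), np.random.default_rng(0)
            )
            assert "producer" not in seq
            assert sorted(seq) == sorted(web.nodes(include_producer=False))

    def test_generality_high_first_and_ties_shuffled(self):
        profiles = {
            "hub": TraitProfile("fast", "pelagic", "predator", "large"),
            "a": TraitProfile("slow", "surficial", "suspension-feeder", "small"),
            "b": TraitProfile("slow", "erect", "suspension-feeder", "small"),
        }
        edges = [
            ("producer", "a"), ("producer", "b"),
            ("a", "hub"), ("b", "hub"), ("producer", "hub"),
        ]
        # in-degrees: hub 3, a 1, b 1
        web = make_web_from(profiles, edges)
        orders = set()
        for seed in range(1000):
            seq = order_primary_sequence(
                web, Scenario("generality_HL"), np.random.default_rng(seed)
            )
            assert seq[0] == "hub"
            orders.add(tuple(seq[1:]))
        assert orders == {("a", "b"), ("b", "a")}

    def test_calcification_missing_values_form_final_tier(self):
        profiles = {
            "heavy": TraitProfile("slow", "surficial", "suspension-feeder",
                                  "small", "heavy"),
            "nocal": TraitProfile("fast", "pelagic", "predator", "medium"),
            "light": TraitProfile("slow", "erect", "grazer", "small", "light"),
        }
        web = make_web_from(
            profiles,
            [("producer", "heavy"), ("producer", "light"), ("heavy", "nocal"),
             ("light", "nocal")],
        )
        seq = order_primary_sequence(
            web, Scenario("calcification_HL"), np.random.default_rng(0)
        )
        assert seq == ["heavy", "light", "nocal"]

    def test_calcification_all_missing_is_error(self):
        web = _tiering_web()  # no calcification values anywhere
        with pytest.raises(ValueError, match="calcification"):
            order_primary_sequence(
                web, Scenario("calcification_HL"), np.random.default_rng(0)
            )


class TestRunCascade:
    def test_full_downstream_collapse_same_step(self, chain_web):
        res = run_cascade(chain_web, ["A"], stop_richness=0)
        assert res.events == [
            (1, "A", "primary"), (1, "B", "secondary"), (1, "C", "secondary"),
        ]
        assert res.survivors == frozenset()

    def test_alternative_prey_prevents_secondary(self):
        web = make_web(
            ["A", "B"],
            [("producer", "A"), ("producer", "B"), ("A", "B")],
        )
        res = run_cascade(web, ["A"], stop_richness=0)
        assert res.survivors == {"B"}
        assert res.n_secondary() == 0

    def test_stop_richness_halts_sequence(self, chain_web):
        res = run_cascade(chain_web, ["C", "B", "A"], stop_richness=2)
        assert res.final_richness == 2
        assert res.stop_reason == "stop_richness"

    def test_sequence_exhaustion_flagged(self, chain_web):
        res = run_cascade(chain_web, ["C"], stop_richness=0)
        assert res.stop_reason == "sequence_exhausted"

    def test_producer_in_sequence_rejected(self, chain_web):
        with pytest.raises(ValueError):
            run_cascade(chain_web, ["producer"], stop_richness=0)

    def test_no_guild_extinct_twice(self, random_feasible_web):
        web = random_feasible_web(4, richness=20)
        seq = order_primary_sequence(
            web, Scenario("random"), np.random.default_rng(1)
        )
        res = run_cascade(web, seq, stop_richness=5)
        guilds = [g for _, g, _ in res.events]
        assert len(guilds) == len(set(guilds))
        assert res.survivors == set(web.nodes(include_producer=False)) - set(guilds)

    @pytest.mark.parametrize("seed", range(6))
    def test_survivors_match_independent_simulator(
        self, seed, random_feasible_web
    ):
        web = random_feasible_web(seed, richness=16)
        for name in SCENARIO_NAMES:
            seq = order_primary_sequence(
                web, Scenario(name), np.random.default_rng(seed)
            )
            res = run_cascade(web, seq, stop_richness=4)
            expected = cascade_oracle(
                web.edges(), web.nodes(), "producer", seq, stop_richness=4
            )
            assert res.survivors == expected, name

    def test_fixpoint_invariant_to_propagation_order(self, random_feasible_web):
        web = random_feasible_web(8, richness=18)
        seq = order_primary_sequence(
            web, Scenario("random"), np.random.default_rng(3)
        )
        res = run_cascade(web, seq, stop_richness=6)
        for order_seed in range(5):
            scrambled = cascade_oracle(
                web.edges(), web.nodes(), "producer", seq, 6,
                rng=np.random.default_rng(order_seed),
            )
            assert scrambled == res.survivors


class TestEnsembles:
    def test_fifty_replicates_default(self, random_feasible_web):
        web = random_feasible_web(2, richness=14)
        results = run_scenario_ensemble(
            web, Scenario("random"), stop_richness=6, seed=0
        )
        assert len(results) == 50

    def test_same_seed_identical_logs(self, random_feasible_web):
        web = random_feasible_web(2, richness=14)
        a = run_scenario_ensemble(web, Scenario("tiering_IP"), 6, seed=9)
        b = run_scenario_ensemble(web, Scenario("tiering_IP"), 6, seed=9)
        assert [r.events for r in a] == [r.events for r in b]

    def test_stop_richness_respected_with_atomic_overshoot(
        self, random_feasible_web
    ):
        web = random_feasible_web(6, richness=20)
        results = run_scenario_ensemble(web, Scenario("tiering_IP"), 10, seed=2)
        for res in results:
            assert res.final_richness <= 10
            # overshoot bounded by the final atomic step's cascade size
            if res.events:
                last_step = res.events[-1][0]
                last_cascade = sum(1 for s, _, _ in res.events if s == last_step)
                assert res.final_richness > 10 - last_cascade

    def test_single_guild_levels_are_deterministic_across_replicates(self):
        profiles = {
            "inf": TraitProfile("slow", "deep-infaunal", "mining", "tiny"),
            "epi": TraitProfile("slow", "surficial", "grazer", "small"),
            "pel": TraitProfile("fast", "pelagic", "suspension-feeder", "medium"),
        }
        web = make_web_from(profiles)
        results = run_scenario_ensemble(web, Scenario("tiering_IP"), 1, seed=0)
        logs = {tuple(r.events) for r in results}
        assert len(logs) == 1  # one guild per level -> no within-level freedom
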