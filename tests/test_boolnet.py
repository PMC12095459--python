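"""Synchronous Boolean dynamics, attractors, phenotype labels, scans."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import polariscape as ps
from polariscape.boolnet import (
    DEFAULT_PHENOTYPE_RULES,
    NetworkDefinitionError,
    PhenotypeRules,
    parse_rule,
)


class TestStep:
    @pytest.mark.parametrize(
        "state, expected",
        [
            ((0, 1, 0), (1, 0, 1)),  # hand evaluation of the three rules
            ((1, 1, 0), (1, 1, 0)),  # fixed point
            ((0, 0, 0), (0, 0, 1)),
        ],
    )
    def test_hand_evaluated_transitions(self, toy3, state, expected):
        assert ps.step(toy3, state) == expected

    def test_clamped_node_holds_its_value(self, toy3):
        net = ps.perturb(toy3, "C", 1)
        for s in [(0, 0, 0), (1, 1, 0), (0, 1, 1)]:
            assert ps.step(net, s)[2] == 1

    def test_wrong_state_length_rejected(self, toy3):
        with pytest.raises(ValueError):
            ps.step(toy3, (0, 1))


class TestRuleParsing:
    def test_precedence_not_binds_tighter_than_and_than_or(self):
        net = ps.BooleanNetwork(
            nodes=("A", "B", "C", "X"),
            rules={"A": "A", "B": "B", "C": "C", "X": "NOT A AND B OR C"},
        )
        # (NOT A AND B) OR C
        for a, b, c in [(0, 1, 0), (1, 1, 0), (0, 0, 1), (1, 0, 0)]:
            out = ps.step(net, (a, b, c, 0))
            assert out[3] == ((1 - a) & b) | c

    def test_unknown_identifier_rejected_at_load(self):
        with pytest.raises(NetworkDefinitionError, match="unknown node"):
            ps.BooleanNetwork(nodes=("A",), rules={"A": "A OR MISSING"})

    def test_malformed_expression_rejected(self):
        for bad in ["A AND", "(A", "A B", "AND A", "A %% B"]:
            with pytest.raises(NetworkDefinitionError):
                ps.BooleanNetwork(nodes=("A", "B"), rules={"A": bad, "B": "A"})

    def test_constants_and_case_insensitive_keywords(self):
        ast = parse_rule("a and not 0 or FALSE")
        assert ast is not None


class TestFindAttractors:
    def test_exhaustive_toy3_matches_hand_enumeration(self, toy3):
        atts = ps.find_attractors(toy3)
        by_states = {a.states: a for a in atts}
        assert len(atts) == 3
        assert by_states[((0, 0, 1),)].basin_size == 2
        assert by_states[((1, 1, 0),)].basin_size == 2
        assert by_states[((0, 1, 0), (1, 0, 1))].basin_size == 4

    def test_basins_partition_state_space(self, toy3):
        atts = ps.find_attractors(toy3)
        assert sum(a.basin_size for a in atts) == 2**3
        assert np.isclose(sum(a.basin_fraction for a in atts), 1.0)

    def test_sampled_converges_to_exhaustive_fractions(self, toy3):
        n = 10_000
        atts = ps.find_attractors(toy3, mode="sampled", n_samples=n, seed=42)
        frac = {a.states: a.basin_fraction for a in atts}
        for states, p in [
            (((0, 0, 1),), 0.25),
            (((1, 1, 0),), 0.25),
            (((0, 1, 0), (1, 0, 1)), 0.5),
        ]:
            se = np.sqrt(p * (1 - p) / n)
            assert abs(frac[states] - p) < 3 * se

    def test_sampled_is_deterministic_given_seed(self, toy3):
        a1 = ps.find_attractors(toy3, mode="sampled", n_samples=500, seed=7)
        a2 = ps.find_attractors(toy3, mode="sampled", n_samples=500, seed=7)
        assert [(a.states, a.basin_size) for a in a1] == [
            (a.states, a.basin_size) for a in a2
        ]

    def test_exhaustive_cap_enforced(self):
        net = ps.make_toy_network("random", n=6, seed=0)
        with pytest.raises(ValueError, match="cap"):
            ps.find_attractors(net, cap=4)

    def test_clamped_enumeration_over_free_nodes(self, toy3):
        # exhaustive over the 4 free states with C clamped ON
        atts = ps.find_attractors(ps.perturb(toy3, "C", 1))
        sizes = {a.states: a.basin_size for a in atts}
        assert sizes[((0, 0, 1),)] == 1
        assert sizes[((1, 1, 1),)] == 1
        assert sizes[((0, 1, 1), (1, 0, 1))] == 2
        assert sum(sizes.values()) == 4

    @pytest.mark.parametrize("n", [3, 5, 7])
    def test_ring_oscillator_all_cycles_no_fixed_points(self, n):
        # the negated ring is a bijection under synchronous update: every
        # attractor is a cycle equal to its own basin, and the odd negative
        # feedback loop forbids fixed points
        net = ps.make_toy_network("ring", n=n)
        atts = ps.find_attractors(net)
        assert all(len(a.states) > 1 for a in atts)
        assert all(a.basin_size == len(a.states) for a in atts)
        assert sum(a.basin_size for a in atts) == 2**n

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 8))
    def test_random_network_basins_partition(self, seed, n):
        net = ps.make_toy_network("random", n=n, k=2, seed=seed)
        atts = ps.find_attractors(net)
        assert sum(a.basin_size for a in atts) == 2**n
        for a in atts:
            # applying one step to states[k] yields states[(k+1) % len]
            for k, s in enumerate(a.states):
                assert ps.step(net, s) == a.states[(k + 1) % len(a.states)]

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_clamped_node_on_in_every_attractor_state(self, seed):
        net = ps.make_toy_network("random", n=6, k=2, seed=seed)
        clamped = ps.perturb(net, net.nodes[0], 1)
        for a in ps.find_attractors(clamped):
            assert all(s[0] == 1 for s in a.states)


class TestClassifyPhenotype:
    RULES = PhenotypeRules(
        {
            "M1": "STAT1 OR NFKB",
            "M2a": "STAT6",
            "M2d": "TLR4 AND A2A",
        }
    )
    NODES = ("STAT1", "NFKB", "STAT6", "TLR4", "A2A")

    def _attractor(self, *states):
        return ps.Attractor(
            states=tuple(states), basin_size=1, basin_fraction=1.0, nodes=self.NODES
        )

    def test_pure_m1(self):
        a = self._attractor((1, 0, 0, 0, 0))
        assert ps.classify_phenotype(a, self.RULES) == "M1"

    def test_unpolarized_is_m0(self):
        a = self._attractor((0, 0, 0, 0, 0))
        assert ps.classify_phenotype(a, self.RULES) == "M0"

    def test_hybrid_concatenates_in_fixed_order(self):
        a = self._attractor((1, 0, 0, 1, 1))
        assert ps.classify_phenotype(a, self.RULES) == "M1M2d"

    def test_cycle_activity_all_vs_any(self):
        a = self._attractor((1, 0, 0, 0, 0), (0, 0, 0, 0, 0))
        assert ps.classify_phenotype(a, self.RULES, activity="all") == "M0"
        assert ps.classify_phenotype(a, self.RULES, activity="any") == "M1"

    def test_label_invariant_under_cycle_rotation(self):
        s1, s2 = (1, 0, 1, 0, 0), (1, 0, 0, 0, 0)
        a = self._attractor(s1, s2)
        b = self._attractor(s2, s1)
        assert ps.classify_phenotype(a, self.RULES) == ps.classify_phenotype(b, self.RULES)

    def test_unknown_rule_node_rejected(self):
        a = self._attractor((0, 0, 0, 0, 0))
        bad = PhenotypeRules({"M1": "NOPE"})
        with pytest.raises(NetworkDefinitionError):
            ps.classify_phenotype(a, bad)

    def test_default_table_m1_or_branch(self):
        nodes = tuple(sorted(DEFAULT_PHENOTYPE_RULES.variables()))
        act = {n: 0 for n in nodes}
        act["STAT1"] = 1
        assert DEFAULT_PHENOTYPE_RULES.label(act) == "M1"
        act = {n: 0 for n in nodes}
        act["TNFA"] = 1  # TNFA alone is not enough without AP1 ...
        assert DEFAULT_PHENOTYPE_RULES.label(act) == "M0"
        act["AP1"] = 1  # ... but AP1 alone activates M2b as well
        assert DEFAULT_PHENOTYPE_RULES.label(act) == "M1M2b"


class TestPerturb:
    def test_returns_copy_original_unchanged(self, toy3):
        net2 = ps.perturb(toy3, "A", 0)
        assert toy3.clamps == {}
        assert net2.clamps == {"A": 0}

    def test_unknown_node_rejected(self, toy3):
        with pytest.raises(KeyError):
            ps.perturb(toy3, "Z", 1)

    def test_reclamping_replaces(self, toy3):
        net = ps.perturb(ps.perturb(toy3, "A", 0), "A", 1)
        assert net.clamps == {"A": 1}

    def test_clamp_off_propagates_to_attractors(self, toy3):
        for a in ps.find_attractors(ps.perturb(toy3, "A", 0)):
            assert all(s[0] == 0 for s in a.states)


class TestPerturbationScan:
    RULES = PhenotypeRules({"M1": "A AND B", "M2a": "C AND NOT A AND NOT B"})

    def test_empty_perturbation_list(self, toy3):
        rep = ps.perturbation_scan(toy3, [], self.RULES)
        assert len(rep.rows) == 0
        assert len(rep.aggregates) == 0

    def test_unchanged_class_has_zero_pct_change(self, toy3):
        # clamp C=1: the class of the (0,0,1) fixed point keeps fraction 0.25
        rep = ps.perturbation_scan(
            toy3, [("C", 1)], self.RULES,
            antitumoral_classes={"M1"}, protumoral_classes={"M2a"},
            activity="any",
        )
        row = rep.rows[rep.rows["phenotype"] == "M2a"].iloc[0]
        assert row["wt_fraction"] == 0.25
        assert row["pert_fraction"] == 0.25
        assert row["pct_change"] == 0.0
        assert row["category"] == "minimal"

    def test_disappeared_category(self, toy3):
        # clamp A=1 forces A ON everywhere: the M2a ((0,0,1)) class vanishes
        rep = ps.perturbation_scan(
            toy3, [("A", 1)], self.RULES,
            antitumoral_classes={"M1"}, protumoral_classes={"M2a"},
        )
        m2a = rep.rows[rep.rows["phenotype"] == "M2a"].iloc[0]
        assert m2a["pert_fraction"] == 0.0
        assert m2a["category"] == "disappeared"

    def test_pct_changes_recompute_from_fractions(self, toy3):
        rep = ps.perturbation_scan(
            toy3, [("C", 0), ("B", 1)], self.RULES,
            antitumoral_classes={"M1"}, protumoral_classes={"M2a"},
        )
        for _, r in rep.rows.iterrows():
            if r["category"] in ("novel", "disappeared"):
                continue
            expect = 100.0 * (r["pert_fraction"] - r["wt_fraction"]) / r["wt_fraction"]
            assert r["pct_change"] == pytest.approx(expect)

    def test_overlapping_class_sets_rejected(self, toy3):
        with pytest.raises(ValueError, match="disjoint"):
            ps.perturbation_scan(
                toy3, [("C", 1)], self.RULES,
                antitumoral_classes={"M1"}, protumoral_classes={"M1"},
            )
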