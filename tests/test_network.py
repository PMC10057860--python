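"""Reaction-network construction, candidate connection and degree filtering,
checked against brute-force all-pairs difference matching."""

import pytest

from formulanet.candidates import Candidate, CandidateSet, generate_candidates
from formulanet.formula import ElementRules, Formula, ion_mz
from formulanet.network import (
    ConnectedCandidate,
    ReactionTable,
    ReactionTableError,
    build_initial_network,
    connect_candidates,
    degree_filter,
    network_stats,
)
from formulanet.synth import make_seed_universe
from oracle_utils import brute_force_edges


class TestReactionTable:
    def test_default_loads(self, reactions):
        assert len(reactions) > 40
        assert reactions.match(Formula.parse("H2O")) == "hydration"
        assert reactions.match(-Formula.parse("H2O")) == "hydration"

    def test_rejects_zero_and_duplicate_differences(self):
        with pytest.raises(ReactionTableError):
            ReactionTable([("null", Formula([0] * 6))])
        with pytest.raises(ReactionTableError):
            ReactionTable([
                ("a", Formula.parse("H2O")),
                ("b", -Formula.parse("H2O")),
            ])


class TestBuildNetwork:
    def test_single_phosphorylation_pair(self, reactions, rules):
        net = build_initial_network(
            [Formula.parse("C6H12O6"), Formula.parse("C6H13O9P")],
            reactions, rules,
        )
        assert net.edge_count == 1
        assert net.degree(Formula.parse("C6H12O6")) == 1

    def test_unrelated_pair_has_no_edge(self, reactions, rules):
        net = build_initial_network(
            [Formula.parse("C6H12O6"), Formula.parse("C10H16N5O13P3")],
            reactions, rules,
        )
        assert net.edge_count == 0

    def test_edges_match_brute_force(self, reactions, rules):
        seeds = make_seed_universe(200, reactions, rules, 3.0, rng_seed=3)
        net = build_initial_network(seeds, reactions, rules)
        got = {frozenset((a, b)) for a, b in net.graph.edges}
        assert got == brute_force_edges(seeds, reactions)

    def test_order_invariance(self, reactions, rules):
        seeds = make_seed_universe(80, reactions, rules, 2.0, rng_seed=4)
        a = build_initial_network(seeds, reactions, rules)
        b = build_initial_network(seeds[::-1], reactions, rules)
        assert set(map(frozenset, a.graph.edges)) == set(
            map(frozenset, b.graph.edges)
        )

    def test_seed_filtering(self, reactions):
        rules = ElementRules(mass_range=(50, 300))
        net = build_initial_network(
            [Formula.parse("C6H12O6"), Formula.parse("C6H12O6"),
             Formula.parse("C30H50O10")],  # duplicate + above mass range
            reactions, rules,
        )
        assert net.node_count == 1
        with pytest.raises(ValueError):
            build_initial_network([Formula.parse("C30H50O10")], reactions, rules)

    def test_adding_nodes_never_lowers_degree(self, reactions, rules):
        seeds = make_seed_universe(120, reactions, rules, 3.0, rng_seed=5)
        net = build_initial_network(seeds[:100], reactions, rules)
        before = {f: net.degree(f) for f in seeds[:100]}
        net.add_formulas(seeds[100:], reactions, origin="round-1")
        assert all(net.degree(f) >= d for f, d in before.items())


class TestConnectCandidates:
    def _cs(self, formulas, adduct="[M+H]+"):
        cands = tuple(
            Candidate(adduct, f, ion_mz(f, adduct), 0.0) for f in formulas
        )
        return CandidateSet(feature_id="f1", mz=cands[0].mz_theo, candidates=cands)

    def test_reaction_neighbor_detected(self, reactions, rules):
        net = build_initial_network([Formula.parse("C6H13O9P")], reactions, rules)
        connected, unconnected = connect_candidates(
            net, self._cs([Formula.parse("C6H12O6")]), reactions
        )
        assert len(connected) == 1 and not unconnected
        assert connected[0].degree == 1
        assert connected[0].neighbors[0][1] == "phosphorylation"
        assert not connected[0].identity_match

    def test_distant_candidate_unconnected(self, reactions, rules):
        net = build_initial_network([Formula.parse("C6H13O9P")], reactions, rules)
        connected, unconnected = connect_candidates(
            net, self._cs([Formula.parse("C20H30N2O5S2")]), reactions
        )
        assert not connected and len(unconnected) == 1

    def test_identity_match_flagged(self, reactions, rules):
        net = build_initial_network(
            [Formula.parse("C6H12O6"), Formula.parse("C6H13O9P")], reactions, rules
        )
        connected, _ = connect_candidates(
            net, self._cs([Formula.parse("C6H12O6")]), reactions
        )
        assert connected[0].identity_match
        assert connected[0].degree == 1  # its node's degree

    def test_degrees_match_brute_force(self, reactions, rules):
        seeds = make_seed_universe(500, reactions, rules, 3.0, rng_seed=6)
        net = build_initial_network(seeds[:400], reactions, rules)
        probe = seeds[400:]
        keys = {d.canonical_difference() for d in reactions.differences}
        connected, unconnected = connect_candidates(
            net, self._cs(probe), reactions
        )
        got = {c.formula: c.degree for c in connected}
        got.update({c.formula: 0 for c in unconnected})
        for f in probe:
            expected = sum(
                (f - node).canonical_difference() in keys
                for node in seeds[:400] if node != f
            )
            assert got[f] == expected, str(f)


class TestDegreeFilter:
    def _mk(self, degree, identity=False):
        return ConnectedCandidate(
            "f", "[M+H]+", Formula.parse("C6H12O6"), 181.0, 0.0,
            degree, (), identity,
        )

    def test_inclusive_cutoff(self):
        cands = [self._mk(d) for d in (1, 2, 3)]
        assert [c.degree for c in degree_filter(cands, 2)] == [2, 3]

    def test_cutoff_one_is_identity_on_connected(self):
        cands = [self._mk(d) for d in (1, 5)]
        assert degree_filter(cands, 1) == cands

    def test_cutoff_above_max_empties(self):
        assert degree_filter([self._mk(2)], 5) == []

    def test_exclusive_variant(self):
        cands = [self._mk(d) for d in (2, 3)]
        assert [c.degree for c in degree_filter(cands, 2, inclusive=False)] == [3]

    def test_identity_always_survives(self):
        keeper = self._mk(0, identity=True)
        assert degree_filter([keeper, self._mk(1)], 4) == [keeper]

    def test_rejects_nonpositive_cutoff(self):
        with pytest.raises(ValueError):
            degree_filter([], 0)


class TestStats:
    def test_two_node_chain(self, reactions, rules):
        net = build_initial_network(
            [Formula.parse("C6H12O6"), Formula.parse("C6H13O9P")], reactions, rules
        )
        stats = network_stats(net)
        assert stats["nodes"] == 2 and stats["edges"] == 1
        assert stats["mean_degree"] == 1.0

    def test_histogram_consistency(self, reactions, rules):
        seeds = make_seed_universe(300, reactions, rules, 3.0, rng_seed=7)
        net = build_initial_network(seeds, reactions, rules)
        stats = network_stats(net)
        hist = stats["degree_histogram"]
        assert sum(hist.values()) == stats["nodes"]
        assert sum(k * v for k, v in hist.items()) == 2 * stats["edges"]
        lt3 = sum(v for k, v in hist.items() if k < 3)
        assert stats["fraction_degree_lt_3"] == pytest.approx(
            lt3 / stats["nodes"]
        )

    def test_chain_universe_mean_degree_bound(self, reactions, rules):
        # a reaction-closed chain: each member one step from the previous
        base = Formula.parse("C10H20O5")
        ch2 = Formula.parse("CH2")
        chain = [base]
        for _ in range(19):
            chain.append(chain[-1] + ch2)
        net = build_initial_network(chain, reactions, rules)
        n = net.node_count
        assert network_stats(net)["mean_degree"] >= 2 * (n - 1) / n
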