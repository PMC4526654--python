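"""Engine semantics: successors, STG construction, attractors, summaries."""

import pytest

from sinboole.dynamics import (
    ClampInconsistency,
    StateSpaceTooLarge,
    async_successors,
    build_stg,
    find_attractors,
    find_fixed_points,
    reachable_attractors,
    summarize,
    sync_successor,
)
from sinboole.experiments import stage_clamps
from sinboole.logic_core import parse_rules
from sinboole.synthetic import RandomNetSpec, random_network

from oracle import oracle_attractors, oracle_fixed_points


def _state(net, **bits):
    from sinboole.dynamics import NetworkState

    return NetworkState(net.nodes, [bits[n] for n in net.nodes])


class TestSuccessors:
    def test_oscillator_async_successor(self, toggle_net):
        succ = async_successors({"A": 0}, toggle_net)
        assert {s["A"] for s in succ} == {1}

    def test_fixed_point_has_no_successors(self, sin):
        clamps = stage_clamps("interphase", sin)
        (fp,) = find_fixed_points(sin, clamps)
        assert async_successors(fp, sin, clamps) == set()

    @pytest.mark.parametrize("seed", range(10))
    def test_successor_count_equals_disagreeing_nodes(self, seed):
        net = random_network(RandomNetSpec(n=8, k=2, seed=seed))
        state = {n: (seed >> i) & 1 for i, n in enumerate(net.nodes)}
        succ = async_successors(state, net)
        disagreeing = sum(
            1 for n in net.nodes if net.rules[n].evaluate(state) != state[n]
        )
        assert len(succ) == disagreeing

    def test_sync_updates_all_at_once(self, toy2):
        succ = sync_successor({"A": 0, "B": 0}, toy2)
        assert succ.as_dict() == {"A": 1, "B": 1}

    def test_async_fixed_point_is_sync_fixed_point(self, sin):
        clamps = stage_clamps("early_mitosis", sin)
        (fp,) = find_fixed_points(sin, clamps)
        assert sync_successor(fp, sin, clamps) == fp

    def test_sin_early_mitosis_first_sync_step(self, sin):
        clamps = stage_clamps("early_mitosis", sin)
        start = {n: clamps.get(n, 0) for n in sin.nodes}
        succ = sync_successor(start, sin, clamps)
        assert succ["Fin1"] == 1 and succ["Plo1"] == 1

    def test_state_clamp_inconsistency_raises(self, toggle_net):
        with pytest.raises(ClampInconsistency):
            async_successors({"A": 0}, toggle_net, {"A": 1})

    def test_bad_clamp_values_and_unknown_nodes_rejected(self, toggle_net):
        with pytest.raises(ClampInconsistency):
            async_successors({"A": 0, "B": 0}, toggle_net, {"B": 0})
        with pytest.raises(ClampInconsistency):
            find_fixed_points(toggle_net, {"A": 2})


class TestTransitionGraph:
    def test_sin_stage_space_is_2_to_the_11(self, sin):
        stg = build_stg(sin, stage_clamps("late_mitosis", sin))
        assert stg.n_states == 2**11
        assert len(stg.free_nodes) == 11

    def test_zero_free_nodes_single_state(self):
        net = parse_rules("input A")
        stg = build_stg(net, {"A": 1})
        assert stg.n_states == 1 and stg.n_transitions == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_edge_count_matches_successor_recount(self, seed):
        net = random_network(RandomNetSpec(n=6, k=2, seed=seed))
        stg = build_stg(net)
        recount = sum(len(async_successors(s, net)) for s in stg.states())
        assert stg.n_transitions == recount

    def test_sync_out_degree_at_most_one(self):
        net = random_network(RandomNetSpec(n=6, k=2, seed=3))
        stg = build_stg(net, mode="synchronous")
        assert max((d for _, d in stg.graph.out_degree()), default=0) <= 1

    def test_cap_exceeded_names_count(self, sin):
        with pytest.raises(StateSpaceTooLarge, match="11"):
            build_stg(sin, stage_clamps("interphase", sin), cap=10)


class TestAttractors:
    def test_oscillator_is_one_cyclic_attractor_both_modes(self, toggle_net):
        for mode in ("asynchronous", "synchronous"):
            (att,) = find_attractors(toggle_net, mode=mode)
            assert att.kind == "cyclic" and len(att) == 2

    def test_bistable_toy_two_fixed_points(self, toy2):
        atts = find_attractors(toy2)
        assert [a.kind for a in atts] == ["fixed_point", "fixed_point"]

    def test_interphase_unique_inactive_fixed_point(self, sin):
        fps = find_fixed_points(sin, stage_clamps("interphase", sin))
        assert len(fps) == 1
        fp = fps[0]
        assert fp["GAP"] == 1
        assert all(fp[k] == 0 for k in ("Spg1", "Cdc7", "Sid1_Cdc14", "Sid2_Mob1"))

    def test_all_constant_rules_single_fixed_point(self):
        net = parse_rules("A := 1\nB := 0")
        assert len(find_fixed_points(net)) == 1

    @pytest.mark.parametrize("seed", range(30))
    def test_engine_matches_bruteforce_oracle(self, seed):
        net = random_network(RandomNetSpec(n=8, k=2, seed=seed))
        got = [
            frozenset(s.bits for s in att.states) for att in find_attractors(net)
        ]
        assert sorted(got, key=min) == oracle_attractors(net)

    @pytest.mark.parametrize("seed", range(30))
    def test_fixed_points_mode_independent_and_match_oracle(self, seed):
        net = random_network(
            RandomNetSpec(n=7, k=2, seed=seed, rule_family="random_truth_table")
        )
        fps = find_fixed_points(net)
        assert sorted(s.bits for s in fps) == oracle_fixed_points(net)
        sync_singletons = {
            a.states[0].bits
            for a in find_attractors(net, mode="synchronous")
            if a.is_fixed_point
        }
        async_singletons = {
            a.states[0].bits
            for a in find_attractors(net, mode="asynchronous")
            if a.is_fixed_point
        }
        assert sync_singletons == async_singletons == {s.bits for s in fps}

    @pytest.mark.parametrize("seed", range(10))
    def test_every_state_reaches_an_attractor(self, seed):
        import networkx as nx

        net = random_network(RandomNetSpec(n=6, k=2, seed=seed))
        stg = build_stg(net)
        atts = find_attractors(net)
        members = set()
        for a in atts:
            members |= {stg.index_of(s) for s in a.states}
        for i in range(stg.n_states):
            assert (i in members) or (nx.descendants(stg.graph, i) & members)

    def test_clamped_nodes_constant_across_attractors(self, sin):
        clamps = stage_clamps("late_mitosis", sin)
        for att in find_attractors(sin, clamps):
            for state in att.states:
                for node, value in clamps.items():
                    assert state[node] == value


class TestSummarize:
    def test_single_fixed_point_never_ambivalent(self, sin):
        atts = find_attractors(sin, stage_clamps("interphase", sin))
        assert "AMBIVALENT" not in summarize(atts).values()

    def test_complementary_fixed_points_are_ambivalent(self, toy2):
        summary = summarize(find_attractors(toy2))
        assert summary == {"A": "AMBIVALENT", "B": "AMBIVALENT"}

    def test_late_mitosis_plo1_on_terminal_kinase_ambivalent(self, sin):
        summary = summarize(find_attractors(sin, stage_clamps("late_mitosis", sin)))
        assert summary["Plo1"] == "ON"
        assert summary["Sid2_Mob1"] == "AMBIVALENT"

    def test_empty_attractor_list_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestReachability:
    def test_initial_state_restricts_to_basin(self, toy2):
        stg = build_stg(toy2)
        atts = find_attractors(toy2)
        reached = reachable_attractors(stg, atts, {"A": 1, "B": 0})
        assert len(reached) == 1
        assert reached[0].states[0].as_dict() == {"A": 1, "B": 0}

    def test_unconstrained_initial_reaches_all(self, toy2):
        stg = build_stg(toy2)
        atts = find_attractors(toy2)
        assert reachable_attractors(stg, atts, {}) == atts
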