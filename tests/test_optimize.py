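"""Optimization core: feasibility semantics, parametric subproblem,
Dinkelbach loop, fixed-size comparator, suboptimal enumeration."""

import numpy as np
import pytest

from deregsub import (
    SubgraphInstance,
    DirectedNetwork,
    InfeasibleInstance,
    SolverSettings,
    brute_force_optimal,
    check_feasible,
    solve,
    solve_fixed_size,
    solve_suboptimal,
    solve_union_over_sizes,
    union_summary,
)
from deregsub.optimize import separate_scc_violations, solve_parametric, write_solution

from conftest import random_instance


@pytest.fixture
def cycle_net():
    """Root feeding a 2-cycle: R1 -> A, B <-> C."""
    return DirectedNetwork(
        ["R1", "A", "B", "C"], [("R1", "A"), ("B", "C"), ("C", "B")]
    )


def make_instance(net, score=None, **kw):
    score = score or {v: 1.0 for v in net.nodes}
    kw.setdefault("k_min", 1)
    kw.setdefault("k_max", len(net))
    return SubgraphInstance(network=net, score=score, **kw)


class TestCheckFeasible:
    def test_valid_chain(self):
        net = DirectedNetwork(["R1", "A", "B"], [("R1", "A"), ("A", "B")])
        inst = make_instance(
            net, receptors=frozenset({"R1"}), terminals=frozenset({"B"}),
            k_min=2, k_max=3,
        )
        ok, tags = check_feasible(inst, {"R1", "A", "B"}, "R1")
        assert ok and tags == []

    def test_uncovered_cycle_flags_connectivity_row(self, cycle_net):
        inst = make_instance(cycle_net, k_min=1, k_max=4)
        ok, tags = check_feasible(inst, {"R1", "B", "C"}, "R1")
        assert not ok
        assert tags == ["1f"]

    def test_isolated_node_flags_in_neighbor_row(self):
        net = DirectedNetwork("ABCD", [("A", "B"), ("C", "D")])
        inst = make_instance(net)
        ok, tags = check_feasible(inst, {"A", "B", "C"}, "A")
        assert not ok
        assert tags == ["1e"]

    def test_multiple_violations_all_tagged(self):
        net = DirectedNetwork("ABCD", [("A", "B"), ("C", "D")])
        inst = make_instance(
            net, receptors=frozenset({"C"}), exclude=frozenset({"B"}),
            k_min=3, k_max=4,
        )
        ok, tags = check_feasible(inst, {"A", "B"}, "A")
        assert not ok
        assert set(tags) == {"1d", "1g", "1j"}

    def test_root_outside_set_and_unknown_root(self):
        net = DirectedNetwork("AB", [("A", "B")])
        inst = make_instance(net)
        ok, tags = check_feasible(inst, {"B"}, "A")
        assert not ok and "1b" in tags
        with pytest.raises(ValueError):
            check_feasible(inst, {"A"}, "Z")

    def test_terminal_and_include_tags(self):
        net = DirectedNetwork("ABC", [("A", "B"), ("B", "C")])
        inst = make_instance(
            net, terminals=frozenset({"C"}), include=frozenset({"C"}),
            k_min=1, k_max=3,
        )
        ok, tags = check_feasible(inst, {"A", "B"}, "A")
        assert not ok
        assert set(tags) == {"1h", "1i"}


class TestSeparation:
    def test_uncovered_two_cycle_detected(self, cycle_net):
        inst = make_instance(cycle_net)
        assert separate_scc_violations(inst, {"R1", "B", "C"}, "R1") == [
            frozenset({"B", "C"})
        ]

    def test_covered_cycle_not_violating(self):
        net = DirectedNetwork(
            ["R1", "A", "B", "C"],
            [("R1", "A"), ("A", "B"), ("B", "C"), ("C", "B")],
        )
        inst = make_instance(net)
        assert separate_scc_violations(inst, {"R1", "A", "B", "C"}, "R1") == []

    def test_acyclic_selection_clean(self):
        net = DirectedNetwork("ABC", [("A", "B"), ("B", "C")])
        inst = make_instance(net)
        assert separate_scc_violations(inst, {"A", "B", "C"}, "A") == []


class TestParametric:
    def test_zero_weight_picks_max_total(self, triangle):
        inst = SubgraphInstance(
            network=triangle, score={"A": 1, "B": 0.5, "C": 1},
            receptors=frozenset("A"), terminals=frozenset("C"),
            k_min=2, k_max=3,
        )
        nodes, root, val = solve_parametric(inst, 0.0)
        assert nodes == {"A", "B", "C"} and root == "A" and val == pytest.approx(2.5)

    def test_unit_weight_prefers_dense_scores(self, triangle):
        inst = SubgraphInstance(
            network=triangle, score={"A": 1, "B": 0.5, "C": 1},
            receptors=frozenset("A"), terminals=frozenset("C"),
            k_min=2, k_max=3,
        )
        nodes, root, val = solve_parametric(inst, 1.0)
        assert nodes == {"A", "C"} and val == pytest.approx(0.0)

    def test_exclude_everything_infeasible(self, triangle):
        inst = SubgraphInstance(
            network=triangle, score={v: 1.0 for v in triangle.nodes},
            exclude=frozenset(triangle.nodes) - frozenset("A"),
            k_min=2, k_max=3,
        )
        with pytest.raises(InfeasibleInstance):
            solve_parametric(inst, 0.0)


class TestSolve:
    def test_average_beats_total(self, triangle_instance):
        sol = solve(triangle_instance)
        assert sol.node_set == {"A", "C"}
        assert sol.objective == pytest.approx(1.0)
        assert sol.converged

    def test_forced_size_three(self, triangle):
        inst = SubgraphInstance(
            network=triangle, score={"A": 1, "B": 0, "C": 1},
            receptors=frozenset("A"), terminals=frozenset("C"),
            k_min=3, k_max=3,
        )
        sol = solve(inst)
        assert sol.node_set == {"A", "B", "C"}
        assert sol.objective == pytest.approx(2 / 3)

    def test_single_node(self):
        net = DirectedNetwork(["A", "B"], [("A", "B")])
        inst = SubgraphInstance(
            network=net, score={"A": 5.0, "B": 0.0},
            receptors=frozenset("A"), k_min=1, k_max=1,
        )
        sol = solve(inst)
        assert sol.node_set == {"A"} and sol.objective == pytest.approx(5.0)

    def test_minimize_mirrors_negated_maximize(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            inst = random_instance(rng, sense="minimize")
            neg = SubgraphInstance(
                network=inst.network,
                score={v: -s for v, s in inst.score.items()},
                receptors=inst.receptors,
                terminals=inst.terminals,
                k_min=inst.k_min,
                k_max=inst.k_max,
                sense="maximize",
            )
            try:
                lo = solve(inst)
            except InfeasibleInstance:
                with pytest.raises(InfeasibleInstance):
                    solve(neg)
                continue
            hi = solve(neg)
            assert lo.objective == pytest.approx(-hi.objective, abs=1e-9)

    def test_shift_invariance_of_argmax(self):
        rng = np.random.default_rng(6)
        inst = random_instance(rng)
        shifted = SubgraphInstance(
            network=inst.network,
            score={v: s + 10.0 for v, s in inst.score.items()},
            receptors=inst.receptors,
            terminals=inst.terminals,
            k_min=inst.k_min,
            k_max=inst.k_max,
        )
        a, b = solve(inst), solve(shifted)
        assert b.objective == pytest.approx(a.objective + 10.0, abs=1e-7)

    def test_reverse_mode_equals_forward_on_reversed(self, triangle):
        inst_rev = SubgraphInstance(
            network=triangle, score={"A": 1, "B": 0, "C": 1},
            receptors=frozenset("A"), terminals=frozenset("C"),
            k_min=2, k_max=3, mode="reverse",
        )
        inst_fwd = SubgraphInstance(
            network=triangle.reverse(), score={"A": 1, "B": 0, "C": 1},
            receptors=frozenset("C"), terminals=frozenset("A"),
            k_min=2, k_max=3,
        )
        a, b = solve(inst_rev), solve(inst_fwd)
        assert a.node_set == b.node_set
        assert a.objective == pytest.approx(b.objective)

    def test_absolute_uses_magnitudes(self, triangle):
        inst = SubgraphInstance(
            network=triangle, score={"A": -3.0, "B": 0.1, "C": -3.0},
            receptors=frozenset("A"), terminals=frozenset("C"),
            k_min=2, k_max=3, absolute=True,
        )
        sol = solve(inst)
        assert sol.node_set == {"A", "C"}
        assert sol.objective == pytest.approx(3.0)

    def test_include_and_exclude_respected(self, triangle):
        inst = SubgraphInstance(
            network=triangle, score={"A": 1, "B": 0, "C": 1},
            receptors=frozenset("A"),
            include=frozenset("B"), k_min=2, k_max=3,
        )
        sol = solve(inst)
        assert "B" in sol.node_set


class TestFixedSizeAndUnion:
    def test_fixed_sizes(self, triangle):
        score = {"A": 1.0, "B": 0.0, "C": 1.0}
        s2 = solve_fixed_size(triangle, score, 2, frozenset("A"), frozenset("C"))
        assert s2.node_set == {"A", "C"} and s2.total_score == pytest.approx(2.0)
        s3 = solve_fixed_size(triangle, score, 3, frozenset("A"), frozenset("C"))
        assert s3.node_set == {"A", "B", "C"} and s3.total_score == pytest.approx(2.0)

    def test_size_one_conflicts_with_roles(self, triangle):
        with pytest.raises(InfeasibleInstance):
            solve_fixed_size(
                triangle, {"A": 1, "B": 0, "C": 1}, 1,
                frozenset("A"), frozenset("C"),
            )

    def test_union_over_sizes(self, triangle):
        union = solve_union_over_sizes(
            triangle, {"A": 1, "B": 0, "C": 1}, 2, 3,
            frozenset("A"), frozenset("C"),
        )
        assert union == {"A", "B", "C"}

    def test_union_skips_infeasible_sizes(self, triangle):
        union = solve_union_over_sizes(
            triangle, {"A": 1, "B": 0, "C": 1}, 1, 2,
            frozenset("A"), frozenset("C"),
        )
        assert union == {"A", "C"}  # k=1 infeasible, skipped

    def test_unique_path(self):
        net = DirectedNetwork(["R1", "A", "B"], [("R1", "A"), ("A", "B")])
        union = solve_union_over_sizes(
            net, {v: 1.0 for v in net.nodes}, 3, 3,
            frozenset({"R1"}), frozenset({"B"}),
        )
        assert union == {"R1", "A", "B"}


class TestSuboptimal:
    def test_enumeration_order_and_exhaustion(self, triangle_instance):
        sols = solve_suboptimal(triangle_instance, 5)
        assert [s.rank for s in sols] == [0, 1]
        assert sols[0].node_set == {"A", "C"}
        assert sols[1].node_set == {"A", "B", "C"}
        assert sols[0].objective >= sols[1].objective

    def test_zero_extras(self, triangle_instance):
        sols = solve_suboptimal(triangle_instance, 0)
        assert len(sols) == 1 and sols[0].rank == 0

    def test_objectives_non_increasing_random(self):
        rng = np.random.default_rng(8)
        inst = random_instance(rng)
        try:
            sols = solve_suboptimal(inst, 3)
        except InfeasibleInstance:
            pytest.skip("random instance infeasible")
        objs = [s.objective for s in sols]
        assert objs == sorted(objs, reverse=True)
        assert len({s.node_set for s in sols}) == len(sols)


class TestUnionSummary:
    def test_frequencies(self, triangle, triangle_instance):
        sols = solve_suboptimal(triangle_instance, 1)
        summary = union_summary(sols, triangle)
        assert summary.network.node_set == {"A", "B", "C"}
        assert summary.frequency == {"A": 2, "B": 1, "C": 2}

    def test_disjoint_singletons(self):
        net = DirectedNetwork("AB", [])
        from deregsub import SubgraphSolution

        sols = [
            SubgraphSolution(frozenset("A"), "A", 1.0, 1.0),
            SubgraphSolution(frozenset("B"), "B", 1.0, 1.0),
        ]
        summary = union_summary(sols, net)
        assert summary.network.node_set == {"A", "B"}
        assert summary.network.edges == ()


class TestBruteForce:
    def test_matches_solve_on_triangle(self, triangle_instance):
        bf = brute_force_optimal(triangle_instance)
        sol = solve(triangle_instance)
        assert bf.objective == pytest.approx(sol.objective)
        assert bf.node_set == {"A", "C"}

    def test_whole_graph_when_forced(self, triangle):
        inst = SubgraphInstance(
            network=triangle, score={v: 1.0 for v in triangle.nodes},
            k_min=3, k_max=3,
        )
        assert brute_force_optimal(inst).node_set == {"A", "B", "C"}

    def test_all_excluded_infeasible(self, triangle):
        inst = SubgraphInstance(
            network=triangle, score={v: 1.0 for v in triangle.nodes},
            exclude=frozenset("BC"), k_min=2, k_max=3,
        )
        with pytest.raises(InfeasibleInstance):
            brute_force_optimal(inst)

    def test_size_cap(self):
        rng = np.random.default_rng(0)
        from conftest import random_digraph

        net = random_digraph(rng, 16)
        inst = SubgraphInstance(network=net, score={v: 1.0 for v in net.nodes}, k_min=2, k_max=3)
        with pytest.raises(ValueError):
            brute_force_optimal(inst)


class TestSerialization:
    def test_graphml_and_sidecar(self, tmp_path, triangle_instance):
        sol = solve(triangle_instance)
        graphml, sidecar = write_solution(sol, triangle_instance, tmp_path / "sol")
        assert graphml.exists() and sidecar.exists()
        import json

        data = json.loads(sidecar.read_text())
        assert data["objective"] == pytest.approx(1.0)
        assert set(data["nodes"]) == {"A", "C"}
        assert data["root"] == "A"
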