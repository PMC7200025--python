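"""Flow algebra: overlaps, flux, missing input, hidden-input inference."""

import networkx as nx
import numpy as np
import pytest

from regulonflow import OperonMap, PathwayGraph, ValidationError
from regulonflow.flow import (
    UndefinedOverlapError,
    build_flux_regulons,
    infer_hidden_inputs,
    overlap_fraction,
    quantify_flow,
)
from regulonflow.regulons import DifferentialRecord, Regulon, ThresholdPolicy

from oracles import brute_force_flow


def R(name, genes):
    return Regulon(name, set(genes))


# ---------------------------------------------------------------- overlap

def test_identical_regulons_overlap_100():
    pct, genes = overlap_fraction(R("a", {"g1", "g2"}), R("b", {"g1", "g2"}))
    assert pct == 100.0 and genes == {"g1", "g2"}


def test_disjoint_regulons_overlap_0():
    pct, genes = overlap_fraction(R("a", {"g1"}), R("b", {"g2"}))
    assert pct == 0.0 and genes == set()


def test_overlap_denominator_choices():
    a, b = R("a", {"g1", "g2", "g3", "g4"}), R("b", {"g3", "g4", "g5"})
    assert overlap_fraction(a, b, "first")[0] == pytest.approx(50.0)
    assert overlap_fraction(a, b, "second")[0] == pytest.approx(200 / 3)
    assert overlap_fraction(a, b, "union")[0] == pytest.approx(40.0)


def test_empty_denominator_raises():
    with pytest.raises(UndefinedOverlapError):
        overlap_fraction(R("a", set()), R("b", {"g1"}), "first")


# ---------------------------------------------------------------- quantify

def test_chain_with_full_transmission(chain_pathway):
    D = R("direct", {f"g{i}" for i in range(10)})
    regs = {"X": R("X", D.members), "Y": R("Y", D.members),
            "Z": R("Z", D.members)}
    res = quantify_flow(chain_pathway, regs, D)
    assert res.node_input_pct == {"X": 100.0, "Y": 100.0, "Z": 100.0}
    assert res.edge_flux_pct == {("X", "Y"): 100.0, ("Y", "Z"): 100.0}
    assert res.missing_input_pct == {"Y": 0.0, "Z": 0.0}


def test_hand_enumerated_two_predecessor_example():
    # D = g1..g10; A covers g1..g6, B covers g5..g8; fluxes sum past input
    pw = PathwayGraph([("A", "A", False), ("B", "B", False), ("Y", "Y", False)],
                      [("A", "Y"), ("B", "Y")], "Y")
    D = R("direct", {f"g{i}" for i in range(1, 11)})
    regs = {"A": R("A", {f"g{i}" for i in range(1, 7)}),
            "B": R("B", {f"g{i}" for i in range(5, 9)}),
            "Y": R("Y", D.members | {"extra"})}
    res = quantify_flow(pw, regs, D)
    assert res.edge_flux_pct[("A", "Y")] == 60.0
    assert res.edge_flux_pct[("B", "Y")] == 40.0
    assert res.missing_input_pct["Y"] == 20.0
    assert res.node_input_pct["Y"] == 100.0
    total_flux = sum(res.edge_flux_pct.values())
    assert total_flux == 100.0  # 60 + 40: shared genes counted per edge
    assert total_flux + res.missing_input_pct["Y"] > res.node_input_pct["Y"]


def _random_instance(rng):
    n_nodes = int(rng.integers(2, 6))
    names = [f"n{i}" for i in range(n_nodes)]
    genes = [f"g{i}" for i in range(int(rng.integers(1, 21)))]
    edges = [(names[i], names[j])
             for i in range(n_nodes) for j in range(i + 1, n_nodes)
             if rng.random() < 0.5]
    sink = names[-1]
    if not any(v == sink for _, v in edges) and n_nodes > 1:
        edges.append((names[0], sink))
    pw = PathwayGraph([(n, n, False) for n in names], edges, sink)
    regs = {n: R(n, {g for g in genes if rng.random() < 0.5}) for n in names}
    direct = {g for g in genes if rng.random() < 0.6} or {genes[0]}
    regs[sink] = R(sink, regs[sink].members | direct)
    return pw, regs, R("direct", direct), genes


def test_flow_equals_brute_force_enumeration(rng):
    for _ in range(50):
        pw, regs, direct, genes = _random_instance(rng)
        res = quantify_flow(pw, regs, direct)
        node_sets = {n: regs[n].members for n in regs}
        o_input, o_flux, o_missing = brute_force_flow(
            pw.edges, node_sets, direct.members, genes)
        for n in pw.nodes:
            assert res.node_input_pct[n] == pytest.approx(o_input[n])
        for e in pw.edges:
            assert res.edge_flux_pct[e] == pytest.approx(o_flux[e])
        for n in o_missing:
            assert res.missing_input_pct[n] == pytest.approx(o_missing[n])


def test_flow_invariants_on_random_instances(rng):
    for _ in range(30):
        pw, regs, direct, _ = _random_instance(rng)
        res = quantify_flow(pw, regs, direct)
        step = 100.0 / res.reference_size
        for pct in (list(res.node_input_pct.values())
                    + list(res.edge_flux_pct.values())
                    + list(res.missing_input_pct.values())):
            assert 0.0 <= pct <= 100.0
            assert pct / step == pytest.approx(round(pct / step))  # gene counts
        # the sink regulon contains D, so its input is 100%
        assert res.node_input_pct[pw.sink] == 100.0
        for node, miss in res.missing_input_pct.items():
            preds = pw.predecessors(node)
            flux_sum = sum(res.edge_flux_pct[(p, node)] for p in preds)
            assert res.node_input_pct[node] <= miss + flux_sum + 1e-9
            pred_sets = [regs[p].members & direct.members for p in preds]
            disjoint = all(not (a & b) for i, a in enumerate(pred_sets)
                           for b in pred_sets[i + 1:])
            if disjoint:
                assert res.node_input_pct[node] == pytest.approx(miss + flux_sum)


def test_missing_input_shrinks_when_predecessor_regulon_grows(chain_pathway):
    D = R("direct", {f"g{i}" for i in range(10)})
    regs = {"X": R("X", {"g0", "g1"}), "Y": R("Y", D.members),
            "Z": R("Z", D.members)}
    before = quantify_flow(chain_pathway, regs, D)
    regs["X"] = R("X", {"g0", "g1", "g2", "g3"})
    after = quantify_flow(chain_pathway, regs, D)
    assert after.missing_input_pct["Y"] <= before.missing_input_pct["Y"]
    assert after.edge_flux_pct[("X", "Y")] >= before.edge_flux_pct[("X", "Y")]


def test_node_without_regulon_and_empty_direct_raise(chain_pathway):
    D = R("direct", {"g1"})
    with pytest.raises(ValidationError, match="no regulon"):
        quantify_flow(chain_pathway, {"X": D, "Z": D}, D)
    with pytest.raises(ValidationError, match="empty"):
        quantify_flow(chain_pathway, {"X": D, "Y": D, "Z": D},
                      R("direct", set()))


def test_declared_hidden_node_uses_neighbor_set_algebra():
    pw = PathwayGraph(
        [("A", "A", False), ("B", "B", False), ("H", None, True),
         ("Z", "Z", False)],
        [("A", "H"), ("B", "H"), ("H", "Z")], "Z")
    D = R("direct", {"g1", "g2", "g3", "g4"})
    regs = {"A": R("A", {"g1", "g9"}), "B": R("B", {"g2"}),
            "Z": R("Z", D.members)}
    res = quantify_flow(pw, regs, D)
    # R_H = (R_A ∪ R_B) ∩ R_Z = {g1, g2}
    assert res.node_input_pct["H"] == 50.0
    assert res.edge_flux_pct[("H", "Z")] == 50.0


# ---------------------------------------------------------------- hidden inference

def test_no_missing_input_leaves_graph_unchanged(chain_pathway):
    D = R("direct", {"g1"})
    regs = {n: R(n, {"g1"}) for n in "XYZ"}
    flow = quantify_flow(chain_pathway, regs, D)
    augmented = infer_hidden_inputs(chain_pathway, flow)
    assert augmented == chain_pathway


def test_one_leaky_node_gets_exactly_one_hidden_input(chain_pathway):
    D = R("direct", {f"g{i}" for i in range(10)})
    regs = {"X": R("X", {f"g{i}" for i in range(8)}),
            "Y": R("Y", D.members), "Z": R("Z", D.members)}
    flow = quantify_flow(chain_pathway, regs, D)
    assert flow.missing_input_pct["Y"] == 20.0
    augmented = infer_hidden_inputs(chain_pathway, flow)
    new_nodes = set(augmented.nodes) - set(chain_pathway.nodes)
    assert new_nodes == {"missing_Y"}
    assert ("missing_Y", "Y") in augmented.edges
    assert augmented.is_hidden("missing_Y")


def test_threshold_suppresses_small_leaks(chain_pathway):
    D = R("direct", {f"g{i}" for i in range(10)})
    regs = {"X": R("X", {f"g{i}" for i in range(9)}),
            "Y": R("Y", D.members), "Z": R("Z", D.members)}
    flow = quantify_flow(chain_pathway, regs, D)
    assert infer_hidden_inputs(chain_pathway, flow, threshold_pct=15.0) \
        == chain_pathway


# ---------------------------------------------------------------- flux regulons

def test_weak_gene_excluded_from_strict_but_in_flux_regulon():
    from regulonflow import call_regulon

    records = {"DivJ": [DifferentialRecord("g1", 0.6, 0.4, 100.0)]}
    assert len(call_regulon(records["DivJ"], ThresholdPolicy.deletion())) == 0
    flux = build_flux_regulons(records, {"DivJ": "deletion"})
    assert flux["DivJ"].members == {"g1"}


def test_depletion_flux_regulon_equals_strict_regulon(small_operons):
    from regulonflow import call_regulon

    records = {"ChpT": [DifferentialRecord("g2", 2.0, 0.01, 100.0),
                        DifferentialRecord("g9", 2.0, 0.5, 100.0)]}
    flux = build_flux_regulons(records, {"ChpT": "depletion"}, small_operons)
    strict = call_regulon(records["ChpT"], ThresholdPolicy.depletion(),
                          small_operons, node="ChpT")
    assert flux["ChpT"] == strict


def test_flux_regulons_contain_strict_regulons(rng):
    from regulonflow import call_regulon

    for _ in range(10):
        records = [DifferentialRecord(f"g{i}", float(rng.normal(0, 1.5)),
                                      float(rng.uniform(0, 1)),
                                      float(rng.uniform(0, 200)))
                   for i in range(50)]
        for mode, policy in (("deletion", ThresholdPolicy.deletion()),
                             ("depletion", ThresholdPolicy.depletion())):
            flux = build_flux_regulons({"n": records}, {"n": mode})
            strict = call_regulon(records, policy, node="n")
            assert strict.members <= flux["n"].members
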