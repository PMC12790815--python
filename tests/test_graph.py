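import numpy as np
import pandas as pd
import pytest

from ckgmed.cohort import Cohort
from ckgmed.errors import FormatError, StructuralError
from ckgmed.graph import (CKGraph, assign_population, load_graph,
                          normalize_icd, write_graph)

from oracles import random_dag


def test_icd_normalisation_strips_dots_and_uppercases():
    assert normalize_icd("E11.9") == "E119"
    assert normalize_icd(" e11 ") == "E11"


def test_hand_built_graph_structure(toy_graph):
    assert toy_graph.diseases() == {"A00", "B00", "C00", "C001"}
    assert toy_graph.drugs() == {"RX1", "RX2", "RX3"}
    assert toy_graph.edges_of("progression") == {("A00", "B00"), ("B00", "C00")}
    assert toy_graph.drugs_indicated_for("A00") == {"RX1", "RX2"}


def test_causal_subgraph_inverts_indications(toy_graph):
    dag = toy_graph.causal_subgraph()
    assert dag.has_edge("A00", "RX1")       # inverse of indication
    assert dag.has_edge("A00", "B00")       # progression kept as-is
    assert not dag.has_edge("RX1", "C00")   # side_effect excluded
    assert not dag.has_edge("C001", "C00")  # is_a excluded
    # pure function of the edge set
    again = toy_graph.causal_subgraph()
    assert set(dag.edges) == set(again.edges) and set(dag.nodes) == set(again.nodes)


def test_is_a_only_graph_has_empty_causal_subgraph():
    g = CKGraph.from_edges([("A001", "is_a", "A00")])
    assert g.causal_subgraph().number_of_edges() == 0


def test_progression_cycle_is_a_structural_error():
    with pytest.raises(StructuralError, match="causal subgraph"):
        CKGraph.from_edges([("A00", "progression", "B00"),
                            ("B00", "progression", "A00")])


def test_is_a_cycle_is_a_structural_error():
    with pytest.raises(StructuralError, match="is_a"):
        CKGraph.from_edges([("A00", "is_a", "B00"), ("B00", "is_a", "A00")])


def test_unknown_relation_and_mixed_kind_rejected():
    with pytest.raises(FormatError, match="relation"):
        CKGraph.from_edges([("A00", "treats", "B00")])
    with pytest.raises(FormatError, match="both"):
        # RX used as drug (indication source) and as disease (progression source)
        CKGraph.from_edges([("RX", "indication", "A00"),
                            ("RX", "progression", "B00")])


def test_load_is_idempotent_and_deduplicated(tmp_path):
    dag = random_dag(20, 0.2, seed=5)
    edges = [(u, v) for u, v in dag.edges][:50]
    df = pd.DataFrame(edges * 2, columns=["source", "target"])  # duplicates
    g1 = load_graph({"progression": df})
    g2 = load_graph({"progression": df})
    assert g1.edges == g2.edges
    assert len(g1.edges_of("progression")) == len(set(edges))


def test_write_then_load_round_trips(toy_graph, tmp_path):
    write_graph(toy_graph, tmp_path)
    reloaded = load_graph({rel: tmp_path / f"{rel}.tsv"
                           for rel in ("progression", "indication",
                                       "side_effect", "is_a")})
    assert reloaded.edges == toy_graph.edges
    assert dict(reloaded.nodes) == dict(toy_graph.nodes)


def test_ntriples_export_is_sorted_and_stable(toy_graph):
    out = toy_graph.to_ntriples()
    assert out == toy_graph.to_ntriples()
    assert list(out.strip().splitlines()) == sorted(out.strip().splitlines())


# ---------------------------------------------------------------------------
# population assignment


def _cohort(diag_rows, presc_rows, persons):
    cov = pd.DataFrame({"person_id": list(persons)})
    cov["age"] = 50
    return Cohort(
        pd.DataFrame(diag_rows, columns=["person_id", "icd10", "date"]),
        pd.DataFrame(presc_rows, columns=["person_id", "rxnorm", "date"]),
        cov, pd.Series(True, index=list(persons)),
    )


def test_child_diagnosis_propagates_to_is_a_ancestor():
    g = CKGraph.from_edges([("E119", "is_a", "E11"),
                            ("E11", "progression", "I10")])
    cohort = _cohort([("p1", "E11.9", "2001-01-01")], [], ["p1"])
    pa = assign_population(g, cohort)
    assert pa.membership["E119"] == {"p1"}
    assert pa.membership["E11"] == {"p1"}   # via is_a subsumption
    assert pa.membership["I10"] == frozenset()


def test_empty_cohort_gives_zero_measure(toy_graph):
    pa = assign_population(toy_graph, _cohort([], [], []))
    assert all(m == frozenset() for m in pa.membership.values())
    assert pa.measure("A00") == 0.0


def test_membership_matches_brute_force_closure():
    """On a random 20-code hierarchy with 100 persons, f equals explicit
    ancestor-set propagation."""
    rng = np.random.default_rng(7)
    codes = [f"C{i:02d}" for i in range(20)]
    edges = []
    for i in range(1, 20):  # random forest: each code under a previous one
        parent = codes[rng.integers(0, i)]
        edges.append((codes[i], "is_a", parent))
    g = CKGraph.from_edges(edges)
    persons = [f"p{i}" for i in range(100)]
    diag = [(p, codes[rng.integers(0, 20)], "2001-01-01")
            for p in persons for _ in range(rng.integers(1, 4))]
    cohort = _cohort(diag, [], persons)
    pa = assign_population(g, cohort)

    # oracle: walk every diagnosis up through explicit parent links
    parent_of = {s: t for s, _, t in edges}
    expected = {c: set() for c in codes}
    for p, code, _ in diag:
        node = code
        while node is not None:
            expected[node].add(p)
            node = parent_of.get(node)
    for code in codes:
        assert pa.membership[code] == frozenset(expected[code]), code


def test_subsumption_closure_and_measure_monotonicity():
    g = CKGraph.from_edges([("A001", "is_a", "A00"), ("A0011", "is_a", "A001")])
    diag = [("p1", "A0011", "2001-01-01"), ("p2", "A001", "2001-01-01"),
            ("p3", "A00", "2001-01-01")]
    pa = assign_population(g, _cohort(diag, [], ["p1", "p2", "p3", "p4"]))
    for child, rel, parent in g.edges:
        if rel == "is_a":
            assert pa.membership[child] <= pa.membership[parent]
            assert pa.measure(child) <= pa.measure(parent)
    assert pa.measure(pa.population) == 1.0
    assert pa.measure(frozenset()) == 0.0
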