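import itertools

import networkx as nx
import numpy as np
import pytest

from ckgmed.adjustment import (AdjustmentSet, add_hypothesis_edge,
                               backdoor_sets, d_separated,
                               disjunctive_cause_set, is_valid_backdoor_set,
                               prune_hierarchy)
from ckgmed.errors import UntestableHypothesis
from ckgmed.graph import CKGraph

from oracles import backdoor_valid, d_separated_paths, minimal_backdoor_sets, random_dag


def dag_of(*edges):
    g = nx.DiGraph()
    g.add_edges_from(edges)
    return g


# ---------------------------------------------------------------------------
# d-separation


def test_confounder_triangle_blocking():
    g = dag_of(("C", "T"), ("C", "Y"))
    assert d_separated(g, {"T"}, {"Y"}, {"C"})
    assert not d_separated(g, {"T"}, {"Y"}, set())


def test_collider_conditioning_opens_the_path():
    g = dag_of(("T", "K"), ("Y", "K"))
    assert d_separated(g, {"T"}, {"Y"}, set())
    assert not d_separated(g, {"T"}, {"Y"}, {"K"})


def test_missing_node_is_a_lookup_error():
    g = dag_of(("A", "B"))
    with pytest.raises(KeyError):
        d_separated(g, {"A"}, {"Z"}, set())


def test_overlapping_sets_rejected():
    g = dag_of(("A", "B"), ("B", "C"))
    with pytest.raises(ValueError):
        d_separated(g, {"A"}, {"B"}, {"B"})


@pytest.mark.parametrize("seed", range(40))
def test_agrees_with_path_enumeration_oracle(seed):
    """Exhaustive (A,B,Z) agreement on random DAGs (acceptance runs 200)."""
    rng = np.random.default_rng(seed)
    g = random_dag(int(rng.integers(4, 8)), 0.3, seed)
    nodes = sorted(g.nodes)
    for a, b in itertools.combinations(nodes, 2):
        rest = [x for x in nodes if x not in (a, b)]
        for k in range(len(rest) + 1):
            for z in itertools.combinations(rest, k):
                assert d_separated(g, {a}, {b}, set(z)) == \
                    d_separated_paths(g, a, b, set(z)), (a, b, z)


# ---------------------------------------------------------------------------
# backdoor criterion


def test_confounder_triangle_chooses_the_confounder():
    g = dag_of(("C", "T"), ("C", "Y"), ("T", "Y"))
    assert backdoor_sets(g, "T", "Y").covariates == {"C"}


def test_no_backdoor_path_gives_the_empty_set():
    g = dag_of(("T", "Y"))
    assert backdoor_sets(g, "T", "Y").covariates == frozenset()


def test_forbidden_mediator_is_never_admitted():
    g = dag_of(("C", "T"), ("C", "Y"), ("T", "M"), ("M", "Y"))
    adj = backdoor_sets(g, "T", "Y", forbidden={"M"})
    assert "M" not in adj.covariates


def test_enumeration_is_deterministic():
    g = random_dag(7, 0.4, seed=3)
    first = backdoor_sets(g, "n0", "n6").covariates
    for _ in range(3):
        assert backdoor_sets(g, "n0", "n6").covariates == first


@pytest.mark.parametrize("seed", range(40))
def test_chosen_set_is_valid_and_minimal(seed):
    """Validity and minimality vs full subset enumeration on random DAGs."""
    rng = np.random.default_rng(1000 + seed)
    g = random_dag(int(rng.integers(4, 9)), 0.3, 1000 + seed)
    nodes = sorted(g.nodes)
    t, y = nodes[0], nodes[-1]
    minimal = minimal_backdoor_sets(g, t, y)
    if not minimal:
        with pytest.raises(UntestableHypothesis):
            backdoor_sets(g, t, y)
        return
    adj = backdoor_sets(g, t, y)
    assert backdoor_valid(g, t, y, adj.covariates)
    assert is_valid_backdoor_set(g, t, y, adj.covariates)
    assert len(adj.covariates) == len(minimal[0])
    assert adj.covariates in minimal
    assert not adj.covariates & nx.descendants(g, t)


def test_cap_limits_valid_set_collection():
    # a graph with no backdoor path has many valid sets; cap=1 still returns
    # the first-encountered minimum (the empty set)
    g = dag_of(("T", "Y"), ("T", "A"), ("A", "B"))
    g.add_nodes_from(["C1", "C2", "C3"])
    assert backdoor_sets(g, "T", "Y", cap=1).covariates == frozenset()


# ---------------------------------------------------------------------------
# disjunctive cause criterion


def test_disjunctive_takes_parents_of_treatment_and_outcome():
    g = dag_of(("C1", "T"), ("C2", "Y"), ("C3", "T"), ("C3", "Y"), ("T", "Y"))
    adj = disjunctive_cause_set(g, "T", "Y")
    assert adj.covariates == {"C1", "C2", "C3"}


def test_isolated_nodes_give_empty_disjunctive_set():
    g = nx.DiGraph()
    g.add_nodes_from(["T", "Y"])
    assert disjunctive_cause_set(g, "T", "Y").covariates == frozenset()


def test_disjunctive_never_contains_the_mediator():
    g = dag_of(("T", "M"), ("M", "Y"), ("C", "T"), ("C", "Y"))
    adj = disjunctive_cause_set(g, "T", "Y", mediator="M")
    assert "M" not in adj.covariates
    assert adj.covariates == {"C"}


@pytest.mark.parametrize("seed", range(20))
def test_disjunctive_matches_brute_force_parent_union(seed):
    g = random_dag(8, 0.35, 2000 + seed)
    t, y = "n1", "n6"
    adj = disjunctive_cause_set(g, t, y)
    expected = (set(g.predecessors(t)) | set(g.predecessors(y))) - {t, y}
    assert adj.covariates == expected


# ---------------------------------------------------------------------------
# hypothesis edge and hierarchy pruning


def test_add_hypothesis_edge_is_pure_and_idempotent():
    g = dag_of(("X", "M"))
    g2 = add_hypothesis_edge(g, "M", "Y")
    assert g2.has_edge("M", "Y") and not g.has_edge("M", "Y")
    g3 = add_hypothesis_edge(g2, "M", "Y")
    assert set(g3.edges) == set(g2.edges)


def test_cycle_creating_edge_flags_untestable():
    g = dag_of(("Y", "M"))
    with pytest.raises(UntestableHypothesis):
        add_hypothesis_edge(g, "M", "Y")


def _hier_graph():
    return CKGraph.from_edges([
        ("E119", "is_a", "E11"),
        ("A11", "is_a", "A1"), ("A111", "is_a", "A11"),
    ])


def test_pruning_keeps_the_parent():
    g = _hier_graph()
    adj = AdjustmentSet(frozenset({"E11", "E119"}), "backdoor")
    assert prune_hierarchy(adj, g).covariates == {"E11"}


def test_pruning_three_level_chain_reaches_fixpoint():
    g = _hier_graph()
    adj = AdjustmentSet(frozenset({"A1", "A11", "A111"}), "backdoor")
    pruned = prune_hierarchy(adj, g)
    assert pruned.covariates == {"A1"}
    assert prune_hierarchy(pruned, g).covariates == {"A1"}  # idempotent


def test_pruning_leaves_unrelated_sets_unchanged():
    g = _hier_graph()
    adj = AdjustmentSet(frozenset({"E11", "A1", "RX1"}), "disjunctive")
    pruned = prune_hierarchy(adj, g)
    assert pruned.covariates == {"E11", "A1", "RX1"}
    assert len(pruned.covariates) <= len(adj.covariates)
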