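"""Graph-based adjustment-set identification for mediation hypotheses.

For each hypothesis the causal subgraph is augmented with a single candidate
edge drug→outcome, then one of two criteria selects covariates:

* **backdoor** — a set that blocks every backdoor path between treatment and
  outcome and contains no descendant of the treatment.  Candidate sets are
  enumerated in a deterministic order (increasing cardinality, then
  lexicographic); enumeration stops after a configurable number of valid
  sets (default 1000) and the minimum-cardinality set is returned,
  first-encountered on ties.
* **disjunctive cause** — all direct causes (graph parents) of the treatment
  or the outcome, excluding treatment, outcome and mediator.

Finally, when an adjustment set contains both a disease and one of its
is_a-ancestors, the more specific descendant is pruned to avoid redundant
adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .errors import UntestableHypothesis
from .graph import CKGraph

logger = logging.getLogger(__name__)

BACKDOOR = "backdoor"
DISJUNCTIVE = "disjunctive"


@dataclass(frozen=True)
class AdjustmentSet:
    covariates: frozenset
    criterion: str
    hypothesis: tuple | None = None
    pruned: bool = False


def add_hypothesis_edge(dag: nx.DiGraph, drug: str, outcome: str) -> nx.DiGraph:
    """Copy of ``dag`` with the candidate causal edge drug→outcome added.

    Idempotent if the edge already exists.  If the edge would create a
    cycle the hypothesis is untestable.
    """
    out = dag.copy()
    out.add_node(drug)
    out.add_node(outcome)
    if not out.has_edge(drug, outcome):
        out.add_edge(drug, outcome)
        if not nx.is_directed_acyclic_graph(out):
            raise UntestableHypothesis(
                f"edge {drug}->{outcome} would create a cycle in the causal graph"
            )
    return out


def d_separated(dag: nx.DiGraph, a, b, z) -> bool:
    """Standard d-separation of node sets ``a`` and ``b`` given ``z``.

    Chains and forks are blocked when the middle node is in ``z``; collider
    paths are blocked unless the collider or one of its descendants is in
    ``z``.
    """
    a, b, z = set(_as_set(a)), set(_as_set(b)), set(_as_set(z))
    for node in a | b | z:
        if node not in dag:
            raise KeyError(f"node {node!r} not in graph")
    if (a & b) or (a & z) or (b & z):
        raise ValueError("A, B and Z must be disjoint")
    return nx.is_d_separator(dag, a, b, z)


def _as_set(x):
    if isinstance(x, str):
        return {x}
    return set(x)


def is_valid_backdoor_set(
    dag: nx.DiGraph, treatment: str, outcome: str, z
) -> bool:
    """Backdoor validity: no treatment descendant in ``z`` and ``z``
    d-separates treatment from outcome once the treatment's outgoing edges
    are removed (only backdoor paths remain)."""
    z = frozenset(_as_set(z))
    if treatment in z or outcome in z:
        return False
    if z & nx.descendants(dag, treatment):
        return False
    mutilated = dag.copy()
    mutilated.remove_edges_from(list(dag.out_edges(treatment)))
    if not nx.has_path(mutilated.to_undirected(as_view=False), treatment, outcome):
        return True
    return d_separated(mutilated, {treatment}, {outcome}, z)


def backdoor_sets(
    dag: nx.DiGraph,
    treatment: str,
    outcome: str,
    cap: int = 1000,
    forbidden=(),
    max_subsets: int = 200_000,
) -> AdjustmentSet:
    """Choose a backdoor adjustment set for (treatment, outcome).

    Candidates are subsets of the remaining nodes minus descendants of the
    treatment and minus ``forbidden`` (e.g. the mediator drug), enumerated
    by increasing cardinality then lexicographically.  Up to ``cap`` valid
    sets are collected; the minimum-cardinality one (first encountered on
    ties) is returned.  Under this enumeration order that is exactly the
    first valid set found.  Returns the empty set when no backdoor path
    exists.

    Raises
    ------
    UntestableHypothesis
        when no valid set is found within the enumeration budget.
    """
    if treatment not in dag or outcome not in dag:
        raise KeyError("treatment/outcome not in graph")
    eligible = sorted(
        set(dag.nodes)
        - {treatment, outcome}
        - nx.descendants(dag, treatment)
        - set(forbidden)
    )
    examined = 0
    found: list[frozenset] = []
    for size in range(len(eligible) + 1):
        for combo in combinations(eligible, size):
            examined += 1
            if examined > max_subsets:
                break
            z = frozenset(combo)
            if is_valid_backdoor_set(dag, treatment, outcome, z):
                found.append(z)
                if len(found) >= cap:
                    break
        if found or examined > max_subsets:
            break
    if not found:
        raise UntestableHypothesis(
            f"no valid backdoor set for ({treatment}, {outcome}) "
            f"within {min(examined, max_subsets)} candidate subsets"
        )
    best = min(found, key=len)  # first-encountered min cardinality (stable)
    return AdjustmentSet(best, BACKDOOR, hypothesis=(treatment, outcome))


def disjunctive_cause_set(
    dag: nx.DiGraph, treatment: str, outcome: str, mediator: str | None = None
) -> AdjustmentSet:
    """Direct causes of the treatment or the outcome.

    parents(treatment) ∪ parents(outcome), excluding treatment, outcome and
    the mediator drug.
    """
    for node in (treatment, outcome):
        if node not in dag:
            raise KeyError(f"node {node!r} not in graph")
    parents = set(dag.predecessors(treatment)) | set(dag.predecessors(outcome))
    parents -= {treatment, outcome}
    if mediator is not None:
        parents.discard(mediator)
    return AdjustmentSet(frozenset(parents), DISJUNCTIVE,
                         hypothesis=(treatment, outcome))


def prune_hierarchy(adjustment: AdjustmentSet, graph: CKGraph) -> AdjustmentSet:
    """Drop covariates whose is_a-ancestor is also in the set.

    Adjusting for both a disease and its more specific child is redundant;
    only the parent is kept.  Reaches a fixpoint (a three-level chain
    collapses to its top element) and is idempotent.
    """
    kept = set(adjustment.covariates)
    for node in sorted(adjustment.covariates):
        if graph.is_a_ancestors(node) & adjustment.covariates:
            kept.discard(node)
    return AdjustmentSet(frozenset(kept), adjustment.criterion,
                         hypothesis=adjustment.hypothesis, pruned=True)
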