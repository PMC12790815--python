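"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: d-separation by
exhaustive path enumeration, backdoor sets by full subset enumeration,
Benjamini–Hochberg by the literal step-up definition, and the natural
indirect effect by direct simulation of potential outcomes.
"""

from itertools import combinations

import networkx as nx
import numpy as np


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def all_undirected_paths(dag: nx.DiGraph, a, b):
    """All simple paths between a and b in the skeleton, as node lists."""
    skeleton = nx.Graph()
    skeleton.add_nodes_from(dag.nodes)
    skeleton.add_edges_from(dag.edges)
    return list(nx.all_simple_paths(skeleton, a, b))


def path_blocked(dag: nx.DiGraph, path, z):
    """Blocking rules applied literally to one undirected path."""
    z = set(z)
    for i in range(1, len(path) - 1):
        prev, node, nxt = path[i - 1], path[i], path[i + 1]
        into_prev = dag.has_edge(prev, node)
        out_next = dag.has_edge(node, nxt)
        collider = into_prev and not out_next  # prev -> node <- nxt
        if collider:
            desc = {node} | nx.descendants(dag, node)
            if not (desc & z):
                return True
        else:  # chain or fork
            if node in z:
                return True
    return False


def d_separated_paths(dag: nx.DiGraph, a, b, z):
    """Exhaustive path-enumeration d-separation oracle."""
    return all(path_blocked(dag, p, z) for p in all_undirected_paths(dag, a, b))


def backdoor_valid(dag: nx.DiGraph, treatment, outcome, z):
    z = set(z)
    if {treatment, outcome} & z:
        return False
    if z & nx.descendants(dag, treatment):
        return False
    mutilated = dag.copy()
    mutilated.remove_edges_from(list(dag.out_edges(treatment)))
    return d_separated_paths(mutilated, treatment, outcome, z)


def minimal_backdoor_sets(dag: nx.DiGraph, treatment, outcome):
    """All minimum-cardinality valid backdoor sets, by full enumeration."""
    eligible = sorted(set(dag.nodes) - {treatment, outcome}
                      - nx.descendants(dag, treatment))
    for size in range(len(eligible) + 1):
        found = [frozenset(c) for c in combinations(eligible, size)
                 if backdoor_valid(dag, treatment, outcome, c)]
        if found:
            return found
    return []


def bh_stepup(pvals, alpha=0.05):
    """Literal Benjamini–Hochberg step-up: reject flags in input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= rank * alpha / m:
            k_star = rank
    reject = [False] * m
    for rank, i in enumerate(order, start=1):
        if rank <= k_star:
            reject[i] = True
    return reject


def mc_nie_binary(a, b, alpha_m, alpha_y, mc_n=1_000_000, seed=0):
    """Simulated natural indirect effect for logistic T→M→Y equations.

    Draws the potential mediators M(0), M(1) and potential outcomes with
    shared outcome noise; returns (value, mc standard error).
    """
    rng = np.random.default_rng(seed)
    m0 = rng.random(mc_n) < _expit(np.full(mc_n, alpha_m))
    m1 = rng.random(mc_n) < _expit(np.full(mc_n, alpha_m + a))
    u = rng.random(mc_n)
    y1 = u < _expit(alpha_y + b * m1)
    y0 = u < _expit(alpha_y + b * m0)
    delta = y1.astype(float) - y0.astype(float)
    return float(delta.mean()), float(delta.std(ddof=1) / np.sqrt(mc_n))


def random_dag(n, p, seed):
    """Random DAG on nodes n0..n{n-1}; edges follow the node order."""
    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    names = [f"n{i}" for i in range(n)]
    g.add_nodes_from(names)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(names[i], names[j])
    return g
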