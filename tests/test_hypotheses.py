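import numpy as np
import pandas as pd
import pytest

from ckgmed.cohort import Cohort
from ckgmed.graph import CKGraph
from ckgmed.hypotheses import (FILTERED_CONTRADICTED, FILTERED_SUPPORT,
                               TESTABLE, Hypothesis, comorbidity_directed_pairs,
                               compute_comorbidity_pairs, extract_causal_pairs,
                               filter_by_support, filter_contradicted,
                               filter_contradicted_sparql, generate_hypotheses)


def _cohort(diag_rows, presc_rows, persons):
    cov = pd.DataFrame({"person_id": list(persons)})
    return Cohort(
        pd.DataFrame(diag_rows, columns=["person_id", "icd10", "date"]),
        pd.DataFrame(presc_rows, columns=["person_id", "rxnorm", "date"]),
        cov, pd.Series(True, index=list(persons)),
    )


def test_causal_pairs_are_exactly_the_progression_edges(toy_graph):
    assert extract_causal_pairs(toy_graph) == [("A00", "B00"), ("B00", "C00")]
    empty = CKGraph.from_edges([("A001", "is_a", "A00")])
    assert extract_causal_pairs(empty) == []


def test_hypothesis_generation_expands_indicated_drugs(toy_graph):
    hyps = generate_hypotheses([("A00", "B00")], toy_graph)
    assert {(h.indication, h.drug, h.outcome) for h in hyps} == {
        ("A00", "RX1", "B00"), ("A00", "RX2", "B00")}
    assert generate_hypotheses([("C00", "A00")], toy_graph) == []  # no drug for C00
    # count identity over a pair list
    pairs = [("A00", "B00"), ("B00", "C00"), ("C00", "A00")]
    total = sum(len(toy_graph.drugs_indicated_for(x)) for x, _ in pairs)
    assert len(generate_hypotheses(pairs, toy_graph)) == total


# ---------------------------------------------------------------------------
# comorbidity pairs


def test_independent_diseases_rarely_significant():
    rng = np.random.default_rng(21)
    n = 2000
    persons = [f"p{i}" for i in range(n)]
    diag = []
    for code in ("A00", "B00"):
        for i in np.flatnonzero(rng.random(n) < 0.3):
            diag.append((persons[i], code, "2001-01-01"))
    pairs = compute_comorbidity_pairs(_cohort(diag, [], persons))
    assert len(pairs) == 1
    assert abs(pairs[0].rr - 1.0) < 0.25
    assert pairs[0].q_value > 0.05


def test_planted_cooccurrence_is_oriented_by_majority_order():
    rng = np.random.default_rng(4)
    n = 600
    persons = [f"p{i}" for i in range(n)]
    diag = []
    for i in range(n):
        if rng.random() < 0.5:
            # A precedes B in 90% of co-cases
            if rng.random() < 0.9:
                diag += [(persons[i], "A00", "2001-01-01"),
                         (persons[i], "B00", "2002-01-01")]
            else:
                diag += [(persons[i], "B00", "2001-01-01"),
                         (persons[i], "A00", "2002-01-01")]
    pairs = compute_comorbidity_pairs(_cohort(diag, [], persons))
    assert pairs[0].q_value <= 0.05
    assert comorbidity_directed_pairs(pairs) == [("A00", "B00")]


def test_exact_tie_in_orientation_drops_the_pair():
    persons = [f"p{i}" for i in range(40)]
    diag = []
    for i in range(20):
        first, second = ("A00", "B00") if i % 2 == 0 else ("B00", "A00")
        diag += [(persons[i], first, "2001-01-01"),
                 (persons[i], second, "2002-01-01")]
    pairs = compute_comorbidity_pairs(_cohort(diag, [], persons))
    assert all(p.direction is None for p in pairs)


def test_null_significance_rate_controlled_after_bh():
    """Independent diseases: BH-significant fraction stays near or below alpha."""
    rng = np.random.default_rng(11)
    n, n_codes = 400, 12
    persons = [f"p{i}" for i in range(n)]
    diag = [(persons[i], f"C{j:02d}", "2001-01-01")
            for j in range(n_codes)
            for i in np.flatnonzero(rng.random(n) < 0.3)]
    pairs = compute_comorbidity_pairs(_cohort(diag, [], persons))
    frac = np.mean([p.q_value <= 0.05 for p in pairs])
    se = np.sqrt(0.05 * 0.95 / len(pairs))
    assert frac <= 0.05 + 3 * se


# ---------------------------------------------------------------------------
# filters


def _decoy_hypotheses(graph):
    pairs = extract_causal_pairs(graph)
    return generate_hypotheses(pairs, graph)


def test_contradiction_filter_removes_exactly_the_decoys(decoy_graph):
    hyps = _decoy_hypotheses(decoy_graph)
    filtered = filter_contradicted(hyps, decoy_graph)
    status = {h.key(): h.status for h in filtered}
    assert status[("X2", "RXA", "Y2")] == FILTERED_CONTRADICTED  # rule (i)
    assert status[("X3", "RXB", "Y3")] == FILTERED_CONTRADICTED  # rule (ii)
    assert status[("X1", "RXC", "Y1")] != FILTERED_CONTRADICTED
    assert status[("X4", "RXU", "Y4")] != FILTERED_CONTRADICTED


def test_sparql_route_agrees_with_native_filter(decoy_graph):
    hyps = _decoy_hypotheses(decoy_graph)
    native = filter_contradicted(hyps, decoy_graph)
    sparql = filter_contradicted_sparql(hyps, decoy_graph)
    assert [(h.key(), h.status) for h in native] == \
           [(h.key(), h.status) for h in sparql]


def test_contradiction_filter_matches_brute_force_predicates():
    rng = np.random.default_rng(30)
    diseases = [f"D{i:02d}" for i in range(8)]
    drugs = [f"RX{i}" for i in range(6)]
    triples = []
    for drug in drugs:
        for d in diseases:
            if rng.random() < 0.3:
                triples.append((drug, "indication", d))
            if rng.random() < 0.3:
                triples.append((drug, "side_effect", d))
    graph = CKGraph.from_edges(triples + [("D00", "progression", "D01")])
    hyps = [Hypothesis(a, m, b) for a in diseases for b in diseases
            for m in drugs if a != b][:30]
    filtered = filter_contradicted(hyps, graph)
    for h in filtered:
        ind = graph.indications_of(h.drug)
        rule_i = h.indication in ind and h.outcome in ind
        rule_ii = any({h.indication, h.outcome} <= graph.side_effects_of(d)
                      for d in graph.drugs())
        assert (h.status == FILTERED_CONTRADICTED) == (rule_i or rule_ii), h


def test_support_filter_removes_unobserved_triples(decoy_graph, decoy_cohort):
    hyps = _decoy_hypotheses(decoy_graph)
    filtered = filter_by_support(hyps, decoy_cohort)
    status = {h.key(): h.status for h in filtered}
    assert status[("X4", "RXU", "Y4")] == FILTERED_SUPPORT  # drug never prescribed
    assert status[("X1", "RXC", "Y1")] == TESTABLE


def test_single_supported_person_is_enough():
    persons = ["p1", "p2"]
    cohort = _cohort(
        [("p1", "X00", "2001-01-01"), ("p1", "Y00", "2002-01-01")],
        [("p1", "RX1", "2001-06-01")], persons)
    graph = CKGraph.from_edges([("X00", "progression", "Y00"),
                                ("RX1", "indication", "X00")])
    hyps = filter_by_support(_decoy_hypotheses(graph), cohort)
    assert hyps[0].status == TESTABLE


def test_filters_commute(decoy_graph, decoy_cohort):
    hyps = _decoy_hypotheses(decoy_graph)
    ab = filter_by_support(filter_contradicted(hyps, decoy_graph),
                           decoy_cohort)
    ba = filter_contradicted(filter_by_support(hyps, decoy_cohort),
                             decoy_graph)
    testable_ab = {h.key() for h in ab if h.status == TESTABLE}
    testable_ba = {h.key() for h in ba if h.status == TESTABLE}
    assert testable_ab == testable_ba
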