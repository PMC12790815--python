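"""Candidate hypothesis generation and knowledge-based filtering.

A mediation hypothesis is an ordered triple (indication disease ``x``, drug
``m``, outcome disease ``y``): the drug, prescribed for ``x``, is conjectured
to mediate the progression from ``x`` to ``y``.  Candidate disease pairs come
from two sources: the graph's progression edges (causal set) and disease
pairs significantly co-morbid in the cohort, oriented by diagnosis order
(comorbidity set).  Two contradiction filters remove triples the graph
already explains — the drug indicated for both diseases (treatment overlap),
or both diseases listed as side effects of a single drug (common downstream
effect) — and a support filter removes triples never jointly observed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort, apply_temporal_validity
from .graph import CKGraph, normalize_icd

CANDIDATE = "candidate"
FILTERED_CONTRADICTED = "filtered_contradicted"
FILTERED_SUPPORT = "filtered_support"
TESTABLE = "testable"


@dataclass(frozen=True)
class Hypothesis:
    indication: str
    drug: str
    outcome: str
    source: str = "causal"  # {"causal", "comorbidity"}
    status: str = CANDIDATE

    def key(self) -> tuple:
        return (self.indication, self.drug, self.outcome)


@dataclass(frozen=True)
class ComorbidityPair:
    """Co-occurrence statistics for an unordered disease pair.

    ``rr`` is the relative risk (n_both * n_total) / (n_a * n_b); the
    p-value is from a one-sided Fisher exact test of enrichment on the
    person-level 2x2 table; ``direction`` is set only for pairs significant
    after Benjamini–Hochberg and with a strict majority diagnosis order.
    """

    disease_a: str
    disease_b: str
    rr: float
    p_value: float
    q_value: float = float("nan")
    direction: tuple | None = None  # oriented (source, target) or None
    n_both: int = 0
    n_a: int = 0
    n_b: int = 0
    n_total: int = 0


def extract_causal_pairs(graph: CKGraph) -> list:
    """Directed disease pairs from progression edges, sorted for determinism."""
    return sorted(graph.edges_of("progression"))


def compute_comorbidity_pairs(cohort: Cohort, alpha: float = 0.05) -> list:
    """Relative-risk comorbidity screen with BH correction and orientation.

    Co-occurrence is counted at lifetime-record level (ever diagnosed).
    Significant pairs are oriented by first-diagnosis dates: if a strict
    majority of co-diagnosed persons had ``a`` before ``b``, the direction
    is a→b; exact ties leave the pair unoriented (dropped downstream).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    diag = cohort.diagnoses
    first = diag.groupby(["person_id", "icd10"])["date"].min()
    by_code: dict[str, set] = {}
    for (person, code) in first.index:
        by_code.setdefault(code, set()).add(person)
    codes = sorted(c for c, members in by_code.items() if members)
    n_total = len(cohort.persons())

    raw = []
    for i, a in enumerate(codes):
        for b in codes[i + 1:]:
            sa, sb = by_code[a], by_code[b]
            n_both = len(sa & sb)
            if n_both == 0:
                continue  # RR = 0, never enriched
            n_a, n_b = len(sa), len(sb)
            rr = (n_both * n_total) / (n_a * n_b)
            table = np.array([
                [n_both, n_a - n_both],
                [n_b - n_both, n_total - n_a - n_b + n_both],
            ])
            p = fisher_exact(table, alternative="greater")[1]
            raw.append(ComorbidityPair(a, b, rr, p,
                                       n_both=n_both, n_a=n_a, n_b=n_b,
                                       n_total=n_total))
    if not raw:
        return []
    reject, q_values, _, _ = multipletests(
        [pair.p_value for pair in raw], alpha=alpha, method="fdr_bh"
    )
    out = []
    for pair, rej, q in zip(raw, reject, q_values):
        direction = None
        if rej:
            direction = _orient(first, pair.disease_a, pair.disease_b)
        out.append(replace(pair, q_value=float(q), direction=direction))
    return out


def _orient(first_dates: pd.Series, a: str, b: str) -> tuple | None:
    """Majority first-diagnosis order among co-diagnosed persons; ties drop."""
    fa = first_dates.xs(a, level="icd10")
    fb = first_dates.xs(b, level="icd10")
    both = fa.index.intersection(fb.index)
    a_first = int((fa[both] < fb[both]).sum())
    b_first = int((fb[both] < fa[both]).sum())
    if a_first > b_first and a_first > (len(both) - a_first):
        return (a, b)
    if b_first > a_first and b_first > (len(both) - b_first):
        return (b, a)
    return None


def comorbidity_directed_pairs(pairs: Iterable[ComorbidityPair]) -> list:
    """Oriented (source, target) pairs of the BH-significant comorbidities."""
    return [p.direction for p in pairs if p.direction is not None]


def generate_hypotheses(
    pairs: Sequence, graph: CKGraph, source: str = "causal"
) -> list:
    """One hypothesis per (directed disease pair, drug indicated for the source)."""
    hypotheses = []
    for x, y in pairs:
        x, y = normalize_icd(x), normalize_icd(y)
        if x == y:
            continue
        for drug in sorted(graph.drugs_indicated_for(x)):
            hypotheses.append(Hypothesis(x, drug, y, source=source))
    return hypotheses


def filter_contradicted(hypotheses: Iterable[Hypothesis], graph: CKGraph) -> list:
    """Mark hypotheses the graph already explains.

    Rule (i): the drug is indicated for both the indication and the outcome
    (treatment overlap, not mediation).  Rule (ii): some single drug lists
    both diseases as side effects (common downstream effect).
    """
    # pre-index side-effect co-listing: all unordered disease pairs sharing a drug
    shared_se: set = set()
    for drug in graph.drugs():
        effects = sorted(graph.side_effects_of(drug))
        for i, a in enumerate(effects):
            for b in effects[i + 1:]:
                shared_se.add((a, b))
    out = []
    for h in hypotheses:
        if h.status not in (CANDIDATE, TESTABLE):
            out.append(h)
            continue
        indicated = graph.indications_of(h.drug)
        pair = tuple(sorted((h.indication, h.outcome)))
        if (h.indication in indicated and h.outcome in indicated) or pair in shared_se:
            out.append(replace(h, status=FILTERED_CONTRADICTED))
        else:
            out.append(h)
    return out


CONTRADICTION_SPARQL = """
PREFIX rel: <urn:ckg:relation:>
ASK {{
  {{ ?d rel:indication <urn:ckg:node:{x}> .
     ?d rel:indication <urn:ckg:node:{y}> .
     FILTER(?d = <urn:ckg:node:{m}>) }}
  UNION
  {{ ?d rel:side_effect <urn:ckg:node:{x}> .
     ?d rel:side_effect <urn:ckg:node:{y}> . }}
}}
"""


def filter_contradicted_sparql(hypotheses: Iterable[Hypothesis], graph: CKGraph) -> list:
    """Contradiction filter run as SPARQL ASK queries over the N-Triples export.

    Semantically identical to :func:`filter_contradicted`; exists so the
    filter can also be executed against any RDF triple store.
    """
    import rdflib

    g = rdflib.Graph()
    g.parse(data=graph.to_ntriples(), format="nt")
    out = []
    for h in hypotheses:
        if h.status not in (CANDIDATE, TESTABLE):
            out.append(h)
            continue
        q = CONTRADICTION_SPARQL.format(x=h.indication, y=h.outcome, m=h.drug)
        if bool(g.query(q).askAnswer):
            out.append(replace(h, status=FILTERED_CONTRADICTED))
        else:
            out.append(h)
    return out


def filter_by_support(
    hypotheses: Iterable[Hypothesis],
    cohort: Cohort,
    descendants=None,
) -> list:
    """Mark hypotheses without a single fully supported person.

    A hypothesis survives only if, after temporal-validity encoding, at
    least one person has indication = drug = outcome = 1; triples whose drug
    or either disease never appears in the cohort are likewise marked.
    Survivors are promoted to ``testable``.
    """
    out = []
    for h in hypotheses:
        if h.status not in (CANDIDATE, TESTABLE):
            out.append(h)
            continue
        table = apply_temporal_validity(cohort, h, descendants=descendants)
        if table.untestable or not table.supported:
            out.append(replace(h, status=FILTERED_SUPPORT))
        else:
            out.append(replace(h, status=TESTABLE))
    return out


def write_hypotheses(hypotheses: Sequence[Hypothesis], path) -> None:
    pd.DataFrame(
        [(h.indication, h.drug, h.outcome, h.source, h.status) for h in hypotheses],
        columns=["indication", "drug", "outcome", "source", "status"],
    ).to_csv(path, sep="\t", index=False)
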