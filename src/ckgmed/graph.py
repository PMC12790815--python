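"""Causal knowledge graph (CKG) data model and I/O.

A CKG couples a typed drug--disease knowledge graph with a population-level
probabilistic interpretation.  Nodes are diseases (normalised ICD-10 codes)
and drugs (RxNorm identifiers); edges carry one of four relations:

* ``progression`` — disease ``u`` can lead to the onset of disease ``v``;
* ``indication`` — drug ``m`` is indicated for disease ``v``;
* ``side_effect`` — drug ``m`` lists disease ``v`` as a known side effect;
* ``is_a`` — disease subsumption (e.g. a four-character ICD-10 code under
  its three-character category).

Progression edges together with the *inverse* of indication edges (a disease
diagnosis leads to the prescription of a drug) form the causal relation
subset; the induced causal subgraph must be acyclic.  A population
:math:`\\Omega` of persons is attached through a membership map
:math:`f(v) \\subseteq \\Omega` (everyone ever diagnosed with ``v`` or any
``is_a``-descendant of ``v``, or ever prescribed drug ``v``) and the
empirical measure :math:`P(S) = |S|/|\\Omega|`.  The subsumption constraint
``f(child) ⊆ f(parent)`` is enforced by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import FormatError, StructuralError

logger = logging.getLogger(__name__)

RELATIONS = ("progression", "indication", "side_effect", "is_a")

#: relation types with a causal reading; indication edges enter the causal
#: subgraph inverted (disease -> drug).
CAUSAL_RELATIONS = frozenset({"progression", "indication_inverse"})

DISEASE = "disease"
DRUG = "drug"

# endpoint kinds implied by each relation: (source kind, target kind)
_EDGE_KINDS = {
    "progression": (DISEASE, DISEASE),
    "indication": (DRUG, DISEASE),
    "side_effect": (DRUG, DISEASE),
    "is_a": (DISEASE, DISEASE),
}


def normalize_icd(code: str) -> str:
    """Normalise an ICD-10 code to the internal namespace (strip dots, upper).

    ``E11.9`` and ``e119`` both map to ``E119``.  The display form is the
    caller's concern; internally only the normalised form is used so that
    cohort dialects with and without dots join cleanly.
    """
    return str(code).replace(".", "").strip().upper()


def icd_category(code: str) -> str:
    """Three-character ICD-10 category of a (normalised or dotted) code."""
    return normalize_icd(code)[:3]


@dataclass(frozen=True)
class CKGraph:
    """Typed drug--disease knowledge graph with a marked causal subset.

    Parameters
    ----------
    nodes : mapping of node id to kind (``"disease"`` or ``"drug"``)
    edges : frozenset of ``(source, relation, target)`` triples
    provenance : optional mapping of triple to source-dataset label (audit
        only; never used in computation)
    """

    nodes: Mapping[str, str]
    edges: frozenset
    provenance: Mapping[tuple, str] = field(default_factory=dict)

    # -- constructors ---------------------------------------------------

    @staticmethod
    def from_edges(
        triples: Iterable[tuple],
        provenance: Mapping[tuple, str] | None = None,
    ) -> "CKGraph":
        """Build and validate a graph from ``(source, relation, target)`` triples.

        Duplicate triples are deduplicated.  Node kinds are inferred from the
        relations they participate in; a node used both as a drug and as a
        disease is a format error, as is an unknown relation label.  The
        causal subgraph and the is_a hierarchy must both be acyclic.
        """
        edges = frozenset(
            (str(s), str(r), str(t)) for s, r, t in triples
        )
        nodes: dict[str, str] = {}
        for s, r, t in edges:
            if r not in _EDGE_KINDS:
                raise FormatError(f"unknown relation label: {r!r}")
            if not s or not t:
                raise FormatError(f"empty node id in edge ({s!r}, {r}, {t!r})")
            for node, kind in ((s, _EDGE_KINDS[r][0]), (t, _EDGE_KINDS[r][1])):
                prev = nodes.setdefault(node, kind)
                if prev != kind:
                    raise FormatError(
                        f"node {node!r} used both as {prev} and as {kind}"
                    )
        graph = CKGraph(nodes, edges, dict(provenance or {}))
        graph._validate_acyclic()
        return graph

    def _validate_acyclic(self) -> None:
        causal = self.causal_subgraph()
        try:
            cycle = nx.find_cycle(causal)
        except nx.NetworkXNoCycle:
            pass
        else:
            raise StructuralError(
                "cycle in causal subgraph: "
                + " -> ".join(u for u, _ in cycle) + f" -> {cycle[-1][1]}"
            )
        hier = nx.DiGraph(
            (s, t) for s, r, t in self.edges if r == "is_a"
        )
        try:
            cycle = nx.find_cycle(hier)
        except nx.NetworkXNoCycle:
            pass
        else:
            raise StructuralError(
                "cycle in is_a hierarchy: "
                + " -> ".join(u for u, _ in cycle) + f" -> {cycle[-1][1]}"
            )

    # -- views ----------------------------------------------------------

    def edges_of(self, relation: str) -> frozenset:
        """``(source, target)`` pairs of one relation type."""
        return frozenset((s, t) for s, r, t in self.edges if r == relation)

    def diseases(self) -> frozenset:
        return frozenset(n for n, k in self.nodes.items() if k == DISEASE)

    def drugs(self) -> frozenset:
        return frozenset(n for n, k in self.nodes.items() if k == DRUG)

    def drugs_indicated_for(self, disease: str) -> frozenset:
        """Drugs with an indication edge pointing at ``disease``."""
        return frozenset(
            s for s, r, t in self.edges if r == "indication" and t == disease
        )

    def indications_of(self, drug: str) -> frozenset:
        return frozenset(
            t for s, r, t in self.edges if r == "indication" and s == drug
        )

    def side_effects_of(self, drug: str) -> frozenset:
        return frozenset(
            t for s, r, t in self.edges if r == "side_effect" and s == drug
        )

    def is_a_parents(self, node: str) -> frozenset:
        return frozenset(
            t for s, r, t in self.edges if r == "is_a" and s == node
        )

    def is_a_descendants(self, node: str) -> frozenset:
        """All strict is_a-descendants of ``node`` (transitive closure)."""
        hier = self._hierarchy()
        if node not in hier:
            return frozenset()
        return frozenset(nx.ancestors(hier, node))  # edges run child -> parent

    def is_a_ancestors(self, node: str) -> frozenset:
        hier = self._hierarchy()
        if node not in hier:
            return frozenset()
        return frozenset(nx.descendants(hier, node))

    def _hierarchy(self) -> nx.DiGraph:
        hier = nx.DiGraph()
        hier.add_nodes_from(self.diseases())
        hier.add_edges_from(self.edges_of("is_a"))
        return hier

    def causal_subgraph(self) -> nx.DiGraph:
        """Directed acyclic graph over diseases and drugs.

        Contains every progression edge and, for each indication edge
        drug→disease, one causal edge disease→drug.  is_a and side_effect
        edges are excluded.  Pure function of the edge set.
        """
        dag = nx.DiGraph()
        dag.add_nodes_from(self.nodes)
        for s, r, t in sorted(self.edges):
            if r == "progression":
                dag.add_edge(s, t)
            elif r == "indication":
                dag.add_edge(t, s)
        return dag

    # -- export ---------------------------------------------------------

    def to_ntriples(self) -> str:
        """Bit-stable RDF N-Triples serialisation (sorted triples).

        One predicate IRI per relation type, so graph-level filters can also
        be phrased as SPARQL queries against any triple store.
        """
        lines = []
        for s, r, t in sorted(self.edges):
            lines.append(
                f"<urn:ckg:node:{s}> <urn:ckg:relation:{r}> <urn:ckg:node:{t}> ."
            )
        return "\n".join(lines) + "\n"


def load_graph(edge_tables: Mapping[str, "str | Path | pd.DataFrame"]) -> CKGraph:
    """Load a CKG from per-relation edge tables.

    Parameters
    ----------
    edge_tables : mapping of relation label to a TSV path (columns
        ``source``/``target``, one header line) or an equivalent DataFrame.

    Disease identifiers are ICD-10-normalised (dots stripped, uppercased).
    Duplicate triples are deduplicated; endpoint-kind constraints and
    acyclicity of the causal subgraph and the is_a hierarchy are verified.
    """
    triples: list[tuple] = []
    provenance: dict[tuple, str] = {}
    for relation, table in edge_tables.items():
        if relation not in _EDGE_KINDS:
            raise FormatError(f"unknown relation label: {relation!r}")
        if isinstance(table, pd.DataFrame):
            df = table
            origin = "<dataframe>"
        else:
            df = pd.read_csv(table, sep="\t", dtype=str)
            origin = str(table)
        if not {"source", "target"}.issubset(df.columns):
            raise FormatError(
                f"{origin}: expected columns 'source' and 'target'"
            )
        src_kind, tgt_kind = _EDGE_KINDS[relation]
        for s, t in zip(df["source"], df["target"]):
            s = normalize_icd(s) if src_kind == DISEASE else str(s).strip()
            t = normalize_icd(t) if tgt_kind == DISEASE else str(t).strip()
            triple = (s, relation, t)
            triples.append(triple)
            provenance.setdefault(triple, origin)
    return CKGraph.from_edges(triples, provenance)


def write_graph(graph: CKGraph, out_dir: "str | Path") -> dict:
    """Write per-relation TSV edge lists; returns relation -> path mapping."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for relation in RELATIONS:
        pairs = sorted(graph.edges_of(relation))
        path = out_dir / f"{relation}.tsv"
        pd.DataFrame(pairs, columns=["source", "target"]).to_csv(
            path, sep="\t", index=False
        )
        paths[relation] = path
    return paths


# ---------------------------------------------------------------------------
# population assignment


@dataclass(frozen=True)
class PopulationAssignment:
    """Population :math:`\\Omega`, membership map ``f`` and measure ``P``.

    ``membership[v]`` is the set of persons assigned to node ``v``; for a
    disease this includes anyone diagnosed with ``v`` or any of its
    is_a-descendants, so the subsumption constraint holds by construction.
    ``measure`` is the empirical relative frequency ``|S| / |Ω|``.
    """

    population: frozenset
    membership: Mapping[str, frozenset]

    def measure(self, subset_or_node) -> float:
        if isinstance(subset_or_node, str):
            subset = self.membership.get(subset_or_node, frozenset())
        else:
            subset = frozenset(subset_or_node)
        if not self.population:
            return 0.0
        if not subset <= self.population:
            raise ValueError("subset contains persons outside the population")
        return len(subset) / len(self.population)


def assign_population(graph: CKGraph, cohort) -> PopulationAssignment:
    """Empirically assign persons to every graph node.

    ``f(disease v)`` = persons with at least one diagnosis of ``v`` or of any
    is_a-descendant of ``v``; ``f(drug m)`` = persons with at least one
    prescription of ``m``.  Cohort codes absent from the graph are counted
    and skipped (logged), never fatal.
    """
    population = frozenset(cohort.persons())

    diag_members: dict[str, set] = {}
    skipped = 0
    for person, code in zip(
        cohort.diagnoses["person_id"], cohort.diagnoses["icd10"]
    ):
        code = normalize_icd(code)
        if code in graph.nodes:
            diag_members.setdefault(code, set()).add(person)
        else:
            skipped += 1
    presc_members: dict[str, set] = {}
    for person, drug in zip(
        cohort.prescriptions["person_id"], cohort.prescriptions["rxnorm"]
    ):
        drug = str(drug)
        if drug in graph.nodes:
            presc_members.setdefault(drug, set()).add(person)
        else:
            skipped += 1
    if skipped:
        logger.info("assign_population: %d records with codes absent from the graph skipped", skipped)

    membership: dict[str, frozenset] = {}
    for node, kind in graph.nodes.items():
        if kind == DRUG:
            membership[node] = frozenset(presc_members.get(node, set()))
        else:
            members = set(diag_members.get(node, set()))
            for desc in graph.is_a_descendants(node):
                members |= diag_members.get(desc, set())
            membership[node] = frozenset(members)
    return PopulationAssignment(population, membership)
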