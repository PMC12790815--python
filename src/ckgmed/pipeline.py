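"""End-to-end orchestration: graph + cohort → hypotheses → adjustment →
covariate selection → mediation → BH → evaluation.

All randomness flows from one top-level seed; each hypothesis gets a
deterministic derived seed so results are reproducible item by item and
independent of execution order.  Per-hypothesis failures are recorded as
N/A statuses, never fatal — the summary's category counts (untestable +
insignificant + positive + negative) always add up to the number of
generated hypotheses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hypotheses as hyp_mod
from .adjustment import (BACKDOOR, DISJUNCTIVE, add_hypothesis_edge,
                         backdoor_sets, disjunctive_cause_set, prune_hierarchy)
from .cohort import (Cohort, SEVERITY_COLUMNS, apply_temporal_validity,
                     severity_proxies)
from .errors import UntestableHypothesis
from .evaluation import match_reference
from .graph import CKGraph, DRUG
from .mediation import (bh_correct, estimate_acme, fit_models, results_frame,
                        untestable_result)
from .selection import select_covariates, union_selection

logger = logging.getLogger(__name__)

DEMOGRAPHICS = ("sex", "age", "bmi", "ethnicity")


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    seed: int
    out_dir: str | Path | None = None
    source: str = "causal"          # causal | comorbidity | both
    criterion: str = DISJUNCTIVE    # backdoor | disjunctive
    lasso: bool = True
    sims: int = 1000
    alpha: float = 0.05
    backdoor_cap: int = 1000
    graph_dir: str | Path | None = None
    cohort_dir: str | Path | None = None
    reference: str | Path | None = None  # side-effect TSV used as evaluation reference

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.criterion not in (BACKDOOR, DISJUNCTIVE):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        return RunConfig(**yaml.safe_load(Path(path).read_text()))


def derived_seed(base: int, index: int) -> int:
    """Stable per-hypothesis seed below 2^31."""
    return int((np.uint64(base) * np.uint64(1000003) + np.uint64(index * 7919 + 17))
               % np.uint64(2**31 - 1))


def _log(stage, hypothesis, event, detail=""):
    key = "|".join(hypothesis) if hypothesis else "-"
    logger.info("%s | %s | %s | %s", stage, key, event, detail)


def _node_covariate(cohort: Cohort, graph: CKGraph, node: str,
                    descendants) -> pd.Series:
    """Binary ever-exposed indicator column for an adjustment-set node."""
    if graph.nodes.get(node) == DRUG:
        members = set(cohort.prescriptions.loc[
            cohort.prescriptions["rxnorm"] == node, "person_id"])
    else:
        codes = {node} | set(descendants.get(node, ()))
        members = set(cohort.diagnoses.loc[
            cohort.diagnoses["icd10"].isin(codes), "person_id"])
    idx = pd.Index(sorted(cohort.persons()), name="person_id")
    return pd.Series(idx.isin(members).astype(int), index=idx)


def run_pipeline(
    config: RunConfig,
    graph: CKGraph | None = None,
    cohort: Cohort | None = None,
) -> dict:
    """Execute every stage and return ``{"results", "summary", "hypotheses"}``.

    Graph and cohort may be passed in memory or loaded from the configured
    directories.  When ``config.out_dir`` is set, stage outputs
    (hypotheses.tsv, adjustment_sets.tsv, results.tsv, summary.json) are
    written there.
    """
    from .graph import load_graph
    from .cohort import load_cohort

    if graph is None:
        if config.graph_dir is None:
            raise ValueError("no graph supplied")
        gdir = Path(config.graph_dir)
        graph = load_graph({rel: gdir / f"{rel}.tsv"
                            for rel in ("progression", "indication",
                                        "side_effect", "is_a")
                            if (gdir / f"{rel}.tsv").exists()})
    if cohort is None:
        if config.cohort_dir is None:
            raise ValueError("no cohort supplied")
        cohort = load_cohort(config.cohort_dir)

    descendants = {d: graph.is_a_descendants(d) for d in graph.diseases()}

    # ---- hypotheses ------------------------------------------------------
    pairs = []
    if config.source in ("causal", "both"):
        pairs += [(p, "causal") for p in hyp_mod.extract_causal_pairs(graph)]
    if config.source in ("comorbidity", "both"):
        compairs = hyp_mod.compute_comorbidity_pairs(cohort, alpha=config.alpha)
        pairs += [(p, "comorbidity")
                  for p in hyp_mod.comorbidity_directed_pairs(compairs)]
    hypotheses = []
    for pair, source in pairs:
        hypotheses += hyp_mod.generate_hypotheses([pair], graph, source=source)
    # de-duplicate triples across sources, keeping the first source label
    seen, unique = set(), []
    for h in hypotheses:
        if h.key() not in seen:
            seen.add(h.key())
            unique.append(h)
    hypotheses = unique
    _log("hypotheses", None, "generated", f"{len(hypotheses)} candidates")

    hypotheses = hyp_mod.filter_contradicted(hypotheses, graph)
    for h in hypotheses:
        if h.status == hyp_mod.FILTERED_CONTRADICTED:
            _log("filter", h.key(), "contradicted", "graph already explains the pair")
    hypotheses = hyp_mod.filter_by_support(hypotheses, cohort,
                                           descendants=descendants)
    for h in hypotheses:
        if h.status == hyp_mod.FILTERED_SUPPORT:
            _log("filter", h.key(), "no_support", "no fully supported person")

    testable = [h for h in hypotheses if h.status == hyp_mod.TESTABLE]
    _log("hypotheses", None, "testable", str(len(testable)))

    # ---- per-hypothesis analysis ----------------------------------------
    proxies = severity_proxies(cohort).set_index("person_id")
    causal_dag = graph.causal_subgraph()
    results, adj_rows = [], []
    for i, h in enumerate(testable):
        seed_i = derived_seed(config.seed, i)
        try:
            result = _analyse_one(h, graph, cohort, causal_dag, descendants,
                                  proxies, config, seed_i, adj_rows)
        except UntestableHypothesis as exc:
            _log("mediate", h.key(), "untestable", exc.reason)
            result = untestable_result(h, exc.reason, config.sims, seed_i)
        results.append(result)

    results = bh_correct(results, alpha=config.alpha)
    frame = results_frame(results)

    # ---- summary ---------------------------------------------------------
    n_total = len(hypotheses)
    n_filtered = sum(h.status in (hyp_mod.FILTERED_CONTRADICTED,
                                  hyp_mod.FILTERED_SUPPORT) for h in hypotheses)
    n_na = int((frame["status"] != "ok").sum()) if len(frame) else 0
    ok = frame[frame["status"] == "ok"] if len(frame) else frame
    n_pos = int((ok["significant"] & (ok["acme"] > 0)).sum()) if len(ok) else 0
    n_neg = int((ok["significant"] & (ok["acme"] <= 0)).sum()) if len(ok) else 0
    n_insig = int(len(ok) - n_pos - n_neg) if len(ok) else 0
    summary = {
        "hypotheses": n_total,
        "filtered": n_filtered,
        "na": n_na,
        "insignificant": n_insig,
        "positive_acme": n_pos,
        "negative_acme": n_neg,
        "criterion": config.criterion,
        "lasso": config.lasso,
        "seed": config.seed,
    }

    if config.reference is not None and len(ok):
        ref = pd.read_csv(config.reference, sep="\t", dtype=str)
        ref_pairs = set(zip(ref["source"], ref["target"]))
        preds = set(zip(ok.loc[ok["significant"] & (ok["acme"] > 0), "drug"],
                        ok.loc[ok["significant"] & (ok["acme"] > 0), "outcome"]))
        universe = {(h.drug, h.outcome) for h in testable}
        report = match_reference(preds, ref_pairs, universe=universe)
        summary.update(precision=report.precision, recall=report.recall,
                       f1=report.f1, tp=report.tp, fp=report.fp, fn=report.fn)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        hyp_mod.write_hypotheses(hypotheses, out / "hypotheses.tsv")
        pd.DataFrame(adj_rows, columns=["indication", "drug", "outcome",
                                        "criterion", "covariates"]
                     ).to_csv(out / "adjustment_sets.tsv", sep="\t", index=False)
        frame.to_csv(out / "results.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    return {"results": frame, "summary": summary, "hypotheses": hypotheses,
            "mediation": results}


def _analyse_one(h, graph, cohort, causal_dag, descendants, proxies,
                 config: RunConfig, seed: int, adj_rows: list):
    table = apply_temporal_validity(cohort, h, descendants=descendants,
                                    extra_covariates=proxies)
    if table.untestable:
        raise UntestableHypothesis(table.reason or "untestable")
    if not table.supported:
        raise UntestableHypothesis("support: no person with T=M=Y=1")

    dag = add_hypothesis_edge(causal_dag, h.drug, h.outcome)
    if config.criterion == BACKDOOR:
        adj = backdoor_sets(dag, h.indication, h.outcome,
                            cap=config.backdoor_cap, forbidden={h.drug})
    else:
        adj = disjunctive_cause_set(dag, h.indication, h.outcome,
                                    mediator=h.drug)
    adj = prune_hierarchy(adj, graph)
    graph_covs = sorted(adj.covariates)
    _log("adjust", h.key(), config.criterion, ",".join(graph_covs) or "(empty)")

    data = table.data.set_index("person_id")
    for node in graph_covs:
        data[f"adj_{node}"] = _node_covariate(cohort, graph, node,
                                              descendants).reindex(data.index).fillna(0).astype(int)
    graph_cols = [f"adj_{node}" for node in graph_covs]
    # categorical demographics enter as dummy indicators
    if "ethnicity" in data.columns:
        dummies = pd.get_dummies(data["ethnicity"], prefix="ethnicity",
                                 drop_first=True, dtype=int)
        data = pd.concat([data.drop(columns="ethnicity"), dummies], axis=1)
    demo_cols = [c for c in data.columns
                 if c in DEMOGRAPHICS or c.startswith("ethnicity_")]
    sev_cols = [c for c in SEVERITY_COLUMNS if c in data.columns]
    always = demo_cols + sev_cols

    # drop degenerate graph covariates (constant columns carry no signal)
    graph_cols = [c for c in graph_cols if data[c].nunique() > 1]

    if config.lasso and graph_cols:
        sel_t = select_covariates(data, "indication", graph_cols,
                                  always_keep=always, seed=seed)
        sel_y = select_covariates(data, "outcome", graph_cols,
                                  always_keep=always, seed=seed)
        graph_cols = list(union_selection(sel_t, sel_y))
        _log("lasso", h.key(), "selected", ",".join(graph_cols) or "(none)")

    covs = always + graph_cols
    adj_rows.append((h.indication, h.drug, h.outcome, adj.criterion,
                     ",".join(graph_covs)))
    models = fit_models(data, covariates=covs)
    result = estimate_acme(models, data, sims=config.sims, seed=seed,
                           hypothesis=h)
    _log("mediate", h.key(), "ok",
         f"acme={result.acme:.4g} p={result.p_value:.3g}")
    return result
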