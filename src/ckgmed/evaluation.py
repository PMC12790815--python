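"""Evaluation of predicted drug effects.

Two complementary checks: (i) significant positive-ACME predictions are
compared against a reference side-effect edge list (precision / recall /
F1, with recall restricted to the evaluated hypothesis universe); and
(ii) a side-effect-similarity analysis — drugs with similar binary
side-effect profiles should share therapeutic indications, quantified by
ROC/PR AUC over drug pairs and a Mann–Whitney U comparison of similarity
scores between indication-sharing and non-sharing pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import mannwhitneyu
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    precision: float  # NaN when undefined (no predictions)
    recall: float
    f1: float


@dataclass
class SimilarityAnalysis:
    pairs: tuple            # ((drug_a, drug_b), ...)
    similarity: np.ndarray  # Jaccard of side-effect profiles, symmetric
    labels: np.ndarray      # 1 = pair shares >= 1 indication
    roc_auc: float          # NaN when all labels identical
    pr_auc: float
    mwu_p: float            # Mann-Whitney U of scores, positive vs negative pairs


def match_reference(
    predictions: Iterable[tuple],
    reference: Iterable[tuple],
    universe: Iterable[tuple] | None = None,
) -> EvaluationReport:
    """Precision/recall/F1 of predicted (drug, outcome) pairs.

    ``universe`` restricts the recall denominator to pairs that were
    actually testable (reference pairs outside the evaluated hypothesis
    space cannot be recovered and are not counted as misses).
    """
    pred = {tuple(p) for p in predictions}
    ref = {tuple(r) for r in reference}
    if universe is not None:
        ref = ref & {tuple(u) for u in universe}
    tp = len(pred & ref)
    fp = len(pred - ref)
    fn = len(ref - pred)
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
        f1 = float("nan") if np.isnan(precision) or np.isnan(recall) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return EvaluationReport(tp, fp, fn, precision, recall, f1)


def jaccard(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def shared_indication_auc(
    side_effect_profiles: Mapping[str, Iterable],
    indications: Mapping[str, Iterable],
) -> SimilarityAnalysis:
    """Does side-effect similarity predict shared indications?

    ``side_effect_profiles`` maps each drug to its set of (known plus
    predicted) side effects; ``indications`` to its indicated diseases.
    Every unordered drug pair is scored by Jaccard similarity of the
    profiles and labelled positive when the drugs share at least one
    indication.  ROC AUC is the rank statistic (probability a positive
    pair outranks a negative one); the Mann–Whitney U test compares the
    score distributions of positive and negative pairs.
    """
    profiles = {d: set(v) for d, v in side_effect_profiles.items() if v}
    drugs = sorted(profiles)
    if len(drugs) < 2:
        raise ValueError("need >= 2 drugs with non-empty side-effect profiles")
    ind = {d: set(indications.get(d, ())) for d in drugs}
    pairs, sims, labels = [], [], []
    for a, b in combinations(drugs, 2):
        pairs.append((a, b))
        sims.append(jaccard(profiles[a], profiles[b]))
        labels.append(int(bool(ind[a] & ind[b])))
    sims = np.asarray(sims, float)
    labels = np.asarray(labels, int)
    if labels.min() == labels.max():
        roc = pr = mwu = float("nan")
    else:
        roc = float(roc_auc_score(labels, sims))
        pr = float(average_precision_score(labels, sims))
        mwu = float(mannwhitneyu(sims[labels == 1], sims[labels == 0],
                                 alternative="greater").pvalue)
    return SimilarityAnalysis(tuple(pairs), sims, labels, roc, pr, mwu)
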