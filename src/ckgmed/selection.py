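"""L1-penalised covariate selection for adjustment sets.

Graph-derived adjustment sets can be large; two LASSO models — one
predicting the indication, one the outcome — shrink them, and the union of
covariates selected in either model is used for adjustment.  Binary targets
use logistic loss with an L1 penalty; the regularisation strength is chosen
to minimise 10-fold cross-validated error.  Demographic covariates can be
passed as ``always_keep``: they enter the design (so selection of graph
covariates is conditional on them) but are reported as kept regardless of
shrinkage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler


def _l1_logistic(lam: float, n: int) -> LogisticRegression:
    """L1 logistic at per-observation penalty λ (sklearn C = 1/(n·λ))."""
    C = 1e8 if lam <= 0 else 1.0 / (n * lam)
    return LogisticRegression(C=C, l1_ratio=1.0, solver="liblinear",
                              max_iter=5000, random_state=0)

logger = logging.getLogger(__name__)

TARGETS = {"indication": "T", "outcome": "Y"}


@dataclass
class LassoSelection:
    target: str
    lam: float
    selected: tuple
    cv_error_curve: tuple = ()  # ((lambda, mean CV deviance), ...)
    kept: tuple = ()            # always-keep covariates, reported unconditionally


def select_covariates(
    table: pd.DataFrame,
    target: str,
    candidates: Sequence[str],
    always_keep: Sequence[str] = (),
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 20,
    lambdas: Sequence[float] | None = None,
) -> LassoSelection:
    """L1-penalised logistic selection of ``candidates`` for one target.

    Parameters
    ----------
    table : analysis table with a ``T``/``Y`` column for the target plus
        candidate columns.
    target : ``"indication"`` (predicts T) or ``"outcome"`` (predicts Y).
    candidates : graph-derived covariate columns eligible for selection.
    always_keep : covariates included in the design but exempt from
        selection (kept unconditionally).
    lambdas : optional explicit penalty grid (per-observation scale, as in
        the objective ``mean loss + λ·||β||₁``); default is a log-spaced
        grid chosen from the data scale.

    Fold assignment is fully determined by ``seed``.  A constant target
    yields an empty selection with a warning; fewer rows than folds reduces
    the fold count with a warning.
    """
    if target not in TARGETS:
        raise ValueError(f"target must be one of {sorted(TARGETS)}")
    ycol = TARGETS[target]
    candidates = [c for c in candidates if c in table.columns]
    y = table[ycol].to_numpy()
    cols = list(always_keep) + list(candidates)
    if not cols:
        return LassoSelection(target, float("inf"), (), kept=tuple(always_keep))
    X = table[cols].to_numpy(dtype=float)
    X = StandardScaler().fit_transform(X)
    n = len(y)

    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        warnings.warn(f"{target} target is constant; empty selection")
        return LassoSelection(target, float("inf"), (), kept=tuple(always_keep))
    if int(counts.min()) < 2:
        warnings.warn(f"{target} target has a singleton class; empty selection")
        return LassoSelection(target, float("inf"), (), kept=tuple(always_keep))
    if n < folds or int(counts.min()) < folds:
        warnings.warn(f"too few rows for {folds} folds; reducing fold count")
        folds = max(2, min(n, int(counts.min())))

    if lambdas is not None:
        lam_grid = np.asarray(sorted(lambdas, reverse=True), dtype=float)
    else:
        lam_grid = np.logspace(-4, 0, n_lambdas)[::-1]

    # explicit CV over the penalty grid: mean held-out binomial deviance
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(X, y))
    mean_dev = np.empty(len(lam_grid))
    for k, lam in enumerate(lam_grid):
        dev = 0.0
        for train, test in splits:
            model = _l1_logistic(lam, len(train))
            model.fit(X[train], y[train])
            p = np.clip(model.predict_proba(X[test])[:, 1], 1e-12, 1 - 1e-12)
            yt = (y[test] == classes[1]).astype(float)
            dev += -2.0 * np.mean(yt * np.log(p) + (1 - yt) * np.log(1 - p))
        mean_dev[k] = dev / len(splits)
    best_idx = int(np.argmin(mean_dev))
    lam = float(lam_grid[best_idx])
    final = _l1_logistic(lam, n)
    final.fit(X, y)
    coefs = final.coef_.ravel()
    selected = tuple(
        c for c, b in zip(cols, coefs) if c in set(candidates) and abs(b) > 1e-8
    )
    curve = tuple(zip(map(float, lam_grid), map(float, mean_dev)))
    return LassoSelection(target, lam, selected, cv_error_curve=curve,
                          kept=tuple(always_keep))


def fit_l1_at(
    table: pd.DataFrame, target: str, candidates: Sequence[str], lam: float
) -> dict:
    """Single L1 logistic fit at a fixed penalty; returns column → coefficient.

    ``lam`` on the per-observation scale; ``lam=0`` is the unpenalised limit
    (approximated with a very large C).
    """
    ycol = TARGETS[target]
    X = StandardScaler().fit_transform(table[list(candidates)].to_numpy(float))
    y = table[ycol].to_numpy()
    n = len(y)
    model = _l1_logistic(lam, n)
    model.fit(X, y)
    return dict(zip(candidates, model.coef_.ravel()))


def union_selection(sel_t: LassoSelection, sel_y: LassoSelection) -> tuple:
    """Union of covariates selected in either model, order-normalised."""
    return tuple(sorted(set(sel_t.selected) | set(sel_y.selected)))
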