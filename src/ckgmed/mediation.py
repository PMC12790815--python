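"""Regression-based causal mediation analysis with quasi-Bayesian inference.

For a hypothesis with treatment ``T`` (indication diagnosed), mediator ``M``
(drug taken) and outcome ``Y`` (candidate side effect diagnosed), the
estimand is the natural indirect effect

.. math::

    \\mathrm{NIE} = E[Y(0, M(1)) - Y(0, M(0))],

the change in the outcome from shifting the mediator between its treated and
untreated values while the treatment stays at baseline.  Reported as the
average causal mediation effect (ACME) on the outcome-probability scale.

Estimation fits two regressions — a mediator model ``M ~ T + X`` and an
outcome model ``Y ~ T + M (+ T×M) + X`` — with heteroskedasticity-consistent
(HC3) coefficient covariances, then draws coefficient vectors from their
asymptotic normal approximation (quasi-Bayesian simulation).  Per draw,
potential-outcome expectations are computed for every person and averaged;
with a binary mediator the expectation over ``M`` is an exact two-term sum,
so the coefficient draw is the only stochastic element.  Confidence
intervals are percentile intervals over draws; the p-value is the two-sided
simulation tail probability.  The interaction term ``T×M`` is kept only when
its coefficient is significant in a pre-screen.

Benjamini–Hochberg correction is applied across all hypotheses of a run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import UntestableHypothesis

logger = logging.getLogger(__name__)

BINOMIAL = "binomial"
GAUSSIAN = "gaussian"


@dataclass
class FittedModels:
    """Mediator and outcome regressions for one hypothesis.

    Families are ``"binomial"`` (logit link, binary variable) or
    ``"gaussian"`` (identity link); covariances are HC3.
    """

    mediator_params: np.ndarray
    mediator_cov: np.ndarray
    mediator_cols: tuple
    mediator_family: str
    outcome_params: np.ndarray
    outcome_cov: np.ndarray
    outcome_cols: tuple
    outcome_family: str
    interaction_included: bool
    covariates: tuple
    n: int


@dataclass
class MediationResult:
    indication: str | None
    drug: str | None
    outcome: str | None
    acme: float
    acme_ci: tuple
    p_value: float
    ade: float
    total_effect: float
    prop_mediated: float
    interaction_included: bool
    n: int
    sims: int
    seed: int
    q_value: float = float("nan")
    significant: bool = False
    status: str = "ok"
    acme_draw_sd: float = float("nan")


def _family_of(values: np.ndarray) -> str:
    vals = np.unique(values)
    return BINOMIAL if np.isin(vals, (0, 1)).all() else GAUSSIAN


def _fit(y: np.ndarray, X: np.ndarray, family: str):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == BINOMIAL:
            model = sm.GLM(y, X, family=sm.families.Binomial())
        else:
            model = sm.OLS(y, X)
        try:
            res = model.fit(cov_type="HC3")
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError) as exc:
            raise UntestableHypothesis(f"model fit failed: {exc}") from exc
    params = np.asarray(res.params, float)
    cov = np.asarray(res.cov_params(), float)
    if not np.all(np.isfinite(params)) or not np.all(np.isfinite(cov)):
        raise UntestableHypothesis("non-finite estimates (likely separation)")
    # separation shows up as exploding logistic coefficients
    if family == BINOMIAL and np.abs(params).max() > 30:
        raise UntestableHypothesis("quasi-separation: unbounded logistic coefficients")
    return res, params, cov


def fit_models(
    table: pd.DataFrame,
    covariates: Sequence[str] = (),
    interaction_alpha: float = 0.05,
) -> FittedModels:
    """Fit the mediator and outcome regressions for one analysis table.

    The outcome model is first fit with the ``T×M`` interaction; the term is
    kept iff its (HC3) p-value is below ``interaction_alpha``, otherwise the
    model is refit without it.  Binary columns get a logit link, continuous
    ones an identity link, so linear-Gaussian data are handled by the same
    interface.

    Raises
    ------
    UntestableHypothesis
        when T, M or Y is constant, or a fit fails to converge / separates.
    """
    covariates = tuple(c for c in covariates if c in table.columns)
    for col in ("T", "M", "Y"):
        if table[col].nunique() < 2:
            raise UntestableHypothesis(f"{col} is constant")
    n = len(table)
    Xc = table[list(covariates)].to_numpy(float) if covariates else np.empty((n, 0))
    T = table["T"].to_numpy(float)
    M = table["M"].to_numpy(float)
    Y = table["Y"].to_numpy(float)

    med_cols = ("const", "T") + covariates
    Xm = np.column_stack([np.ones(n), T, Xc])
    med_family = _family_of(M)
    _, med_params, med_cov = _fit(M, Xm, med_family)

    out_family = _family_of(Y)
    cols_int = ("const", "T", "M", "T:M") + covariates
    X_int = np.column_stack([np.ones(n), T, M, T * M, Xc])
    interaction = False
    try:
        res_int, p_int, c_int = _fit(Y, X_int, out_family)
        interaction = bool(res_int.pvalues[3] < interaction_alpha)
    except UntestableHypothesis:
        res_int = None  # fall back to the additive model
    if interaction:
        out_cols, out_params, out_cov = cols_int, p_int, c_int
    else:
        out_cols = ("const", "T", "M") + covariates
        X_add = np.column_stack([np.ones(n), T, M, Xc])
        _, out_params, out_cov = _fit(Y, X_add, out_family)

    return FittedModels(
        mediator_params=med_params, mediator_cov=med_cov,
        mediator_cols=med_cols, mediator_family=med_family,
        outcome_params=out_params, outcome_cov=out_cov,
        outcome_cols=out_cols, outcome_family=out_family,
        interaction_included=interaction, covariates=covariates, n=n,
    )


def _draw_coefs(rng, params, cov, sims):
    # symmetrise + jitter so Cholesky-based sampling never fails on
    # numerically semi-definite HC3 covariances
    cov = (cov + cov.T) / 2.0
    jitter = 1e-12 * max(1.0, float(np.trace(cov)) / max(len(params), 1))
    cov = cov + jitter * np.eye(len(params))
    return rng.multivariate_normal(params, cov, size=sims, method="cholesky")


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def estimate_acme(
    models: FittedModels,
    table: pd.DataFrame,
    sims: int = 1000,
    seed: int = 0,
    hypothesis=None,
) -> MediationResult:
    """Quasi-Bayesian ACME/ADE/total-effect estimation.

    Per coefficient draw and per person the mediator distribution under
    ``T=0`` and ``T=1`` and the potential-outcome expectations
    ``E[Y(t, M(t'))]`` are computed — by exact summation over ``m ∈ {0,1}``
    for a binary mediator, or by plugging the mediator mean into the
    (linear) outcome model for a continuous one.  ACME is reported at
    ``t=0`` (the natural indirect effect), ADE at ``t=1``, both averaged
    over the observed covariate distribution and over draws.  CI bounds are
    2.5/97.5 draw percentiles; ``p = 2·min(Pr(draw≤0), Pr(draw≥0))``
    floored at ``1/sims``; the mediated proportion is the draw-median of
    ACME/total.
    """
    if sims < 1:
        raise ValueError("sims must be >= 1")
    rng = np.random.default_rng(seed)
    n = models.n
    covariates = models.covariates
    Xc = table[list(covariates)].to_numpy(float) if covariates else np.empty((n, 0))

    Bm = _draw_coefs(rng, models.mediator_params, models.mediator_cov, sims)
    By = _draw_coefs(rng, models.outcome_params, models.outcome_cov, sims)

    ones = np.ones(n)
    zeros = np.zeros(n)

    def med_mean(t):
        X = np.column_stack([ones, np.full(n, float(t)), Xc])
        eta = X @ Bm.T  # (n, sims)
        return _expit(eta) if models.mediator_family == BINOMIAL else eta

    def outcome_mean(t, m):
        # m: scalar or (n, sims) mediator value
        tvec = np.full(n, float(t))
        if np.isscalar(m):
            mcol = np.full(n, float(m))
            base = [ones, tvec, mcol]
            if models.interaction_included:
                base.append(tvec * mcol)
            X = np.column_stack(base + [Xc])
            eta = X @ By.T
        else:
            # continuous mediator: assemble eta per draw (linear outcome model)
            idx = {c: i for i, c in enumerate(models.outcome_cols)}
            eta = (
                By[:, idx["const"]][None, :]
                + np.outer(tvec, By[:, idx["T"]])
                + m * By[:, idx["M"]][None, :]
            )
            if models.interaction_included:
                eta = eta + (tvec[:, None] * m) * By[:, idx["T:M"]][None, :]
            if covariates:
                eta = eta + Xc @ By[:, 3 + models.interaction_included:].T
        return _expit(eta) if models.outcome_family == BINOMIAL else eta

    def potential(t, t_prime, pm):
        """Row/draw matrix of E[Y(t, M(t'))]; pm = mediator mean under t'."""
        if models.mediator_family == BINOMIAL:
            return outcome_mean(t, 1) * pm + outcome_mean(t, 0) * (1.0 - pm)
        return outcome_mean(t, pm)

    pm0 = med_mean(0)
    pm1 = med_mean(1)
    y00 = potential(0, 0, pm0).mean(axis=0)  # (sims,)
    y01 = potential(0, 1, pm1).mean(axis=0)
    y11 = potential(1, 1, pm1).mean(axis=0)

    acme_draws = y01 - y00          # indirect effect at t = 0
    ade_draws = y11 - y01           # direct effect at t = 1
    total_draws = y11 - y00         # = acme + ade identically

    def summarise(draws):
        return float(draws.mean()), (
            float(np.percentile(draws, 2.5)),
            float(np.percentile(draws, 97.5)),
        )

    acme, acme_ci = summarise(acme_draws)
    ade, _ = summarise(ade_draws)
    total, _ = summarise(total_draws)
    p = 2.0 * min((acme_draws <= 0).mean(), (acme_draws >= 0).mean())
    p = float(min(1.0, max(p, 1.0 / sims)))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(total_draws != 0, acme_draws / total_draws, np.nan)
    prop_mediated = float(np.nanmedian(ratio))

    hyp = hypothesis.key() if hypothesis is not None and hasattr(hypothesis, "key") else (None, None, None)
    return MediationResult(
        indication=hyp[0], drug=hyp[1], outcome=hyp[2],
        acme=acme, acme_ci=acme_ci, p_value=p,
        ade=ade, total_effect=total, prop_mediated=prop_mediated,
        interaction_included=models.interaction_included,
        n=n, sims=sims, seed=seed,
        acme_draw_sd=float(acme_draws.std(ddof=1)),
    )


def bh_correct(results: Sequence[MediationResult], alpha: float = 0.05) -> list:
    """Benjamini–Hochberg step-up correction across a run's results.

    Only ``status == "ok"`` results enter the correction; others pass
    through unchanged.  ``significant`` is set iff ``q ≤ alpha``; the sign
    of a significant ACME splits predictions into adverse (positive) and
    protective (negative) categories.
    """
    ok = [r for r in results if r.status == "ok"]
    if ok:
        reject, q, _, _ = multipletests(
            [r.p_value for r in ok], alpha=alpha, method="fdr_bh"
        )
        fixed = {
            id(r): replace(r, q_value=float(qi), significant=bool(ri))
            for r, ri, qi in zip(ok, reject, q)
        }
        return [fixed.get(id(r), r) for r in results]
    return list(results)


def untestable_result(hypothesis, reason: str, sims: int, seed: int) -> MediationResult:
    """Placeholder result for a hypothesis that could not be analysed."""
    key = hypothesis.key() if hasattr(hypothesis, "key") else (None, None, None)
    status = "NA_" + reason.split(":")[0].strip().replace(" ", "_")[:40]
    return MediationResult(
        indication=key[0], drug=key[1], outcome=key[2],
        acme=float("nan"), acme_ci=(float("nan"), float("nan")),
        p_value=float("nan"), ade=float("nan"), total_effect=float("nan"),
        prop_mediated=float("nan"), interaction_included=False,
        n=0, sims=sims, seed=seed, status=status,
    )


def results_frame(results: Sequence[MediationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "indication": r.indication, "drug": r.drug, "outcome": r.outcome,
            "n": r.n, "acme": r.acme, "ci_low": r.acme_ci[0],
            "ci_high": r.acme_ci[1], "p": r.p_value, "q": r.q_value,
            "ade": r.ade, "total": r.total_effect,
            "prop_mediated": r.prop_mediated,
            "interaction": r.interaction_included,
            "sims": r.sims, "seed": r.seed, "status": r.status,
            "significant": r.significant,
        })
    return pd.DataFrame(rows)
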