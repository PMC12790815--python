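"""Synthetic longitudinal cohorts with planted mediation effects.

Generates a cohort (dated diagnoses, dated prescriptions, demographics,
follow-up) plus a companion knowledge graph whose progression and
indication edges contain the planted hypotheses, so every pipeline stage —
hypothesis generation, contradiction and support filtering, adjustment,
LASSO, mediation — can be tested against known structural equations.

Each planted hypothesis (indication disease X, drug M, outcome disease Y)
is an independent block of logistic structural equations per person:

.. math::

    T \\sim \\mathrm{Bern}(\\sigma(\\alpha_T + \\gamma_T C)) \\qquad
    M \\sim \\mathrm{Bern}(\\sigma(\\alpha_M + a T + \\gamma_M C)) \\qquad
    Y \\sim \\mathrm{Bern}(\\sigma(\\alpha_Y + b M + c T + \\gamma_Y C))

where ``C`` is a standardized confounder score built from the demographic
covariates (so demographics genuinely confound T and Y), ``a`` the
treatment→mediator effect, ``b`` the drug→outcome effect under test and
``c`` the direct progression effect.  Event dates are drawn inside windows
respecting the order indication → drug → outcome; a configurable fraction
of records is deliberately disordered to exercise the temporal-validity
exclusions, and decoy graph edges (drug indicated for both diseases; both
diseases side effects of one drug; a triple never observed) give each
knowledge-based filter a dedicated target.

An optional severity mechanism adds a latent per-person severity ``S``
pushing both drug use and outcome (the classic unmitigated-severe-disease
confounding pattern); the observable comorbidity/prescription counts are
driven by ``S`` so that adjusting for them reduces the induced bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort
from .errors import FormatError
from .graph import CKGraph

BASE_DATE = np.datetime64("2001-01-01")


@dataclass(frozen=True)
class PlantedHypothesis:
    """One structural-equation block: indication X, drug M, outcome Y."""

    indication: str
    drug: str
    outcome: str
    a: float = 1.5        # T -> M (log-odds)
    b: float = 0.0        # M -> Y (log-odds): the mediated drug effect
    c: float = 0.5        # T -> Y direct progression (log-odds)
    alpha_t: float = -0.8
    alpha_m: float = -1.5
    alpha_y: float = -2.2
    gamma_t: float = 0.4  # confounder score -> T
    gamma_m: float = 0.0
    gamma_y: float = 0.4
    sev_m: float = 0.0    # latent severity -> M
    sev_y: float = 0.0    # latent severity -> Y
    kind: str = "effect"  # effect | null | contra_indication | contra_side_effect | unsupported

    def key(self):
        return (self.indication, self.drug, self.outcome)


@dataclass
class SimulationConfig:
    n_persons: int = 5000
    seed: int = 0
    hypotheses: tuple = ()
    frac_child_coded: float = 0.2   # diagnoses recorded at the child ICD code
    frac_no_followup: float = 0.02
    frac_disordered: float = 0.02   # event dates scrambled out of valid order
    severity_sd: float = 1.0
    comorbidity_rate: float = 2.0   # baseline Poisson rate of extra comorbidities
    prescription_rate: float = 1.5
    severity_count_slope: float = 0.8  # log-rate slope of counts in severity

    def __post_init__(self):
        keys = [h.key() for h in self.hypotheses]
        if len(keys) != len(set(keys)):
            raise FormatError("duplicate planted hypothesis triples")


def default_config(
    n_persons: int = 10_000,
    n_effects: int = 5,
    n_nulls: int = 20,
    seed: int = 0,
    effect_b: float = 1.2,
    severity: float = 0.0,
) -> SimulationConfig:
    """Study-sized default scenario: planted adverse effects among null decoys.

    ``n_effects`` triples carry a real mediated drug effect (``b``); the
    null triples keep the progression edge but a zero drug effect.  Three of
    the nulls additionally get one knowledge-graph decoy pattern each
    (drug indicated for both diseases / shared side-effect listing /
    unobserved drug), so each filter rule has a dedicated fixture.
    """
    hyps = []
    total = n_effects + n_nulls
    for i in range(total):
        kind = "effect" if i < n_effects else "null"
        hyps.append(PlantedHypothesis(
            indication=f"D{i:02d}", drug=f"RX{i:03d}", outcome=f"E{i:02d}",
            b=effect_b if kind == "effect" else 0.0,
            sev_m=severity, sev_y=severity,
            kind=kind,
        ))
    # knowledge-graph decoys on the last three nulls
    if n_nulls >= 3:
        hyps[-1] = dataclass_replace(hyps[-1], kind="contra_indication")
        hyps[-2] = dataclass_replace(hyps[-2], kind="contra_side_effect")
        hyps[-3] = dataclass_replace(hyps[-3], kind="unsupported")
    return SimulationConfig(n_persons=n_persons, seed=seed, hypotheses=tuple(hyps))


def dataclass_replace(h: PlantedHypothesis, **kw) -> PlantedHypothesis:
    from dataclasses import replace
    return replace(h, **kw)


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _demographics(rng, n):
    sex = rng.integers(0, 2, n)
    age = rng.normal(57.0, 8.0, n)
    bmi = rng.normal(27.0, 4.5, n)
    ethnicity = rng.integers(0, 4, n)
    conf = 0.5 * (age - 57.0) / 8.0 + 0.4 * (sex - 0.5) + 0.4 * (bmi - 27.0) / 4.5
    cov = pd.DataFrame({
        "person_id": [f"P{i:06d}" for i in range(n)],
        "sex": sex,
        "age": np.round(age, 1),
        "bmi": np.round(bmi, 1),
        "ethnicity": ethnicity,
    })
    return cov, conf


def generate(config: SimulationConfig):
    """Sample a cohort, companion graph and ground truth.

    Returns ``(cohort, graph, ground_truth)`` where ``ground_truth`` is a
    DataFrame with one row per planted triple (coefficients, kind and the
    latent person-level variables left out — the oracle NIE is computed
    separately by :func:`true_nie`).  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    cov, conf = _demographics(rng, n)
    persons = cov["person_id"].to_numpy()
    severity = rng.normal(0.0, config.severity_sd, n)

    diag_person, diag_code, diag_day = [], [], []
    presc_person, presc_code, presc_day = [], [], []
    triples = []
    truth_rows = []

    for h in config.hypotheses:
        T = rng.random(n) < _expit(h.alpha_t + h.gamma_t * conf)
        pm = _expit(h.alpha_m + h.a * T + h.gamma_m * conf + h.sev_m * severity)
        M = rng.random(n) < pm
        py = _expit(h.alpha_y + h.b * M + h.c * T + h.gamma_y * conf
                    + h.sev_y * severity)
        Y = rng.random(n) < py
        if h.kind == "unsupported":
            M = np.zeros(n, bool)  # drug never observed in the cohort

        # dates respecting indication -> drug -> outcome
        t_day = rng.integers(0, 1500, n)
        m_day = np.where(T, t_day + rng.integers(0, 365, n),
                         rng.integers(0, 1500, n))
        anchor = np.maximum(np.where(T, t_day, 0), np.where(M, m_day, 0))
        y_day = anchor + rng.integers(1, 365, n)
        scramble = rng.random(n) < config.frac_disordered
        y_day = np.where(scramble & T, np.maximum(t_day - rng.integers(1, 400, n), 0), y_day)

        for person_idx in np.flatnonzero(T):
            diag_person.append(persons[person_idx])
            diag_code.append(h.indication)
            diag_day.append(t_day[person_idx])
        for person_idx in np.flatnonzero(Y):
            diag_person.append(persons[person_idx])
            diag_code.append(h.outcome)
            diag_day.append(y_day[person_idx])
        for person_idx in np.flatnonzero(M):
            presc_person.append(persons[person_idx])
            presc_code.append(h.drug)
            presc_day.append(m_day[person_idx])

        triples.append((h.indication, "progression", h.outcome))
        triples.append((h.drug, "indication", h.indication))
        triples.append((h.indication + "1", "is_a", h.indication))
        triples.append((h.outcome + "1", "is_a", h.outcome))
        if h.kind == "contra_indication":
            triples.append((h.drug, "indication", h.outcome))
        if h.kind == "contra_side_effect":
            decoy = "RXSE" + h.drug[2:]
            triples.append((decoy, "side_effect", h.indication))
            triples.append((decoy, "side_effect", h.outcome))
        truth_rows.append({
            "indication": h.indication, "drug": h.drug, "outcome": h.outcome,
            "kind": h.kind, "a": h.a, "b": h.b, "c": h.c,
        })

    # recode a fraction of diagnoses at the child (4-character) ICD level
    diag_code = np.asarray(diag_code, dtype=object)
    child = rng.random(len(diag_code)) < config.frac_child_coded
    diag_code[child] = diag_code[child] + "1"

    # background comorbidities/prescriptions driving the severity proxies
    com_rate = config.comorbidity_rate * np.exp(config.severity_count_slope * severity)
    extra_diag = rng.poisson(com_rate)
    presc_rate = config.prescription_rate * np.exp(config.severity_count_slope * severity)
    extra_presc = rng.poisson(presc_rate)
    bg_codes = np.array([f"Z{j:02d}" for j in range(30)], dtype=object)
    bg_drugs = np.array([f"RXB{j:02d}" for j in range(30)], dtype=object)
    bg_diag_person, bg_diag_code = [], []
    for person_idx in range(n):
        k = min(int(extra_diag[person_idx]), 30)
        if k:
            bg_diag_person.extend([persons[person_idx]] * k)
            bg_diag_code.extend(rng.choice(bg_codes, size=k, replace=False))
        k = min(int(extra_presc[person_idx]), 30)
        if k:
            presc_person.extend([persons[person_idx]] * k)
            presc_code.extend(rng.choice(bg_drugs, size=k, replace=False))
            presc_day.extend(rng.integers(0, 2000, k))

    all_diag_person = list(diag_person) + bg_diag_person
    all_diag_code = list(diag_code) + bg_diag_code
    all_diag_day = list(diag_day) + list(rng.integers(0, 2000, len(bg_diag_code)))
    diagnoses = pd.DataFrame({
        "person_id": all_diag_person,
        "icd10": all_diag_code,
        "date": BASE_DATE + np.asarray(all_diag_day, dtype="timedelta64[D]"),
    })
    prescriptions = pd.DataFrame({
        "person_id": presc_person,
        "rxnorm": presc_code,
        "date": BASE_DATE + np.asarray(presc_day, dtype="timedelta64[D]"),
    })
    followup = pd.Series(
        rng.random(n) >= config.frac_no_followup, index=persons
    )
    cohort = Cohort(diagnoses, prescriptions, cov, followup)
    graph = CKGraph.from_edges(triples)
    ground_truth = pd.DataFrame(truth_rows)
    return cohort, graph, ground_truth


# ---------------------------------------------------------------------------
# oracles and compact calibration generators


def true_nie(
    config: SimulationConfig, hypothesis, mc_n: int = 1_000_000, seed: int = 0
):
    """Monte-Carlo oracle for the natural indirect effect of a planted triple.

    Simulates the potential mediators M(0), M(1) and the potential outcomes
    Y(0, M(1)), Y(0, M(0)) directly from the true structural equations and
    returns ``(value, mc_se)``.  Independent of the estimation code path.
    """
    h = _find_hypothesis(config, hypothesis)
    rng = np.random.default_rng(seed)
    _, conf = _demographics(rng, mc_n)
    severity = rng.normal(0.0, config.severity_sd, mc_n)
    m0 = rng.random(mc_n) < _expit(h.alpha_m + h.gamma_m * conf + h.sev_m * severity)
    m1 = rng.random(mc_n) < _expit(h.alpha_m + h.a + h.gamma_m * conf + h.sev_m * severity)
    u = rng.random(mc_n)  # shared outcome noise: pure mediator contrast
    y0m1 = u < _expit(h.alpha_y + h.b * m1 + h.gamma_y * conf + h.sev_y * severity)
    y0m0 = u < _expit(h.alpha_y + h.b * m0 + h.gamma_y * conf + h.sev_y * severity)
    delta = y0m1.astype(float) - y0m0.astype(float)
    return float(delta.mean()), float(delta.std(ddof=1) / np.sqrt(mc_n))


def _find_hypothesis(config: SimulationConfig, hypothesis) -> PlantedHypothesis:
    key = hypothesis.key() if hasattr(hypothesis, "key") else tuple(hypothesis)
    for h in config.hypotheses:
        if h.key() == key:
            return h
    raise KeyError(f"hypothesis {key} not planted in config")


def binary_mediation_dataset(
    n: int,
    a: float = 1.0,
    b: float = 1.0,
    c: float = 0.3,
    alpha_t: float = 0.0,
    alpha_m: float = -1.0,
    alpha_y: float = -2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Plain binary T/M/Y table from logistic structural equations.

    Compact generator for estimator calibration studies (no dates, no
    confounders — the models are then correctly specified by construction).
    """
    rng = np.random.default_rng(seed)
    T = (rng.random(n) < _expit(np.full(n, alpha_t))).astype(int)
    M = (rng.random(n) < _expit(alpha_m + a * T)).astype(int)
    Y = (rng.random(n) < _expit(alpha_y + b * M + c * T)).astype(int)
    return pd.DataFrame({"T": T, "M": M, "Y": Y})


def binary_true_nie(
    a: float = 1.0, b: float = 1.0,
    alpha_m: float = -1.0, alpha_y: float = -2.0,
) -> float:
    """Closed-form NIE for :func:`binary_mediation_dataset` (no confounders).

    NIE = (σ(α_y + b) − σ(α_y)) · (σ(α_m + a) − σ(α_m)).
    """
    dm = _expit(alpha_m + a) - _expit(alpha_m)
    dy = _expit(alpha_y + b) - _expit(alpha_y)
    return float(dm * dy)


def linear_gaussian_dataset(
    n: int, a: float = 0.5, b: float = 0.4, c: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Linear-Gaussian mediation data: M = aT + ε, Y = bM + cT + ε.

    With identity links and no interaction the NIE is exactly ``a·b``
    (product of coefficients), giving a closed-form recovery check.
    """
    rng = np.random.default_rng(seed)
    T = rng.integers(0, 2, n).astype(float)
    M = a * T + rng.normal(0.0, 1.0, n)
    Y = b * M + c * T + rng.normal(0.0, 1.0, n)
    return pd.DataFrame({"T": T, "M": M, "Y": Y})


# ---------------------------------------------------------------------------
# config file round-trip (for the CLI)


def config_from_yaml(path) -> SimulationConfig:
    raw = yaml.safe_load(Path(path).read_text())
    hyps = tuple(PlantedHypothesis(**h) for h in raw.pop("hypotheses", []))
    return SimulationConfig(hypotheses=hyps, **raw)


def write_ground_truth(ground_truth: pd.DataFrame, path) -> None:
    ground_truth.to_csv(path, sep="\t", index=False)
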