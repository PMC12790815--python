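"""Longitudinal cohort tables and per-hypothesis analysis encoding.

A cohort holds dated diagnoses (ICD-10), dated drug prescriptions (RxNorm),
a per-person covariate table and a follow-up flag.  For a mediation
hypothesis (indication disease ``x``, drug ``m``, outcome disease ``y``) the
cohort is reduced to a binary analysis table with one row per retained
person: ``T`` (ever diagnosed with the indication), ``M`` (ever prescribed
the drug), ``Y`` (ever diagnosed with the outcome), plus covariates.

Temporal validity enforces the required event order indication → drug →
outcome: persons without follow-up are dropped, as are persons whose outcome
preceded the indication or the drug, or whose drug use occurred only before
the indication diagnosis.  Same-day events count as validly ordered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError
from .graph import icd_category, normalize_icd

DEMOGRAPHIC_NUMERIC = ("age", "bmi")
SEVERITY_COLUMNS = ("comorbidity_count", "prescription_count")


@dataclass
class Cohort:
    """Per-person longitudinal records.

    ``diagnoses``: columns ``person_id, icd10, date``;
    ``prescriptions``: columns ``person_id, rxnorm, date``;
    ``covariates``: one row per person (``person_id`` plus demographic and
    lifestyle columns); ``followup``: ``person_id`` → bool.
    """

    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    covariates: pd.DataFrame
    followup: pd.Series

    def __post_init__(self):
        self.diagnoses = self.diagnoses.copy()
        self.prescriptions = self.prescriptions.copy()
        self.diagnoses["icd10"] = self.diagnoses["icd10"].map(normalize_icd)
        self.diagnoses["date"] = pd.to_datetime(self.diagnoses["date"])
        self.prescriptions["rxnorm"] = self.prescriptions["rxnorm"].astype(str)
        self.prescriptions["date"] = pd.to_datetime(self.prescriptions["date"])
        known = set(self.covariates["person_id"])
        for df, label in ((self.diagnoses, "diagnosis"),
                          (self.prescriptions, "prescription")):
            missing = set(df["person_id"]) - known
            if missing:
                raise FormatError(
                    f"{len(missing)} {label} person ids absent from covariates "
                    f"(e.g. {sorted(missing)[:3]})"
                )

    def persons(self) -> frozenset:
        return frozenset(self.covariates["person_id"])

    def covariate_columns(self) -> list:
        return [c for c in self.covariates.columns if c != "person_id"]


def load_cohort(cohort_dir: "str | Path") -> Cohort:
    """Read ``diagnoses.tsv``, ``prescriptions.tsv``, ``covariates.tsv`` and
    ``followup.tsv`` from a directory."""
    cohort_dir = Path(cohort_dir)
    diagnoses = pd.read_csv(cohort_dir / "diagnoses.tsv", sep="\t", dtype=str)
    prescriptions = pd.read_csv(cohort_dir / "prescriptions.tsv", sep="\t", dtype=str)
    covariates = pd.read_csv(cohort_dir / "covariates.tsv", sep="\t")
    followup_df = pd.read_csv(cohort_dir / "followup.tsv", sep="\t")
    followup = pd.Series(
        followup_df["has_followup"].astype(bool).values,
        index=followup_df["person_id"].values,
    )
    return Cohort(diagnoses, prescriptions, covariates, followup)


def write_cohort(cohort: Cohort, out_dir: "str | Path") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    diag = cohort.diagnoses.copy()
    diag["date"] = diag["date"].dt.strftime("%Y-%m-%d")
    diag.to_csv(out_dir / "diagnoses.tsv", sep="\t", index=False)
    presc = cohort.prescriptions.copy()
    presc["date"] = presc["date"].dt.strftime("%Y-%m-%d")
    presc.to_csv(out_dir / "prescriptions.tsv", sep="\t", index=False)
    cohort.covariates.to_csv(out_dir / "covariates.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"person_id": cohort.followup.index, "has_followup": cohort.followup.values}
    ).to_csv(out_dir / "followup.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------


@dataclass
class AnalysisTable:
    """Binary mediation table for one hypothesis.

    ``data`` has one row per retained person with columns ``T``, ``M``,
    ``Y`` and covariates.  ``untestable`` marks hypotheses whose entities are
    absent from the cohort vocabulary or that lack a fully supported person
    (some row with T=M=Y=1) — the analysis-summary "N/A" category.
    """

    data: pd.DataFrame
    untestable: bool = False
    reason: str | None = None
    n_excluded: dict = field(default_factory=dict)

    @property
    def supported(self) -> bool:
        if self.data.empty:
            return False
        d = self.data
        return bool(((d["T"] == 1) & (d["M"] == 1) & (d["Y"] == 1)).any())


def _first_dates(df: pd.DataFrame, id_col: str, code: str,
                 codes: frozenset | None = None) -> pd.Series:
    wanted = df[id_col].isin(codes) if codes is not None else df[id_col] == code
    sub = df[wanted]
    return sub.groupby("person_id")["date"].min()


def apply_temporal_validity(
    cohort: Cohort,
    hypothesis,
    descendants: Mapping[str, Iterable] | None = None,
    extra_covariates: pd.DataFrame | None = None,
) -> AnalysisTable:
    """Encode a cohort as a binary (T, M, Y) table for one hypothesis.

    Exclusion rules, applied per person:

    1. no follow-up data;
    2. outcome first-diagnosis strictly before indication first-diagnosis;
    3. outcome first-diagnosis strictly before first drug prescription;
    4. drug use occurred *only* before the indication (last prescription
       strictly before the indication's first diagnosis, both present).

    Disease membership optionally propagates is_a-descendants via
    ``descendants`` (code → iterable of descendant codes).  Persons with the
    drug but not the indication are retained — the mediator model needs
    them.  Same-day ties count as valid order.
    """
    ind = normalize_icd(hypothesis.indication)
    out = normalize_icd(hypothesis.outcome)
    drug = str(hypothesis.drug)
    descendants = descendants or {}

    ind_codes = frozenset({ind} | {normalize_icd(c) for c in descendants.get(ind, ())})
    out_codes = frozenset({out} | {normalize_icd(c) for c in descendants.get(out, ())})

    diag_codes = set(cohort.diagnoses["icd10"])
    if not (ind_codes & diag_codes) or not (out_codes & diag_codes):
        return AnalysisTable(pd.DataFrame(), untestable=True,
                             reason="disease absent from cohort")
    if drug not in set(cohort.prescriptions["rxnorm"]):
        return AnalysisTable(pd.DataFrame(), untestable=True,
                             reason="drug absent from cohort")

    t_date = _first_dates(cohort.diagnoses, "icd10", ind, ind_codes)
    y_date = _first_dates(cohort.diagnoses, "icd10", out, out_codes)
    m_sub = cohort.prescriptions[cohort.prescriptions["rxnorm"] == drug]
    m_first = m_sub.groupby("person_id")["date"].min()
    m_last = m_sub.groupby("person_id")["date"].max()

    table = cohort.covariates.set_index("person_id")
    idx = table.index
    T = idx.isin(t_date.index).astype(int)
    M = idx.isin(m_first.index).astype(int)
    Y = idx.isin(y_date.index).astype(int)

    td = t_date.reindex(idx)
    yd = y_date.reindex(idx)
    mf = m_first.reindex(idx)
    ml = m_last.reindex(idx)

    followup = cohort.followup.reindex(idx).fillna(False).astype(bool).values
    excl_followup = ~followup
    excl_y_before_t = (yd < td).values  # NaT comparisons are False
    excl_y_before_m = (yd < mf).values
    excl_m_only_before_t = (ml < td).values

    excluded = excl_followup | excl_y_before_t | excl_y_before_m | excl_m_only_before_t
    n_excluded = {
        "no_followup": int(excl_followup.sum()),
        "outcome_before_indication": int((excl_y_before_t & followup).sum()),
        "outcome_before_drug": int((excl_y_before_m & followup).sum()),
        "drug_only_before_indication": int((excl_m_only_before_t & followup).sum()),
    }

    data = table.loc[~excluded].copy()
    data.insert(0, "T", T[~excluded])
    data.insert(1, "M", M[~excluded])
    data.insert(2, "Y", Y[~excluded])
    if extra_covariates is not None:
        data = data.join(extra_covariates, how="left")
    return AnalysisTable(data.reset_index(), n_excluded=n_excluded)


def severity_proxies(cohort: Cohort) -> pd.DataFrame:
    """Per-person severity proxies: comorbidity and prescription counts.

    ``comorbidity_count`` is the number of distinct three-character ICD-10
    categories ever diagnosed; ``prescription_count`` the number of distinct
    drugs ever prescribed.  Disease severity itself is unobserved; both
    counts correlate with it and serve as adjustment covariates.
    """
    persons = pd.Index(sorted(cohort.persons()), name="person_id")
    diag = cohort.diagnoses.copy()
    diag["category"] = diag["icd10"].map(icd_category)
    comorb = diag.groupby("person_id")["category"].nunique()
    presc = cohort.prescriptions.groupby("person_id")["rxnorm"].nunique()
    return pd.DataFrame(
        {
            "comorbidity_count": comorb.reindex(persons).fillna(0).astype(int),
            "prescription_count": presc.reindex(persons).fillna(0).astype(int),
        },
        index=persons,
    ).reset_index()
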