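import numpy as np
import pandas as pd
import pytest

from ckgmed.cohort import Cohort
from ckgmed.graph import CKGraph


@pytest.fixture(scope="session")
def toy_graph():
    """Progression A→B→C, two indicated drugs, a side-effect pair, one is_a."""
    return CKGraph.from_edges([
        ("A00", "progression", "B00"),
        ("B00", "progression", "C00"),
        ("RX1", "indication", "A00"),
        ("RX2", "indication", "A00"),
        ("RX3", "indication", "B00"),
        ("RX1", "side_effect", "C00"),
        ("C001", "is_a", "C00"),
    ])


@pytest.fixture(scope="session")
def decoy_graph():
    """One hypothesis-generating edge per contradiction-filter rule.

    Progression pairs: (X1, Y1) clean; (X2, Y2) with the indicated drug RXA
    also indicated for Y2 (rule i); (X3, Y3) with a bystander drug RXSE
    listing both as side effects (rule ii); (X4, Y4) whose drug RXU never
    appears in the cohort (support rule).
    """
    return CKGraph.from_edges([
        ("X1", "progression", "Y1"), ("RXC", "indication", "X1"),
        ("X2", "progression", "Y2"), ("RXA", "indication", "X2"),
        ("RXA", "indication", "Y2"),
        ("X3", "progression", "Y3"), ("RXB", "indication", "X3"),
        ("RXSE", "side_effect", "X3"), ("RXSE", "side_effect", "Y3"),
        ("X4", "progression", "Y4"), ("RXU", "indication", "X4"),
    ])


def _cohort_from_events(diag, presc, persons, no_followup=()):
    covariates = pd.DataFrame({
        "person_id": persons,
        "sex": [i % 2 for i in range(len(persons))],
        "age": [50 + i for i in range(len(persons))],
        "bmi": [25.0] * len(persons),
    })
    followup = pd.Series([p not in set(no_followup) for p in persons],
                         index=persons)
    return Cohort(
        pd.DataFrame(diag, columns=["person_id", "icd10", "date"]),
        pd.DataFrame(presc, columns=["person_id", "rxnorm", "date"]),
        covariates, followup,
    )


@pytest.fixture(scope="session")
def hand_cohort():
    """Twelve hand-dated persons exercising every temporal-validity rule.

    Hypothesis (X, RX, Y).  Expected encoding, applying the rules by hand:

    p01 valid X<RX<Y ............ kept (1,1,1)
    p02 indication only ......... kept (1,0,0)
    p03 Y before X .............. excluded (outcome precedes indication)
    p04 Y before RX ............. excluded (outcome precedes drug)
    p05 RX only before X ........ excluded (drug use only pre-indication)
    p06 RX before and after X ... kept (1,1,0)
    p07 no follow-up ............ excluded
    p08 same-day X and RX ....... kept (1,1,1) (ties are valid order)
    p09 drug without indication . kept (0,1,0)
    p10 outcome only ............ kept (0,0,1)
    p11 X then Y, no drug ....... kept (1,0,1)
    p12 no events ............... kept (0,0,0)

    => 8 retained rows, 3 exclusions by ordering + 1 by follow-up.
    """
    diag = [
        ("p01", "X00", "2001-01-01"), ("p01", "Y00", "2001-06-01"),
        ("p02", "X00", "2001-01-01"),
        ("p03", "Y00", "2000-01-01"), ("p03", "X00", "2001-01-01"),
        ("p04", "X00", "2001-01-01"), ("p04", "Y00", "2001-02-01"),
        ("p05", "X00", "2002-01-01"),
        ("p06", "X00", "2001-06-01"),
        ("p07", "X00", "2001-01-01"),
        ("p08", "X00", "2001-03-01"), ("p08", "Y00", "2001-09-01"),
        ("p10", "Y00", "2001-01-01"),
        ("p11", "X00", "2001-01-01"), ("p11", "Y00", "2002-01-01"),
    ]
    presc = [
        ("p01", "RX9", "2001-02-01"),
        ("p04", "RX9", "2001-06-01"),
        ("p05", "RX9", "2001-06-01"),
        ("p06", "RX9", "2001-01-01"), ("p06", "RX9", "2002-01-01"),
        ("p08", "RX9", "2001-03-01"),
        ("p09", "RX9", "2001-01-01"),
    ]
    persons = [f"p{i:02d}" for i in range(1, 13)]
    return _cohort_from_events(diag, presc, persons, no_followup=("p07",))


@pytest.fixture(scope="session")
def decoy_cohort():
    """Cohort supporting (X1..X3, RX*, Y1..Y3) triples but never RXU."""
    diag, presc = [], []
    persons = [f"q{i:02d}" for i in range(12)]
    for i, (x, rx, y) in enumerate([("X1", "RXC", "Y1"), ("X2", "RXA", "Y2"),
                                    ("X3", "RXB", "Y3"), ("X4", None, "Y4")]):
        for j in range(3):
            p = persons[3 * i + j] if 3 * i + j < len(persons) else persons[-1]
            diag += [(p, x, "2001-01-01"), (p, y, "2002-01-01")]
            if rx:
                presc.append((p, rx, "2001-06-01"))
    return _cohort_from_events(diag, presc, persons)
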