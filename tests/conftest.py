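import numpy as np
import pytest
from hypothesis import settings

from sepscore import (GroupedScoreTable, LabPanel, MentalStatus, Outcome,
                      PatientRecord, VitalSigns, table2_fixture)

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def fixture_tables():
    return table2_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_record(id="p1", outcome=Outcome.SURVIVED, sbp=120.0, rr=16.0,
                mental=MentalStatus.ALERT, lactate=1.0, **labs):
    return PatientRecord(
        id=id, outcome=outcome,
        vitals=VitalSigns(sbp=sbp, rr=rr,
                          hr=labs.pop("hr", None), temp=labs.pop("temp", None),
                          map=labs.pop("map", None)),
        labs=LabPanel(lactate=lactate, **labs),
        mental=mental,
    )


def brute_force_auc(scores, labels):
    """O(n^2) pair-enumeration oracle for the tie-corrected AUC."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


@pytest.fixture
def small_table():
    return GroupedScoreTable(levels=(0.0, 1.0, 2.0),
                             counts_pos=(1, 2, 5), counts_neg=(6, 3, 1))
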