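"""Shared fixtures: a hand-computed ascertainment fixture and a small
synthetic study reused across test modules."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

from metacvd import SimConfig, simulate_study


def days(a: str, b: str) -> int:
    """Calendar-day difference computed independently of the package."""
    return (date.fromisoformat(b) - date.fromisoformat(a)).days


CENSOR = "2021-02-05"


@pytest.fixture(scope="session")
def ascertainment_fixture():
    """20-person episode stream with hand-derived expected outcomes.

    Covers: earliest-date rule, the >= 1-day incident-case rule, same-day
    and prior CVD exclusion, OPCS4 procedure mapping, dotted-code
    tolerance, censoring at min(death, administrative date), events after
    death/censoring, persons without T2D, and the follow-up-length
    sensitivity filter.
    """
    rows = [
        # person, system, code, date
        ("P01", "ICD10", "E11.9", "2010-01-01"),
        ("P01", "ICD10", "I21.9", "2010-01-02"),     # event, 1 day
        ("P02", "ICD10", "E11.9", "2010-01-01"),
        ("P02", "ICD10", "I63.9", "2010-01-01"),     # same-day CVD: excluded
        ("P03", "ICD10", "E11.9", "2010-01-01"),
        ("P03", "ICD10", "I21.0", "2009-05-05"),     # prior CVD: excluded
        ("P04", "ICD10", "E11.9", "2015-06-01"),     # censored by death
        ("P05", "ICD10", "E11.2", "2010-01-01"),     # censored admin
        ("P06", "ICD10", "E11.9", "2020-01-01"),
        ("P06", "ICD10", "I21.9", "2021-03-01"),     # CVD after censor date
        ("P07", "ICD10", "E11.9", "2010-06-01"),
        ("P07", "ICD10", "I50.9", "2010-07-01"),     # earliest CVD wins
        ("P07", "ICD10", "I21.9", "2011-01-01"),
        ("P08", "ICD10", "I21.9", "2010-01-01"),     # no T2D: not in cohort
        ("P09", "ICD10", "E11.9", "2010-01-01"),
        ("P09", "ICD10", "I21.9", "2015-01-01"),     # CVD after death
        ("P10", "ICD10", "E11.9", "2010-01-01"),
        ("P10", "ICD10", "I63.5", "2010-01-31"),     # event, 30 days
        ("P11", "ICD10", "E11.9", "2010-01-01"),
        ("P11", "ICD10", "I21.0", "2010-02-01"),     # event, 31 days
        ("P12", "ICD9", "25000", "2012-03-04"),      # ICD9 T2D
        ("P12", "OPCS4", "K401", "2013-03-04"),      # CABG procedure -> CAD
        ("P13", "ICD10", "E11.9", "2010-01-01"),
        ("P13", "ICD10", "I21.0", "2011-01-01"),     # dotted code, event
        ("P14", "ICD10", "E11.9", "2021-03-01"),     # T2D after censor
        ("P15", "ICD10", "E11.9", "2010-01-01"),     # death after censor
        ("P16", "ICD10", "E11.9", "2010-01-01"),
        ("P16", "ICD10", "I63.9", "2009-12-31"),     # prior IS: excluded
        ("P16", "ICD10", "I21.9", "2010-01-02"),
        ("P17", "ICD10", "E11.9", "2010-01-01"),
        ("P17", "ICD10", "I99", "2012-01-01"),       # non-CVD code ignored
        ("P18", "ICD10", "E11.9", "2011-01-01"),
        ("P18", "ICD10", "E11.2", "2010-05-05"),     # earliest T2D wins
        ("P19", "ICD10", "E11.9", "2010-01-01"),
        ("P19", "ICD10", "I50.0", "2020-12-31"),     # late event
        ("P20", "ICD10", "E11.9", "2010-01-01"),
        ("P20", "ICD10", "I21.9", "2010-01-02"),     # event on death day
    ]
    episodes = pd.DataFrame(rows, columns=["person_id", "system", "code",
                                           "date"])
    deaths = pd.DataFrame({
        "person_id": ["P04", "P09", "P15", "P20"],
        "death_date": ["2018-06-01", "2014-01-01", "2021-06-01",
                       "2010-01-02"],
    })
    deaths["death_date"] = pd.to_datetime(deaths["death_date"])
    persons = sorted({r[0] for r in rows})
    covariates = pd.DataFrame({
        "person_id": persons,
        "birth_date": pd.Timestamp("1950-01-01"),
        "sex": 1.0,
    })
    # expected per person: (event, follow_up_days) or None if excluded
    expected = {
        "P01": (1, 1),
        "P02": None,
        "P03": None,
        "P04": (0, days("2015-06-01", "2018-06-01")),
        "P05": (0, days("2010-01-01", CENSOR)),
        "P06": (0, days("2020-01-01", CENSOR)),
        "P07": (1, days("2010-06-01", "2010-07-01")),
        "P08": None,
        "P09": (0, days("2010-01-01", "2014-01-01")),
        "P10": (1, 30),
        "P11": (1, 31),
        "P12": (1, days("2012-03-04", "2013-03-04")),
        "P13": (1, days("2010-01-01", "2011-01-01")),
        "P14": None,
        "P15": (0, days("2010-01-01", CENSOR)),
        "P16": None,
        "P17": (0, days("2010-01-01", CENSOR)),
        "P18": (0, days("2010-05-05", CENSOR)),
        "P19": (1, days("2010-01-01", "2020-12-31")),
        "P20": (1, 1),
    }
    return episodes, deaths, covariates, expected


@pytest.fixture(scope="session")
def small_bundle():
    """A 1500-person, 150-variant synthetic study shared across tests."""
    cfg = SimConfig(n_individuals=1500, n_variants=150, seed=42)
    return simulate_study(cfg)


# ---------------------------------------------------------------------------
# Independent oracles (used only by tests; deliberately simple code paths)


def oracle_breslow_loglik(beta, times, events, X):
    """Breslow partial log-likelihood written out with explicit risk-set
    loops, independent of the package's cumulative-sum implementation."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    ll = 0.0
    for i in range(len(times)):
        if events[i]:
            risk = np.flatnonzero(times >= times[i])
            eta = X[risk] @ beta
            ll += float(X[i] @ beta) - float(np.log(np.exp(eta).sum()))
    return ll


def oracle_auc_paircount(scores, labels):
    """AUC by exhaustive case/control pair counting (ties = 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    wins = 0.0
    for c in cases:
        for u in controls:
            if c > u:
                wins += 1.0
            elif c == u:
                wins += 0.5
    return wins / (len(cases) * len(controls))
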