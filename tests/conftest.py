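import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from vancodose.cohort import SPLITS, apply_exclusions, split_by_patient
from vancodose.features import build_matrix
from vancodose.synthetic_data import SimParams, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient defect-free simulated cohort (tables + hidden truth)."""
    return simulate_cohort(SimParams(n_patients=60, seed=7))


@pytest.fixture(scope="session")
def labeled_small(small_cohort):
    tables, _ = small_cohort
    records, report = apply_exclusions(
        tables["injections"], tables["troughs"], tables["demographics"]
    )
    return records, report


@pytest.fixture(scope="session")
def subsequent_matrices(small_cohort, labeled_small):
    """Train/validation/test subsequent-mode matrices, patient-disjoint."""
    tables, _ = small_cohort
    records, _ = labeled_small
    split = split_by_patient([r.patient_id for r in records], seed=7)
    sub = [r for r in records if not r.is_initial]
    return {
        part: build_matrix(
            [r for r in sub if split[r.patient_id] == part], tables,
            "subsequent", history_records=records,
        )
        for part in SPLITS
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_injection(pid, hours, dose, t0=pd.Timestamp("2019-01-01 08:00")):
    from vancodose.records_io import InjectionEvent

    return InjectionEvent(pid, t0 + pd.Timedelta(hours=float(hours)), dose)


def make_trough(pid, hours, conc, t0=pd.Timestamp("2019-01-01 08:00")):
    from vancodose.records_io import TroughMeasurement

    return TroughMeasurement(pid, t0 + pd.Timedelta(hours=float(hours)), conc)
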