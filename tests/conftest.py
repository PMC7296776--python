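import datetime

import pytest

from crval.cohort import Event, PatientRecord, Treatment
from crval.engine import default_coefficients
from crval.synthetic import make_benchmark_cohort


def make_record(pid="p1", **kwargs):
    """A clean, filter-passing record with overridable fields."""
    base = dict(
        patient_id=pid,
        age_dx=65.0,
        psa=8.0,
        t_stage="T1",
        grade_group=1,
        ppc=0.2,
        treatment=Treatment.CONSERVATIVE,
        comorbid=False,
        metastatic=False,
        dx_date=datetime.date(2005, 6, 1),
        followup_years=10.0,
        event=Event.CENSORED,
    )
    base.update(kwargs)
    return PatientRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def default_coefs():
    return default_coefficients()


@pytest.fixture(scope="session")
def bench_cohort():
    """Small benchmark cohort shared across tests (deterministic)."""
    cohort, truth = make_benchmark_cohort(n=3000, seed=42)
    return cohort, truth
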