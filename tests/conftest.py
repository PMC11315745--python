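import pytest

from vtecost.cohort import PatientRecord, default_cohort_spec, generate_cohort

_DEFAULT_PATHWAY = {"PE": "CTPA", "DVT": "CUS", "none": "CTPA"}


def make_patient(
    age: int,
    d_dimer: float,
    status: str = "none",
    pathway: str | None = None,
    pid: str = "P0001",
    pretest: str = "low",
) -> PatientRecord:
    return PatientRecord(
        pid, age, d_dimer, status, pathway or _DEFAULT_PATHWAY[status], pretest
    )


def make_cohort(cases: list[float], controls: list[float], age: int = 60):
    """Toy cohort from case/control score lists (all DVT/CUS-agnostic)."""
    cohort = []
    for i, d in enumerate(cases):
        cohort.append(make_patient(age, d, "PE", pid=f"C{i:03d}"))
    for i, d in enumerate(controls):
        cohort.append(make_patient(age, d, "none", pid=f"N{i:03d}"))
    return cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded cohort from the shipped reference spec, shared across tests."""
    return generate_cohort(default_cohort_spec(seed=42))


@pytest.fixture(scope="session")
def default_spec():
    return default_cohort_spec(seed=42)
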