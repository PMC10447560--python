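import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cogtraj import Cohort, GeneratorParams, Participant, generate_cohort


@pytest.fixture(scope="session")
def kindred_counts_cohort():
    """Cohort with exactly the kindred's published genotype counts."""
    from cogtraj import cohort_from_genotype_counts

    return cohort_from_genotype_counts()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but analysis-capable synthetic cohort (fixed seed)."""
    cohort, truth = generate_cohort(
        GeneratorParams(n_carriers=250, n_noncarriers=180, seed=7)
    )
    return cohort, truth


def make_participant(**kw) -> Participant:
    defaults = dict(
        id="P1",
        age=40.0,
        sex="F",
        education_years=8.0,
        mmse=28,
        psen1_carrier=True,
        apoe_allele_1="e3",
        apoe_allele_2="e3",
    )
    defaults.update(kw)
    return Participant(**defaults)


@pytest.fixture
def tiny_cohort():
    return Cohort(
        (
            make_participant(id="A", age=30, mmse=30, apoe_allele_1="e3"),
            make_participant(id="B", age=45, mmse=22, apoe_allele_1="e4"),
            make_participant(
                id="C", age=60, mmse=10, psen1_carrier=False, apoe_allele_1="e2"
            ),
        )
    )
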