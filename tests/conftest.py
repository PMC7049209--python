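import hypothesis
import pytest

from mia_score import (
    Aneurysm,
    Cohort,
    GeneratorConfig,
    Location,
    Patient,
    Shape,
    sample_cohort,
    table2_fixture,
)

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture(scope="session")
def prospective():
    """The packaged 34-patient / 83-aneurysm prospective cohort."""
    return table2_fixture()


@pytest.fixture(scope="session")
def prospective_with_reference():
    return table2_fixture(with_reference=True)


def make_patient(pid, specs, **covs):
    """Tiny cohort-building helper: specs = [(size, location, shape, ruptured), ...]."""
    covs.setdefault("age_years", 55.0)
    covs.setdefault("smoker", False)
    covs.setdefault("hypertension", True)
    return Patient(
        patient_id=pid,
        aneurysms=tuple(
            Aneurysm(
                aneurysm_id=f"{pid}-a{i}",
                patient_id=pid,
                size_mm=s,
                location=loc,
                shape=shape,
                ruptured=rupt,
            )
            for i, (s, loc, shape, rupt) in enumerate(specs, 1)
        ),
        **covs,
    )


@pytest.fixture
def two_aneurysm_patient():
    return make_patient(
        "p1",
        [
            (5.0, Location.ACOM_AA, Shape.IRREGULAR, True),
            (13.0, Location.MCA, Shape.REGULAR, False),
        ],
    )


@pytest.fixture(scope="session")
def small_signal_cohort():
    """Strong-signal synthetic cohort reused by slower model tests."""
    return sample_cohort(GeneratorConfig(n_patients=120, seed=42, signal_scale=4.0))
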