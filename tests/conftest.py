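import pytest

from co2gap import CohortConfig, GasPanel, PairedSample, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest full-longitudinal cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(n=60, seed=123))


@pytest.fixture()
def paired_sample():
    """A physiologically typical arterial/venous pair."""
    arterial = GasPanel(
        ph=7.40, pco2=40.0, po2=100.0, so2=0.98, hb=12.0, temp=37.0, lactate=1.5
    )
    venous = GasPanel(ph=7.37, pco2=46.0, po2=40.0, so2=0.69, hb=12.0, temp=37.0)
    return PairedSample(
        patient_id="P1", timepoint="H0", arterial=arterial, venous=venous
    )
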