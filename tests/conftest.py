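import pytest

from metamr.study_data import EffectEstimate, GenotypeCounts, StudyRecord
from metamr.synthetic_data import paper27_config, simulate_studies


@pytest.fixture
def example_counts():
    """Cases (CC=10, CT=20, TT=10) vs controls (CC=20, CT=20, TT=10)."""
    return GenotypeCounts(10, 20, 10), GenotypeCounts(20, 20, 10)


@pytest.fixture
def two_effects():
    return [
        EffectEstimate("a", "allele", 0.0, 1.0),
        EffectEstimate("b", "allele", 1.0, 1.0),
    ]


@pytest.fixture(scope="session")
def paper27_studies():
    """The shipped 27-study fixture (7 HWE-violating), seed 0."""
    return simulate_studies(paper27_config(seed=0))


def make_study(study_id="s1", ethnicity="Asian", control_source="hospital",
               cases=(10, 20, 10), controls=(20, 20, 10), year=2010):
    return StudyRecord(
        study_id=study_id,
        year=year,
        ethnicity=ethnicity,
        control_source=control_source,
        cases=GenotypeCounts(*cases),
        controls=GenotypeCounts(*controls),
    )
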