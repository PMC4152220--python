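import numpy as np
import pytest

from traumatriage import CohortSpec, generate_cohort, impose_missingness
from traumatriage.imputation import ImputedStack


@pytest.fixture(scope="session")
def complete_cohort_4k():
    """Complete synthetic cohort, default study conditions, n=4000."""
    return generate_cohort(CohortSpec(n=4000, seed=101))


@pytest.fixture(scope="session")
def masked_cohort_4k():
    spec = CohortSpec(n=4000, seed=101)
    return impose_missingness(generate_cohort(spec), spec)


@pytest.fixture(scope="session")
def complete_cohort_10k():
    return generate_cohort(CohortSpec(n=10000, seed=202))


@pytest.fixture(scope="session")
def stack_10k(complete_cohort_10k):
    return ImputedStack.from_complete(complete_cohort_10k)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_csv(tmp_path):
    """Three-row canonical cohort CSV with one empty SBP cell."""
    text = (
        "hospital_id,age,sex,tti_hours,transferred,mechanism,sbp,hr,gcs,"
        "died_24h,discharged_early\n"
        "a,35,male,4.5,true,road_traffic,120,88,15,false,false\n"
        "a,52,female,12,false,fall,,95,12,true,false\n"
        "b,19,male,1.0,true,assault,90,110,8,false,true\n"
    )
    path = tmp_path / "cohort.csv"
    path.write_text(text)
    return path
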