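import pytest

from renalcocktail import default_design, default_truth, generate_cohort, simulate_study
from renalcocktail.pipeline import run_study_analysis


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def noisefree_dataset(design, truth):
    """Six pigs, zero noise, zero variability, no leakage: the analytic world."""
    cohort = generate_cohort(6, seed=101)
    return simulate_study(cohort, design=design, truth=truth, noise_cv=0.0,
                          between_animal_cv=0.0, leakage_prob=0.0, seed=202)


@pytest.fixture(scope="session")
def noisefree_results(noisefree_dataset):
    return run_study_analysis(noisefree_dataset)
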