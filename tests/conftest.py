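import numpy as np
import pytest

from dapaer import (CohortSpec, FitOptions, StructuralParameters,
                    fit_sequential, generate_cohort)


@pytest.fixture(scope="session")
def params():
    return StructuralParameters()


@pytest.fixture(scope="session")
def small_cohort():
    """Phase-3-shaped cohort, 60 subjects/arm, at the default truth."""
    spec = CohortSpec(arm_sizes={"placebo": 60, "5mg": 60, "10mg": 60})
    table, truth = generate_cohort(spec, seed=1234)
    return table, truth


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    table, _ = small_cohort
    return table, fit_sequential(
        table, FitOptions(seed=0, n_starts=1, compute_se=False))


@pytest.fixture(scope="session")
def phase3_fit():
    """Full-size (810-subject) cohort and fit; parameters well identified."""
    table, truth = generate_cohort(CohortSpec(), seed=555)
    fit = fit_sequential(table, FitOptions(seed=0, n_starts=1,
                                           compute_se=False))
    return table, truth, fit


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
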