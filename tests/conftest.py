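import warnings

import pytest

from thermnorm.models import TEST_MCMC, ModelSpec, fit_mixed
from thermnorm.pipeline import build_trait_table, metabolic_estimates_from_study
from thermnorm.simulate import SimulationConfig, simulate_study

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def paper_scale_study():
    """One default-condition synthetic study (73 fish x 5 temperatures)."""
    return simulate_study(SimulationConfig(seed=5))


@pytest.fixture(scope="session")
def paper_scale_table(paper_scale_study):
    """Trait table built from the trial-level truth of the default study."""
    est = metabolic_estimates_from_study(paper_scale_study, trace_level=False)
    table, _ = build_trait_table(
        paper_scale_study, est, include_feeding=True
    )
    return table


@pytest.fixture(scope="session")
def smr_slopes_fit(paper_scale_table):
    """A shared random-slopes Gaussian fit of SMR at the test MCMC profile."""
    spec = ModelSpec(
        traits=("smr",),
        families=("gaussian",),
        random_structure="slopes",
        mcmc=TEST_MCMC,
        seed=11,
    )
    return fit_mixed(paper_scale_table, spec)


@pytest.fixture(scope="session")
def smr_intercepts_fit(paper_scale_table):
    spec = ModelSpec(
        traits=("smr",),
        families=("gaussian",),
        random_structure="intercepts",
        mcmc=TEST_MCMC,
        seed=11,
    )
    return fit_mixed(paper_scale_table, spec)
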