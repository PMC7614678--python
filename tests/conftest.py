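import pytest

from cpssd import (
    CommensuratePriorSpec,
    CriterionSpec,
    HistoricalSummary,
    collective_prior,
    get_scenario,
)


@pytest.fixture(scope="session")
def default_spec():
    """Gamma(2,2)/Gamma(18,3) mixture with s0 = 0.05."""
    return CommensuratePriorSpec()


@pytest.fixture(scope="session")
def expert_sources():
    """Five elicited normal summaries of a log-odds ratio with their weights."""
    return list(get_scenario("experts").sources)


@pytest.fixture(scope="session")
def expert_prior(expert_sources, default_spec):
    """The collective prior N(-0.309, 0.154) from the five expert summaries."""
    return collective_prior(expert_sources, default_spec)


@pytest.fixture(scope="session")
def acc_spec():
    return CriterionSpec("acc", hpd_length=0.65, coverage=0.95)


@pytest.fixture(scope="session")
def alc_spec():
    return CriterionSpec("alc", hpd_length=0.65, coverage=0.95)


@pytest.fixture(scope="session")
def apvc_spec():
    return CriterionSpec("apvc", variance_target=0.03)


def make_summary(mean=0.0, variance=1.0, weight=0.5, label=""):
    return HistoricalSummary(mean=mean, variance=variance, weight=weight, label=label)
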