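import pytest

from rnadecay import (compute_normalization_factors, default_included_ids,
                      make_fixture)


@pytest.fixture(scope="session")
def tiny_fixture():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def noiseless_fixture():
    return make_fixture("noiseless")


@pytest.fixture(scope="session")
def default_fixture():
    return make_fixture("default")


@pytest.fixture(scope="session")
def terminator_fixture():
    return make_fixture("terminator")


@pytest.fixture(scope="session")
def operon_fixture():
    return make_fixture("operon")


def normalized_pipeline(fx):
    """Spike-in factors + decay fit for a simulated fixture."""
    from rnadecay import DecayModel

    factors = compute_normalization_factors(
        fx.counts, fx.manifest, default_included_ids(fx.manifest))
    results = DecayModel.from_counts(fx.counts, factors).fit()
    return factors, results


@pytest.fixture(scope="session")
def default_results(default_fixture):
    return normalized_pipeline(default_fixture)


@pytest.fixture(scope="session")
def noiseless_results(noiseless_fixture):
    return normalized_pipeline(noiseless_fixture)
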