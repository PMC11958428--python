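import warnings

import pytest

from tpredictive import (EvidenceBound, Prior, TestLayout, find_critical_region,
                         parse_prior)


@pytest.fixture(scope="session")
def cauchy_default():
    """The default analysis prior of the Bayesian t test."""
    return Prior("scaled_t", 0.0, 0.707, 1.0)


@pytest.fixture(scope="session")
def one_sample_151():
    return TestLayout.one_sample(151)


@pytest.fixture(scope="session")
def bound10():
    return EvidenceBound(10.0)


@pytest.fixture(scope="session")
def worked_example_region(one_sample_151, cauchy_default, bound10):
    """Critical region of the one-sample N=151 / Cauchy(0, 0.707) / b=10
    design, shared across tests (it is expensive to compute)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return find_critical_region(one_sample_151, cauchy_default, bound10)


@pytest.fixture(scope="session")
def allen_priors():
    """One-sided priors of the structural-awareness training example:
    point design prior at delta = 0.64, default Cauchy analysis prior."""
    analysis = parse_prior("cauchy(0,0.707)", side="positive")
    design = parse_prior("point(0.64)", side="positive")
    return analysis, design
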