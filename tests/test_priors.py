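import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tpredictive import Prior, PriorError, parse_prior

ALL_CONTINUOUS = [
    Prior("scaled_t", 0.0, 0.707, 1.0),
    Prior("scaled_t", 0.64, 0.707, 3.0),
    Prior("normal", 0.0, 1.0),
    Prior("normal", 0.3, 0.5),
    Prior("normal_moment", 0.0, 0.45),
    Prior("normal_moment", 0.2, 0.6),
]


class TestDensity:
    def test_standard_cauchy_at_zero(self):
        p = Prior("scaled_t", 0.0, 1.0, 1.0)
        assert p.pdf(0.0) == pytest.approx(1.0 / math.pi, rel=1e-12)

    def test_normal_moment_vanishes_at_location(self):
        p = Prior("normal_moment", 0.0, 0.45)
        assert p.pdf(0.0) == 0.0
        # modes at +- sqrt(2) tau
        tau = 0.45
        grid = np.linspace(-3, 3, 2001)
        mode = grid[np.argmax(p.pdf(grid))]
        assert abs(mode) == pytest.approx(math.sqrt(2) * tau, abs=0.01)

    def test_one_sided_doubles_symmetric_density(self):
        two = Prior("scaled_t", 0.0, 0.707, 1.0)
        pos = Prior("scaled_t", 0.0, 0.707, 1.0, side="positive")
        assert pos.pdf(0.5) == pytest.approx(2.0 * two.pdf(0.5), rel=1e-12)
        assert pos.pdf(-0.5) == 0.0

    @pytest.mark.parametrize("prior", ALL_CONTINUOUS, ids=str)
    @pytest.mark.parametrize("side", ["two_sided", "positive", "negative"])
    def test_normalizes_to_one(self, prior, side):
        p = Prior(prior.family, prior.location, prior.scale, prior.df, side=side)
        total = p.expect(lambda d: np.ones_like(d))
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_point_prior_has_no_density(self):
        with pytest.raises(PriorError):
            Prior("point", 0.64).logpdf(0.5)

    def test_scaled_t_limits_to_normal(self):
        t_prior = Prior("scaled_t", 0.2, 0.8, 1e6)
        n_prior = Prior("normal", 0.2, 0.8)
        grid = np.linspace(-4, 4, 41)
        assert np.max(np.abs(t_prior.pdf(grid) - n_prior.pdf(grid))) < 1e-4


class TestValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(family="banana", location=0.0, scale=1.0),
        dict(family="scaled_t", location=0.0, scale=-1.0, df=1.0),
        dict(family="scaled_t", location=0.0, scale=1.0, df=0.0),
        dict(family="scaled_t", location=0.0, scale=1.0),     # missing df
        dict(family="normal", location=0.0, scale=1.0, df=3.0),
        dict(family="normal", location=0.0, scale=None),
        dict(family="point", location=0.0, scale=1.0),
        dict(family="normal", location=0.0, scale=1.0, side="up"),
        dict(family="normal", location=math.nan, scale=1.0),
    ])
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(PriorError):
            Prior(**kwargs)


class TestSampling:
    def test_point_prior_returns_constant(self):
        assert np.all(Prior("point", 0.64).sample(5, 0) == 0.64)

    def test_seed_reproducibility(self):
        p = Prior("normal_moment", 0.0, 0.45, side="positive")
        assert np.array_equal(p.sample(100, 7), p.sample(100, 7))

    def test_normal_sample_mean_clt_bound(self):
        n = 100_000
        draws = Prior("normal", 0.0, 1.0).sample(n, 11)
        assert abs(draws.mean()) < 4.0 / math.sqrt(n)

    def test_half_cauchy_median_is_scale(self):
        n = 100_000
        p = Prior("scaled_t", 0.0, 0.707, 1.0, side="positive")
        draws = p.sample(n, 3)
        assert np.all(draws > 0)
        # half-Cauchy median equals the scale; MC error of a quantile
        assert np.median(draws) == pytest.approx(0.707, abs=0.02)

    @pytest.mark.parametrize("prior", [
        Prior("scaled_t", 0.0, 0.707, 1.0, side="positive"),
        Prior("normal", 0.3, 0.5),
        Prior("normal_moment", 0.0, 0.45),
    ], ids=str)
    def test_empirical_cdf_matches_analytic(self, prior):
        n = 100_000
        draws = np.sort(prior.sample(n, 19))
        ecdf = (np.arange(n) + 0.5) / n
        ks = np.max(np.abs(prior.cdf(draws) - ecdf))
        assert ks < 4.0 / math.sqrt(n)


class TestParse:
    @pytest.mark.parametrize("text,expected", [
        ("cauchy(0,0.707)", Prior("scaled_t", 0.0, 0.707, 1.0)),
        ("t(0.64, 0.707, 3)", Prior("scaled_t", 0.64, 0.707, 3.0)),
        ("normal(0, 1)", Prior("normal", 0.0, 1.0)),
        ("nlp(0, 0.45)", Prior("normal_moment", 0.0, 0.45)),
        ("point(0.64)", Prior("point", 0.64)),
    ])
    def test_grammar(self, text, expected):
        assert parse_prior(text) == expected

    def test_side_flag(self):
        p = parse_prior("cauchy(0,0.707)", side="positive")
        assert p.side == "positive"

    @pytest.mark.parametrize("bad", ["cauchy", "cauchy(0)", "gaussian(0,1)",
                                     "t(0,1)", "point(0,1)", "normal(a,b)"])
    def test_bad_specs_raise(self, bad):
        with pytest.raises(PriorError):
            parse_prior(bad)


@settings(max_examples=30, deadline=None)
@given(
    family=st.sampled_from(["scaled_t", "normal", "normal_moment"]),
    location=st.floats(-2, 2),
    scale=st.floats(0.1, 3),
    side=st.sampled_from(["two_sided", "positive", "negative"]),
    q=st.floats(0.01, 0.99),
)
def test_cdf_quantile_roundtrip(family, location, scale, side, q):
    """cdf(ppf(q)) == q on the truncated prior, for random valid priors."""
    from hypothesis import assume
    df = 2.5 if family == "scaled_t" else None
    try:
        prior = Prior(family, location, scale, df, side=side)
    except PriorError:
        assume(False)  # truncation left essentially no mass
    # inverse-CDF through the sampling transform
    mass = prior._retained_mass()
    if side == "positive":
        x = prior._base_ppf(np.asarray(prior._base_cdf(0.0) + q * mass))
    elif side == "negative":
        x = prior._base_ppf(np.asarray(q * mass))
    else:
        x = prior._base_ppf(np.asarray(q))
    assert prior.cdf(float(x)) == pytest.approx(q, abs=1e-6)
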