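import math
import warnings

import numpy as np
import pytest
from scipy import stats

from tpredictive import (EvidenceBound, Prior, TestLayout, evidence_probabilities,
                         find_critical_region, log_bf10, power_curve,
                         required_sample_size, tpe_normal_approximation)
from tpredictive.bayes_factor import MarginalMixture


class TestEvidenceBound:
    @pytest.mark.parametrize("b", [1.0, 0.5, -2.0, math.nan])
    def test_bound_must_exceed_one(self, b):
        with pytest.raises(ValueError):
            EvidenceBound(b)


class TestCriticalRegion:
    def test_point_null_analysis_prior_nothing_achievable(self, one_sample_151, bound10):
        cr = find_critical_region(one_sample_151, Prior("point", 0.0), bound10)
        assert not cr.achievable_h1 and not cr.achievable_h0
        assert cr.region_h1.is_empty and cr.region_h0.is_empty

    def test_tiny_sample_cannot_support_null(self, cauchy_default, bound10):
        """At N=5 the Bayes factor in favour of the null never reaches 10;
        a grid maximization of -ln BF10 confirms the ceiling."""
        layout = TestLayout.one_sample(5)
        cr = find_critical_region(layout, cauchy_default, bound10)
        assert not cr.achievable_h0
        assert cr.achievable_h1
        grid = np.linspace(-30, 30, 2001)
        lnbf = MarginalMixture(layout, cauchy_default).log_bf10(grid)
        assert np.max(-lnbf) < math.log(10)

    def test_boundaries_satisfy_bf_identity(self, worked_example_region,
                                            one_sample_151, cauchy_default, bound10):
        """exp(ln BF10) equals b (or 1/b) at every reported boundary."""
        for t_star in worked_example_region.region_h1.boundaries:
            bf = math.exp(log_bf10(t_star, one_sample_151, cauchy_default))
            assert abs(bf - bound10.b) / bound10.b <= 1e-5
        for t_star in worked_example_region.region_h0.boundaries:
            bf01 = math.exp(-log_bf10(t_star, one_sample_151, cauchy_default))
            assert abs(bf01 - bound10.b) / bound10.b <= 1e-5

    def test_regions_disjoint(self, worked_example_region):
        t = np.linspace(-6, 6, 1001)
        h1 = worked_example_region.region_h1.contains(t)
        h0 = worked_example_region.region_h0.contains(t)
        assert not np.any(h1 & h0)


class TestEvidenceProbabilities:
    def test_rows_sum_to_one(self, one_sample_151, cauchy_default, bound10):
        p = evidence_probabilities(one_sample_151, cauchy_default, cauchy_default, bound10)
        assert p.tpe + p.fne + p.inconclusive_h1 == pytest.approx(1.0, abs=1e-8)
        assert p.tne + p.fpe + p.inconclusive_h0 == pytest.approx(1.0, abs=1e-8)

    def test_point_null_design_prior_forces_tpe_equal_fpe(self, one_sample_151,
                                                          cauchy_default, bound10):
        p = evidence_probabilities(one_sample_151, cauchy_default,
                                   Prior("point", 0.0), bound10)
        assert p.tpe == p.fpe
        assert p.tne == p.fne

    def test_raising_bound_lowers_tpe_and_fpe(self, allen_priors):
        analysis, design = allen_priors
        layout = TestLayout.independent(51, 51)
        p3 = evidence_probabilities(layout, analysis, design, EvidenceBound(3))
        p10 = evidence_probabilities(layout, analysis, design, EvidenceBound(10))
        assert p10.tpe < p3.tpe
        assert p10.fpe < p3.fpe

    def test_scaled_t_with_huge_df_matches_normal_prior(self, bound10):
        layout = TestLayout.independent(60, 60)
        t_prior = Prior("scaled_t", 0.0, 1.0, 1e6)
        n_prior = Prior("normal", 0.0, 1.0)
        pt = evidence_probabilities(layout, t_prior, t_prior, bound10)
        pn = evidence_probabilities(layout, n_prior, n_prior, bound10)
        for key in ("tpe", "fpe", "tne", "fne"):
            assert getattr(pt, key) == pytest.approx(getattr(pn, key), abs=1e-3)


class TestSampleSize:
    def test_minimality_in_allen_scenario(self, allen_priors):
        analysis, design = allen_priors
        b = EvidenceBound(3)
        res = required_sample_size(0.8, "independent", analysis, design, b)
        assert res.attainable
        assert res.achieved.tpe >= 0.8
        below = evidence_probabilities(TestLayout.independent(res.n - 1, res.n - 1),
                                       analysis, design, b)
        assert below.tpe < 0.8

    def test_unattainable_below_cap(self, allen_priors):
        analysis, design = allen_priors
        res = required_sample_size(0.8, "independent", analysis, design,
                                   EvidenceBound(3), n_max=20)
        assert not res.attainable
        assert res.n == 20
        assert res.notes

    def test_allocation_ratio_sets_second_group(self, allen_priors):
        analysis, design = allen_priors
        res = required_sample_size(0.8, "independent", analysis, design,
                                   EvidenceBound(3), allocation_ratio=2.0)
        assert res.n2 == math.ceil(2.0 * res.n)
        # the unbalanced design needs fewer group-1 subjects than balanced
        balanced = required_sample_size(0.8, "independent", analysis, design,
                                        EvidenceBound(3))
        assert res.n < balanced.n

    def test_rejects_bad_arguments(self, cauchy_default):
        with pytest.raises(ValueError):
            required_sample_size(1.2, "one_sample", cauchy_default, cauchy_default,
                                 EvidenceBound(10))
        with pytest.raises(ValueError):
            required_sample_size(0.8, "paired", cauchy_default, cauchy_default,
                                 EvidenceBound(10))


class TestPowerCurve:
    def test_single_point_matches_direct_evaluation(self, allen_priors):
        analysis, design = allen_priors
        b = EvidenceBound(3)
        table = power_curve([51], "independent", analysis, design, b)
        direct = evidence_probabilities(TestLayout.independent(51, 51),
                                        analysis, design, b)
        assert table.loc[0, "tpe"] == pytest.approx(direct.tpe, abs=1e-12)
        assert table.loc[0, "n2"] == 51

    def test_tpe_nondecreasing_in_n(self):
        analysis = Prior("scaled_t", 0.0, 0.707, 3.0)
        design = Prior("normal", 0.0, 1.0)
        table = power_curve([6, 10, 14, 18], "independent", analysis, design,
                            EvidenceBound(10))
        assert np.all(np.diff(table["tpe"].to_numpy()) > 0)

    def test_empty_grid_rejected(self, cauchy_default):
        with pytest.raises(ValueError):
            power_curve([], "one_sample", cauchy_default, cauchy_default,
                        EvidenceBound(10))


class TestNormalApproximation:
    def test_degenerate_point_design_at_null(self, bound10):
        """With a point design prior at 0 the approximating law is standard
        normal, so TPE is the standard-normal mass of the critical region."""
        layout = TestLayout.independent(20, 20)
        analysis = Prior("scaled_t", 0.0, 0.707, 3.0)
        design = Prior("point", 0.0)
        region = find_critical_region(layout, analysis, bound10).region_h1
        expected = sum(stats.norm.sf(lo) if not np.isfinite(hi) else
                       stats.norm.cdf(hi) - stats.norm.cdf(lo)
                       for lo, hi in region.intervals)
        got = tpe_normal_approximation(layout, design, analysis, bound10)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_rejects_unsupported_design_prior(self, bound10):
        layout = TestLayout.independent(20, 20)
        analysis = Prior("scaled_t", 0.0, 0.707, 3.0)
        with pytest.raises(ValueError):
            tpe_normal_approximation(layout, Prior("scaled_t", 0.0, 1.0, 1.0),
                                     analysis, bound10)
        with pytest.raises(ValueError):
            tpe_normal_approximation(layout, Prior("normal", 0.0, 1.0, side="positive"),
                                     analysis, bound10)

    def test_converges_to_exact_at_large_n(self, bound10):
        layout = TestLayout.independent(1000, 1000)
        analysis = Prior("scaled_t", 0.0, 0.707, 3.0)
        design = Prior("normal", 0.0, 1.0)
        exact = evidence_probabilities(layout, analysis, design, bound10).tpe
        approx = tpe_normal_approximation(layout, design, analysis, bound10)
        assert abs(exact - approx) <= 0.005
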