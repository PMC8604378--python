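import math

import numpy as np
import pytest
from scipy import stats

from combimeta import (
    DomainError,
    HeterogeneityPrior,
    StudyEffect,
    bayes_pool,
    mu_posterior,
    predictive_distribution,
    sensitivity_analysis,
    shrinkage_intervals,
    tau_marginal_posterior,
)

from _oracles import nnhm_bruteforce, shrinkage_bruteforce

HN05 = HeterogeneityPrior("half_normal", 0.5)


class TestPrior:
    def test_validation(self):
        with pytest.raises(ValueError, match="family"):
            HeterogeneityPrior("normal", 0.5)
        with pytest.raises(ValueError, match="scale"):
            HeterogeneityPrior("half_normal", 0.0)

    def test_parse(self):
        p = HeterogeneityPrior.parse("half_cauchy:0.5")
        assert p.family == "half_cauchy" and p.scale == 0.5
        with pytest.raises(ValueError, match="malformed"):
            HeterogeneityPrior.parse("half_cauchy=0.5")
        with pytest.raises(ValueError, match="not a number"):
            HeterogeneityPrior.parse("half_cauchy:x")

    def test_half_cauchy_density_at_origin(self):
        # closed form: 2 / (pi * scale)
        assert HeterogeneityPrior("half_cauchy", 0.5).pdf(0.0) == pytest.approx(
            2.0 / (math.pi * 0.5)
        )


class TestTauPosterior:
    def test_single_study_posterior_equals_prior(self):
        # one study is uninformative about tau: the marginal likelihood is flat
        post = tau_marginal_posterior([StudyEffect(study_label="s", y=1.0, sigma=0.5)], HN05)
        prior = stats.halfnorm(scale=0.5)
        assert post.median() == pytest.approx(prior.median(), abs=1e-4)
        for q in (0.1, 0.25, 0.75, 0.9):
            assert post.ppf(q) == pytest.approx(prior.ppf(q), abs=1e-4)
        assert post.weights.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(post.weights >= 0)

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            tau_marginal_posterior([], HN05)

    def test_grid_refinement_stability(self, diabetes):
        coarse = bayes_pool(diabetes, HN05, n_grid=2001)
        fine = bayes_pool(diabetes, HN05, n_grid=4001)
        for attr in ("mu_median", "tau_median", "predictive_median"):
            assert getattr(coarse, attr) == pytest.approx(getattr(fine, attr), abs=1e-4)
        for attr in ("mu_cri", "tau_cri", "predictive_cri"):
            assert getattr(coarse, attr) == pytest.approx(getattr(fine, attr), abs=1e-4)


class TestDegenerateLimits:
    """A near point-mass prior at tau = 0 recovers the fixed-effect conjugate case."""

    def test_mu_posterior_collapses_to_fixed_effect_normal(self, make_studies):
        studies = make_studies([0.8, 1.9, 0.3], [0.25, 0.49, 0.16])
        tiny = HeterogeneityPrior("half_normal", 1e-4)
        mix = mu_posterior(studies, tiny)
        w = 1 / np.array([0.25, 0.49, 0.16])
        mu_fe = (w * np.array([0.8, 1.9, 0.3])).sum() / w.sum()
        se_fe = 1 / math.sqrt(w.sum())
        assert mix.median() == pytest.approx(mu_fe, abs=1e-5)
        assert mix.ppf(0.975) == pytest.approx(mu_fe + 1.959964 * se_fe, abs=1e-4)

    def test_predictive_equals_mu_posterior_without_heterogeneity(self, make_studies):
        studies = make_studies([0.8, 1.9, 0.3], [0.25, 0.49, 0.16])
        tiny = HeterogeneityPrior("half_normal", 1e-4)
        mu = mu_posterior(studies, tiny)
        pred = predictive_distribution(studies, tiny)
        assert pred.median() == pytest.approx(mu.median(), abs=1e-5)
        assert pred.hdi() == pytest.approx(mu.hdi(), abs=1e-4)

    def test_shrinkage_equals_mu_posterior_without_heterogeneity(self, make_studies):
        studies = make_studies([0.8, 1.9, 0.3], [0.25, 0.49, 0.16])
        tiny = HeterogeneityPrior("half_normal", 1e-4)
        mu = mu_posterior(studies, tiny)
        for s in shrinkage_intervals(studies, tiny):
            assert s.median == pytest.approx(mu.median(), abs=1e-4)
            assert s.interval == pytest.approx(mu.hdi(), abs=1e-3)


class TestAgainstBruteForce:
    def test_quadrature_matches_2d_grid_integration(self, make_studies):
        rng = np.random.default_rng(11)
        for _ in range(3):
            k = int(rng.integers(2, 5))
            y = rng.normal(1.0, 1.0, k)
            v = rng.uniform(0.05, 2.0, k)
            res = bayes_pool(make_studies(y, v), HN05)
            oracle = nnhm_bruteforce(y, v, family="half_normal", scale=0.5)
            assert res.mu_median == pytest.approx(oracle["mu"].median(), abs=1e-3)
            assert res.mu_cri == pytest.approx(oracle["mu"].hdi(), abs=1e-3)
            assert res.tau_median == pytest.approx(oracle["tau"].median(), abs=1e-3)
            assert res.tau_cri == pytest.approx(
                oracle["tau"].hdi(bounded_below=True), abs=1e-3
            )
            assert res.predictive_median == pytest.approx(
                oracle["predictive"].median(), abs=1e-3
            )

    def test_shrinkage_matches_2d_quadrature(self, make_studies, diabetes):
        y = [0.9, 1.8, 0.1]
        v = [0.3, 0.8, 0.2]
        shrink = shrinkage_intervals(make_studies(y, v), HN05)
        for i in range(3):
            oracle = shrinkage_bruteforce(y, v, i)
            assert shrink[i].median == pytest.approx(oracle.median(), abs=1e-3)
            assert shrink[i].interval == pytest.approx(oracle.hdi(), abs=2e-3)
        # and one study of the reference data
        oracle = shrinkage_bruteforce(diabetes.y, diabetes.variances, 0)
        shrink = shrinkage_intervals(diabetes, HN05)
        assert shrink[0].median == pytest.approx(oracle.median(), abs=1e-3)
        assert shrink[0].interval == pytest.approx(oracle.hdi(), abs=2e-3)


class TestStructuralProperties:
    def test_predictive_interval_contains_mu_interval(self, diabetes):
        res = bayes_pool(diabetes, HN05)
        mu_lo, mu_hi = res.mu_cri
        pr_lo, pr_hi = res.predictive_cri
        assert pr_hi - pr_lo > mu_hi - mu_lo
        assert pr_lo < mu_lo and pr_hi > mu_hi

    def test_inflating_sigmas_widens_mu_interval(self, diabetes):
        base = bayes_pool(diabetes, HN05)
        inflated = [
            StudyEffect(study_label=s.study_label, y=s.y, sigma=2 * s.sigma)
            for s in diabetes
        ]
        wide = bayes_pool(inflated, HN05)
        assert (wide.mu_cri[1] - wide.mu_cri[0]) > (base.mu_cri[1] - base.mu_cri[0])

    def test_uninformative_study_shrinks_to_predictive(self, diabetes):
        studies = list(diabetes.studies) + [
            StudyEffect(study_label="vague", y=0.0, sigma=1e4)
        ]
        res = bayes_pool(studies, HN05)
        vague = res.shrinkage[-1]
        assert vague.median == pytest.approx(res.predictive_median, abs=1e-3)
        assert vague.interval == pytest.approx(res.predictive_cri, abs=5e-3)

    def test_shrinkage_intervals_stay_in_data_range(self, diabetes):
        res = bayes_pool(diabetes, HN05)
        lo = min(s.y - 4 * s.sigma for s in diabetes)
        hi = max(s.y + 4 * s.sigma for s in diabetes)
        for s in res.shrinkage:
            assert lo < s.interval[0] < s.interval[1] < hi

    def test_tau_credible_interval_starts_at_zero_for_modest_heterogeneity(self, diabetes):
        # highest-density intervals: density maximal at the origin
        res = bayes_pool(diabetes, HN05)
        assert res.tau_cri[0] == 0.0
        assert res.tau_cri[1] > res.tau_median > 0


class TestSensitivity:
    def test_wider_priors_give_larger_tau(self, diabetes):
        results = sensitivity_analysis(
            diabetes,
            [HeterogeneityPrior("half_normal", 0.5), HeterogeneityPrior("half_normal", 1.0)],
        )
        assert results[0].tau_median <= results[1].tau_median
        # and wider predictive intervals
        w0 = results[0].predictive_cri[1] - results[0].predictive_cri[0]
        w1 = results[1].predictive_cri[1] - results[1].predictive_cri[0]
        assert w0 < w1

    def test_single_prior_matches_direct_calls(self, make_studies):
        studies = make_studies([0.8, 1.9, 0.3], [0.25, 0.49, 0.16])
        (res,) = sensitivity_analysis(studies, [HN05])
        assert res.mu_median == mu_posterior(studies, HN05).median()
        assert res.predictive_median == predictive_distribution(studies, HN05).median()

    def test_empty_prior_list_rejected(self, make_studies):
        with pytest.raises(DomainError):
            sensitivity_analysis(make_studies([1.0], [0.5]), [])

    def test_half_cauchy_runs_and_is_wilder_than_half_normal(self, diabetes):
        hn = bayes_pool(diabetes, HN05)
        hc = bayes_pool(diabetes, HeterogeneityPrior("half_cauchy", 0.5))
        assert hc.predictive_cri[1] > hn.predictive_cri[1]


class TestPublishedBayesianValues:
    """Comparison against the published Bayesian columns (half-normal 0.5).

    Hypertension and cardiovascular disease reproduce closely; see the
    acceptance tests for the diabetes/CKD/respiratory targets.
    """

    def test_hypertension(self, reference):
        res = bayes_pool(reference["hypertension"], HN05)
        assert res.mu_median == pytest.approx(1.38, abs=0.04)
        assert res.mu_cri == pytest.approx((0.76, 2.02), abs=0.04)
        assert res.tau_median == pytest.approx(0.36, abs=0.04)
        assert res.tau_cri[1] == pytest.approx(0.90, abs=0.10)
        assert res.predictive_median == pytest.approx(1.37, abs=0.04)

    def test_cardiovascular(self, reference):
        res = bayes_pool(reference["cardiovascular_disease"], HN05)
        assert res.mu_median == pytest.approx(1.55, abs=0.04)
        assert res.tau_median == pytest.approx(0.35, abs=0.04)
        assert math.exp(res.predictive_median) == pytest.approx(4.71, abs=0.15)
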