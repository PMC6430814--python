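"""Variance moderation and the empirical Gaussian allelic-imbalance test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from asbkit.model import (
    EmpiricalGaussianASB,
    LoessVarianceTrend,
    ParametricVarianceTrend,
    asb_pvalue,
    bh_adjust,
    expected_variance,
    fit_variance_trend,
    summarize_allele,
)


class TestSummarizeAllele:
    def test_equal_counts(self):
        s = summarize_allele([10.0, 10.0])
        assert (s.mu, s.var, s.cv2) == (10.0, 0.0, 0.0)

    def test_unbiased_variance(self):
        s = summarize_allele([8.0, 12.0])
        assert (s.mu, s.var) == (10.0, 8.0)
        assert s.cv2 == pytest.approx(0.08)

    def test_zero_mean_degenerate(self):
        s = summarize_allele([0.0, 0.0])
        assert s.mu == 0.0 and s.cv2 == 0.0

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            summarize_allele([5.0])


class TestLoessVarianceTrend:
    def test_constant_response(self):
        rng = np.random.default_rng(0)
        mu = rng.uniform(5, 500, size=200)
        trend = LoessVarianceTrend().fit(mu, np.full(200, 0.05))
        assert np.allclose(trend.predict([10, 100, 400]), 0.05, atol=1e-6)

    @pytest.mark.parametrize("span,rtol", [(0.75, 0.30), (0.5, 0.15)])
    def test_recovers_poisson_curve(self, span, rtol):
        # noiseless omega = 1/mu training points; the smoother should track
        # the generating curve over the central 80% of the mu range.  The
        # curve is convex on the log2 scale, so the degree-1 local fits
        # over-smooth at wide spans; tighter spans track more closely.
        rng = np.random.default_rng(1)
        mu = rng.uniform(8, 512, size=2000)
        omega = 1.0 / mu
        trend = LoessVarianceTrend(span=span).fit(mu, omega)
        lo = 8 + 0.1 * (512 - 8)
        hi = 512 - 0.1 * (512 - 8)
        grid = np.linspace(lo, hi, 50)
        pred = trend.predict(grid)
        assert np.all(np.abs(pred - 1.0 / grid) <= rtol / grid)

    def test_clamped_extrapolation(self):
        rng = np.random.default_rng(2)
        mu = rng.uniform(8, 64, size=100)
        trend = LoessVarianceTrend().fit(mu, 0.1 + 0.001 * mu)
        below = trend.predict([1e-3])[0]
        at_min = trend.predict([mu.min()])[0]
        assert below == pytest.approx(at_min)

    def test_floor(self):
        mu = np.linspace(10, 100, 50)
        trend = LoessVarianceTrend().fit(mu, np.zeros(50))
        assert np.all(trend.predict(mu) >= 1e-6)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="Parametric"):
            LoessVarianceTrend().fit(np.arange(1, 10.0), np.ones(9))

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        mu = rng.uniform(5, 500, size=100)
        trend = LoessVarianceTrend().fit(mu, 0.05 + 1 / mu)
        trend.to_tsv(tmp_path / "trend.tsv")
        back = LoessVarianceTrend.from_tsv(tmp_path / "trend.tsv")
        grid = np.linspace(6, 400, 20)
        assert np.allclose(back.predict(grid), trend.predict(grid), rtol=1e-9)

    def test_sklearn_params(self):
        trend = LoessVarianceTrend(span=0.5)
        assert trend.get_params()["span"] == 0.5
        trend.set_params(span=0.9)
        assert trend.span == 0.9


class TestParametricFallback:
    def test_recovers_a_and_b(self):
        mu = np.linspace(5, 500, 200)
        trend = ParametricVarianceTrend().fit(mu, 0.04 + 2.0 / mu)
        assert trend.a_ == pytest.approx(0.04, abs=1e-9)
        assert trend.b_ == pytest.approx(2.0, abs=1e-6)


class _FlatTrend:
    """Deterministic stand-in trend for closed-form p-value checks."""

    def __init__(self, omega):
        self.omega = omega

    def predict(self, mu):
        return np.full(np.atleast_1d(mu).shape, self.omega)


class TestExpectedVariance:
    def test_quadratic_scaling(self):
        t = _FlatTrend(0.04)
        assert expected_variance(50.0, t) == pytest.approx(100.0)
        assert expected_variance(100.0, t) == pytest.approx(400.0)

    def test_rejects_nonpositive_mean(self):
        with pytest.raises(ValueError):
            expected_variance(0.0, _FlatTrend(0.04))


class TestASBPvalue:
    def test_tie_gives_p_one(self):
        p, major, *_ = asb_pvalue([10.0, 10.0], [10.0, 10.0], _FlatTrend(0.05))
        assert p == 1.0 and major == "ref"

    def test_known_value(self):
        # mu_M=40, mu_m=20, sigma2_M=64 (omega=0.04), k=2
        # z = -20 / sqrt(32); p = 2 Phi(z)
        p, major, mu_M, mu_m, var_M = asb_pvalue(
            [40.0, 40.0], [20.0, 20.0], _FlatTrend(0.04))
        assert major == "ref" and mu_M == 40.0 and var_M == pytest.approx(64.0)
        assert p == pytest.approx(2 * stats.norm.cdf(-20 / np.sqrt(32)), rel=1e-12)
        assert p == pytest.approx(4.0695e-4, rel=1e-4)

    def test_integration_oracle_equivalence(self):
        # p must equal 2x the numerically integrated Gaussian posterior tail
        rng = np.random.default_rng(7)
        for _ in range(1000):
            mu_M = rng.uniform(10, 500)
            mu_m = rng.uniform(1, mu_M)
            omega = rng.uniform(1e-4, 0.5)
            k = int(rng.integers(2, 5))
            sd = np.sqrt(omega * mu_M**2 / k)
            closed = min(1.0, 2.0 * stats.norm.cdf((mu_m - mu_M) / sd))
            tail, _ = integrate.quad(
                lambda u: stats.norm.pdf(u, loc=mu_M, scale=sd), -np.inf, mu_m,
                epsabs=1e-14, epsrel=1e-13)
            assert abs(closed - min(1.0, 2 * tail)) < 1e-10
            p, *_ = asb_pvalue([mu_M] * k, [mu_m] * k, _FlatTrend(omega))
            assert p == pytest.approx(closed, abs=1e-12)

    @given(st.floats(1, 400), st.floats(1, 400), st.floats(1e-3, 0.5))
    @settings(max_examples=200, deadline=None)
    def test_symmetric_in_allele_labels(self, a, b, omega):
        t = _FlatTrend(omega)
        p1, *_ = asb_pvalue([a, a], [b, b], t)
        p2, *_ = asb_pvalue([b, b], [a, a], t)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_monotone_in_variance_and_gap(self):
        gaps = [asb_pvalue([40.0, 40.0], [40.0 - g] * 2, _FlatTrend(0.05))[0]
                for g in (5, 10, 20, 30)]
        assert all(a > b for a, b in zip(gaps, gaps[1:]))
        variances = [asb_pvalue([40.0, 40.0], [20.0, 20.0], _FlatTrend(w))[0]
                     for w in (0.01, 0.05, 0.2, 0.5)]
        assert all(a < b for a, b in zip(variances, variances[1:]))

    def test_untestable_allele_raises(self):
        with pytest.raises(ValueError, match="untestable"):
            asb_pvalue([0.0, 0.0], [5.0, 5.0], _FlatTrend(0.05))


class TestBHAdjust:
    def test_single_pvalue(self):
        assert bh_adjust([0.01])[0] == pytest.approx(0.01)

    def test_step_up_with_min(self):
        fdr = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(fdr, 0.04)

    def test_all_ones(self):
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_empty(self):
        assert bh_adjust([]).size == 0

    def test_matches_manual_step_up(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205,
                      0.212, 0.216, 0.222, 0.251, 0.269, 0.275, 0.34, 0.341,
                      0.384, 0.569, 0.594, 0.696, 0.762, 0.94, 0.942, 0.975,
                      0.986])
        n = p.size
        order = np.argsort(p)
        manual = np.empty(n)
        prev = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            i = n - rank_from_top  # 1-based rank
            prev = min(prev, p[idx] * n / i)
            manual[idx] = prev
        assert np.allclose(bh_adjust(p), manual, atol=1e-12)


class TestEmpiricalGaussianASB:
    def test_fit_and_attributes(self):
        rng = np.random.default_rng(11)
        n, k = 400, 2
        mu = rng.uniform(20, 200, size=n)
        x_ref = rng.poisson(mu[:, None], size=(n, k)).astype(float)
        x_alt = rng.poisson(mu[:, None], size=(n, k)).astype(float)
        est = EmpiricalGaussianASB().fit(x_ref, x_alt)
        assert est.pvalues_.shape == (n,)
        assert est.testable_.all()
        assert np.all(est.mu_major_ >= est.mu_minor_)
        assert np.all((est.pvalues_ > 0) & (est.pvalues_ <= 1.0))
        df = est.results_dataframe()
        assert len(df) == n and bool(df["testable"].all())

    def test_untestable_rows_flagged(self):
        rng = np.random.default_rng(12)
        x_ref = rng.uniform(10, 50, size=(60, 2))
        x_alt = rng.uniform(10, 50, size=(60, 2))
        x_alt[0] = 0.0
        est = EmpiricalGaussianASB().fit(x_ref, x_alt)
        assert not est.testable_[0]
        assert np.isnan(est.pvalues_[0]) and not est.significant_[0]

    def test_detects_strong_imbalance(self):
        # shared per-replicate depth factors, as in replicated eCLIP: the
        # across-replicate variance of each allele then includes a component
        # common to both alleles, which the moderated test absorbs
        rng = np.random.default_rng(13)
        n, k = 500, 2
        mu = rng.uniform(50, 300, size=n)
        f = np.exp(rng.normal(-0.5 * 0.25**2, 0.25, size=(n, k)))
        x_ref = rng.poisson(mu[:, None] * f).astype(float)
        x_alt = rng.poisson(mu[:, None] * f).astype(float)
        x_alt[:50] = rng.poisson(mu[:50, None] * f[:50] * 0.15)
        est = EmpiricalGaussianASB().fit(x_ref, x_alt)
        assert est.significant_[:50].mean() > 0.9
        assert est.significant_[50:].mean() < 0.05

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = EmpiricalGaussianASB(span=0.6, fdr_threshold=0.05)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
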