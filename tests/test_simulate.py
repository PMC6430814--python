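"""The ZTNB simulator: coverage sampling, moments, bias injection, regimes."""

import numpy as np
import pytest
from scipy import stats

from asbkit.bias import BiasTable
from asbkit.simulate import (
    OUTSIDE,
    SimConfig,
    SimDataset,
    example_bias_table,
    inject_crosslink_bias,
    make_high_variance,
    sample_allelic_counts_ztnb,
    sample_total_coverage,
    simulate_study,
    ztnb_sample,
)
from asbkit.evaluate import normalized_counts


def ztnb_moments(mean, size):
    """Independent oracle: zero-truncated NB mean and variance."""
    p0 = (size / (size + mean)) ** size
    var = mean + mean**2 / size
    zt_mean = mean / (1 - p0)
    zt_e2 = (var + mean**2) / (1 - p0)
    return zt_mean, zt_e2 - zt_mean**2


class TestCoverage:
    def test_empirical_resampling_frequencies(self, tmp_path):
        f = tmp_path / "cov.txt"
        f.write_text("10\n20\n30\n")
        rng = np.random.default_rng(0)
        draws = sample_total_coverage(f, rng, size=30000)
        for v in (10, 20, 30):
            assert abs((draws == v).mean() - 1 / 3) < 0.01

    def test_lognormal_median(self):
        rng = np.random.default_rng(1)
        draws = sample_total_coverage(None, rng, size=100_000,
                                      min_coverage=1, log_median=np.exp(4.0))
        assert abs(np.median(draws) - np.exp(4)) / np.exp(4) < 0.05

    def test_minimum_enforced(self):
        rng = np.random.default_rng(2)
        draws = sample_total_coverage(None, rng, size=5000, min_coverage=10)
        assert draws.min() >= 10

    def test_empty_empirical_file(self, tmp_path):
        f = tmp_path / "cov.txt"
        f.write_text("")
        with pytest.raises(ValueError):
            sample_total_coverage(f, np.random.default_rng(0), size=10)


class TestZTNB:
    @pytest.mark.parametrize("mean,cv2", [(20, 0.05), (80, 0.05), (200, 0.02)])
    def test_moments_match_truncation_adjusted_targets(self, mean, cv2):
        var = mean + cv2 * mean**2
        size = mean**2 / (var - mean)
        rng = np.random.default_rng(100 + mean)
        draws = ztnb_sample(np.full(100_000, float(mean)), var, rng)
        zt_mean, zt_var = ztnb_moments(mean, size)
        assert abs(draws.mean() - zt_mean) / zt_mean < 0.02
        assert abs(draws.var(ddof=1) - zt_var) / zt_var < 0.05

    def test_every_draw_at_least_one(self):
        rng = np.random.default_rng(3)
        draws = ztnb_sample(np.full(20000, 1.5), np.full(20000, 4.0), rng)
        assert draws.min() >= 1

    def test_poisson_fallback_warns(self):
        rng = np.random.default_rng(4)
        with pytest.warns(UserWarning, match="Poisson"):
            ztnb_sample(np.full(100, 10.0), np.full(100, 5.0), rng)

    def test_balanced_ratio_symmetric(self):
        rng = np.random.default_rng(5)
        major, minor = [], []
        M, m = sample_allelic_counts_ztnb(
            np.full(2, 100.0), 0.5, lambda x: 2 * x, k=2,
            rng=rng)
        # vectorized: draw many SNVs at once through ztnb_sample directly
        var = lambda x: 2 * x
        M = ztnb_sample(np.full(100_000, 50.0), var(np.full(100_000, 50.0)), rng)
        m = ztnb_sample(np.full(100_000, 50.0), var(np.full(100_000, 50.0)), rng)
        ratio = M.sum() / (M.sum() + m.sum())
        assert abs(ratio - 0.5) < 0.005


class TestBiasInjection:
    def test_uniform_table_is_identity(self):
        ds = simulate_study(SimConfig(n_snvs=200, seed=6))[0]
        rng = np.random.default_rng(0)
        out = inject_crosslink_bias(ds, BiasTable.uniform(), rng)
        assert np.array_equal(out.major, ds.major)

    def test_rescale_arithmetic(self):
        q = np.full((4, 51), 0.1)
        q[3, :] = 0.7  # T enriched everywhere
        table = BiasTable(q)
        ds = SimDataset(
            major=np.array([[100, 100]]), minor=np.array([[50, 50]]),
            is_asb=np.array([False]), r=np.array([0.5]),
            offset=np.array([0], dtype=np.int16),
            major_base=np.array(["T"], dtype=object),
            minor_base=np.array(["C"], dtype=object),
            coverage=np.array([150.0]),
        )
        out = inject_crosslink_bias(ds, table, np.random.default_rng(0), assign=False)
        assert np.array_equal(out.major[0], [280, 280])  # 100 * 0.7/0.25
        assert np.array_equal(out.minor[0], [20, 20])  # 50 * 0.1/0.25

    def test_outside_window_untouched(self):
        ds = SimDataset(
            major=np.array([[100, 100]]), minor=np.array([[50, 50]]),
            is_asb=np.array([False]), r=np.array([0.5]),
            offset=np.array([OUTSIDE], dtype=np.int16),
            major_base=np.array(["T"], dtype=object),
            minor_base=np.array(["C"], dtype=object),
            coverage=np.array([150.0]),
        )
        out = inject_crosslink_bias(ds, example_bias_table(),
                                    np.random.default_rng(0), assign=False)
        assert np.array_equal(out.major, ds.major)

    def test_round_trip_with_normalization(self):
        # inject then normalize with the same table: counts recovered +/- 1
        table = example_bias_table()
        ds = simulate_study(SimConfig(n_snvs=2000, seed=7))[0]
        rng = np.random.default_rng(1)
        biased = inject_crosslink_bias(ds, table, rng)
        x_major, x_minor = normalized_counts(biased, table, R=4.0)
        # with R=4 the q's cancel: x = round(y * q/0.25) / (4q); rounding the
        # recovered value restores the original integer within +/-1
        assert np.all(np.abs(np.rint(x_major) - ds.major) <= 1)
        assert np.all(np.abs(np.rint(x_minor) - ds.minor) <= 1)


class TestHighVariance:
    def test_sd_exceeds_reference_and_means_preserved(self):
        ds = simulate_study(SimConfig(n_snvs=300, seed=8))[0]
        ref_sds = np.concatenate([
            ds.major.std(axis=1, ddof=1), ds.minor.std(axis=1, ddof=1)])
        out = make_high_variance(ds, ref_sds, np.random.default_rng(2))
        target = np.percentile(ref_sds, 95)
        assert out.n_snvs > 0
        assert np.all(out.major.std(axis=1, ddof=1) > target)
        assert np.all(out.minor.std(axis=1, ddof=1) > target)
        if out.n_snvs == ds.n_snvs:  # rows aligned when nothing was dropped
            before = ds.major.mean(axis=1)
            after = out.major.mean(axis=1)
            assert np.all(np.abs(after - before) <= 0.1 * np.maximum(before, 1) + 1e-9)

    def test_zero_reference_sds_degenerate(self):
        ds = simulate_study(SimConfig(n_snvs=50, seed=9))[0]
        out = make_high_variance(ds, np.zeros(100), np.random.default_rng(3))
        assert np.all(out.major.std(axis=1, ddof=1) > 0)


class TestStudy:
    def test_label_bookkeeping(self):
        datasets = simulate_study(SimConfig(n_experiments=2, n_snvs=100,
                                            frac_asb=0.1, seed=10))
        assert len(datasets) == 2
        for ds in datasets:
            assert ds.is_asb.sum() == 10
            assert np.all(ds.r[ds.is_asb] == 0.8)
            assert np.all(ds.r[~ds.is_asb] == 0.5)
            assert ds.major.min() >= 1 and ds.minor.min() >= 1

    def test_seed_determinism(self):
        a = simulate_study(SimConfig(n_experiments=2, n_snvs=50, seed=11))
        b = simulate_study(SimConfig(n_experiments=2, n_snvs=50, seed=11))
        for x, y in zip(a, b):
            assert np.array_equal(x.major, y.major)
            assert np.array_equal(x.minor, y.minor)
        c = simulate_study(SimConfig(n_experiments=1, n_snvs=50, seed=12))[0]
        assert not np.array_equal(a[0].major, c.major)

    def test_null_ratio_distribution_symmetric(self):
        ds = simulate_study(SimConfig(n_snvs=5000, frac_asb=0.0, seed=13))[0]
        tot_major = ds.major.sum(axis=1)
        tot_minor = ds.minor.sum(axis=1)
        ratios = tot_major / (tot_major + tot_minor)
        ks = stats.ks_2samp(ratios, 1.0 - ratios)
        assert ks.pvalue > 0.01

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(r_true=0.4)
        with pytest.raises(ValueError):
            SimConfig(k=1)
        with pytest.raises(ValueError):
            SimConfig(frac_asb=1.0)

    def test_tsv_round_trip(self, tmp_path):
        ds = simulate_study(SimConfig(n_snvs=40, seed=14,
                                      bias=example_bias_table()))[0]
        ds.to_tsv(tmp_path / "sim.tsv")
        back = SimDataset.from_tsv(tmp_path / "sim.tsv")
        assert np.array_equal(back.major, ds.major)
        assert np.array_equal(back.minor, ds.minor)
        assert np.array_equal(back.is_asb, ds.is_asb)
        assert np.array_equal(back.offset, ds.offset)
        assert back.seed == ds.seed
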