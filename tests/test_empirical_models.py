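import numpy as np
import pytest
from scipy import stats

from loopgrow.empirical_models import (
    ChiTable,
    DihedralTable,
    DistancePairSet,
    FitError,
    Kde2D,
    SamplingError,
    conditional_slice,
    dihedral_log_prob,
    eval_density,
    fit_kde2d,
    kernel_sum,
    sample_conditional,
    select_k_trials,
    slice_cdf,
    winsorize,
)


def _gaussian_pairs(rng, n=200, rho=0.6):
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return rng.multivariate_normal([6.0, 6.5], cov * 0.8, size=n) + 3.0


class TestWinsorize:
    def test_level_100_identity(self, rng):
        v = rng.uniform(0, 10, 50)
        assert np.array_equal(winsorize(v, 100), v)

    def test_known_percentile(self):
        v = np.arange(1.0, 101.0)
        w = winsorize(v, 95)
        expected_cut = np.percentile(v, 95)  # 95.05 by linear interpolation
        assert abs(expected_cut - 95.05) < 1e-12
        assert np.all(w[w >= expected_cut] == expected_cut)
        assert np.array_equal(w[:94], v[:94])
        assert len(w) == len(v)

    def test_constant_unchanged(self):
        v = np.full(20, 3.3)
        for level in (10, 50, 99):
            assert np.array_equal(winsorize(v, level), v)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            winsorize([], 99)


class TestKde2D:
    def test_grid_matches_brute_force_kernel_sum(self, rng):
        """Every grid node equals the explicit kernel sum to 1e-12 relative."""
        for _ in range(20):
            pairs = np.abs(_gaussian_pairs(rng, n=int(rng.integers(30, 120))))
            kde = fit_kde2d(DistancePairSet(3, pairs))
            xg, yg = np.meshgrid(kde.x_nodes, kde.y_nodes, indexing="ij")
            w = np.column_stack(
                [winsorize(pairs[:, 0], 99), winsorize(pairs[:, 1], 99)]
            )
            ref = kernel_sum(w, kde.bandwidth, xg.ravel(), yg.ravel()).reshape(32, 32)
            assert np.allclose(kde.grid, ref, rtol=1e-12, atol=0)

    def test_tight_cluster_peak_location(self, rng):
        pairs = np.array([[5.0, 5.5]]) + rng.normal(0, 0.05, (40, 2))
        kde = fit_kde2d(DistancePairSet(2, pairs))
        i, j = np.unravel_index(np.argmax(kde.grid), kde.grid.shape)
        peak = np.array([kde.x_nodes[i], kde.y_nodes[j]])
        node_gap = max(np.diff(kde.x_nodes)[0], np.diff(kde.y_nodes)[0])
        assert np.linalg.norm(peak - [5.0, 5.5]) < 2 * node_gap

    def test_grid_integral_near_one(self, rng):
        """Trapezoidal mass stays in [0.95, 1.05] over many random datasets."""
        for _ in range(200):
            pairs = np.abs(_gaussian_pairs(rng, n=int(rng.integers(40, 200))))
            kde = fit_kde2d(DistancePairSet(2, pairs))
            assert 0.95 <= kde.grid_integral() <= 1.05

    def test_zero_variance_rejected(self):
        pairs = np.column_stack([np.full(20, 5.0), np.linspace(4, 6, 20)])
        with pytest.raises(FitError):
            fit_kde2d(DistancePairSet(1, pairs))

    def test_too_few_pairs_rejected(self, rng):
        with pytest.raises(FitError):
            fit_kde2d(DistancePairSet(1, np.abs(rng.normal(5, 1, (5, 2)))))


class TestEvalDensity:
    @pytest.fixture()
    def kde(self, rng):
        return fit_kde2d(DistancePairSet(2, np.abs(_gaussian_pairs(rng))))

    def test_grid_node_exact(self, kde):
        assert eval_density(kde, kde.x_nodes[7], kde.y_nodes[13]) == kde.grid[7, 13]

    def test_cell_center_is_corner_mean(self, kde):
        x = 0.5 * (kde.x_nodes[4] + kde.x_nodes[5])
        y = 0.5 * (kde.y_nodes[9] + kde.y_nodes[10])
        expected = kde.grid[4:6, 9:11].mean()
        assert abs(eval_density(kde, x, y) - expected) < 1e-12

    def test_outside_domain_zero(self, kde):
        assert eval_density(kde, kde.x_nodes[0] - 1.0, kde.y_nodes[5]) == 0.0
        assert eval_density(kde, kde.x_nodes[5], kde.y_nodes[-1] + 1.0) == 0.0


class TestSampleConditional:
    def test_correlated_mean(self, rng):
        """KDE on perfectly correlated pairs: draws at d_prev=6 center on 6."""
        base = rng.uniform(4, 8, 400)
        pairs = np.column_stack([base, base]) + rng.normal(0, 1e-3, (400, 2))
        kde = fit_kde2d(DistancePairSet(2, pairs))
        draws = sample_conditional(kde, 6.0, rng, size=10_000)
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - 6.0) < max(3 * se, 0.15)

    def test_ks_against_analytic_slice(self, rng):
        """Empirical CDF of draws matches the analytic slice CDF (D < 0.02)."""
        worst = 0.0
        for trial in range(5):
            pairs = np.abs(_gaussian_pairs(rng, n=150))
            kde = fit_kde2d(DistancePairSet(3, pairs))
            d_prev = float(np.median(pairs[:, 0]))
            draws = np.asarray(sample_conditional(kde, d_prev, rng, size=10_000))
            y, cdf = slice_cdf(kde, d_prev)

            def analytic_cdf(v):
                return np.interp(v, y, cdf)

            d_stat = stats.kstest(draws, analytic_cdf).statistic
            worst = max(worst, d_stat)
        assert worst < 0.02

    def test_seeded_reproducibility(self, rng):
        pairs = np.abs(_gaussian_pairs(rng))
        kde = fit_kde2d(DistancePairSet(2, pairs))
        d_prev = float(np.median(pairs[:, 0]))
        a = sample_conditional(kde, d_prev, np.random.default_rng(7), size=100)
        b = sample_conditional(kde, d_prev, np.random.default_rng(7), size=100)
        assert np.array_equal(a, b)

    def test_empty_slice_raises(self, rng):
        kde = fit_kde2d(DistancePairSet(2, np.abs(_gaussian_pairs(rng))))
        with pytest.raises(SamplingError):
            sample_conditional(kde, kde.x_nodes[0] - 50.0, rng)
        assert np.all(conditional_slice(kde, kde.x_nodes[0] - 50.0) == 0)


class TestDihedralTable:
    def test_uniform_table_constant(self):
        t = DihedralTable("ALA", counts=np.ones((36, 36)))
        vals = {dihedral_log_prob(t, phi, psi) for phi, psi in
                [(-170, 10), (0, 0), (55, -125), (179, 179)]}
        assert len(vals) == 1

    def test_empty_bin_gets_pseudocount_floor(self):
        t = DihedralTable("GLY")
        t.add(-60, -45, weight=100)
        lp = dihedral_log_prob(t, 100.0, 100.0)
        eps = t.pseudocount_fraction * 100
        z = 100 + eps * 36 * 36
        assert abs(lp - np.log(eps / z)) < 1e-12

    def test_normalization_over_bin_centers(self, rng):
        t = DihedralTable("SER")
        for _ in range(500):
            t.add(rng.uniform(-180, 180), rng.uniform(-180, 180))
        centers = np.arange(-175.0, 180.0, 10.0)
        pp, ss = np.meshgrid(centers, centers, indexing="ij")
        total = np.exp(t.log_prob(pp.ravel(), ss.ravel())).sum()
        assert abs(total - 1.0) < 1e-9


class TestSelectKTrials:
    def test_k_equals_m_returns_all(self, rng):
        t = DihedralTable("ALA", counts=np.ones((36, 36)))
        idx = select_k_trials(np.zeros(5), np.zeros(5), t, 5, rng)
        assert sorted(idx) == [0, 1, 2, 3, 4]

    def test_k_above_m_rejected(self, rng):
        t = DihedralTable("ALA", counts=np.ones((36, 36)))
        with pytest.raises(ValueError):
            select_k_trials(np.zeros(3), np.zeros(3), t, 4, rng)

    def test_dominant_candidate_always_wins(self, rng):
        t = DihedralTable("ALA")
        t.add(-60, -45, weight=1e9)
        phis = np.array([-60.0, 100.0, 100.0, 150.0])
        psis = np.array([-45.0, 100.0, 150.0, 100.0])
        hits = sum(
            select_k_trials(phis, psis, t, 1, rng)[0] == 0 for _ in range(10_000)
        )
        assert hits >= 9990

    def test_uniform_table_uniform_frequencies(self, rng):
        """Chi-squared check: uniform table gives uniform single-draw picks."""
        t = DihedralTable("ALA", counts=np.ones((36, 36)))
        m = 6
        counts = np.zeros(m)
        reps = 10_000
        for _ in range(reps):
            counts[select_k_trials(np.zeros(m), np.zeros(m), t, 1, rng)[0]] += 1
        chi2 = ((counts - reps / m) ** 2 / (reps / m)).sum()
        # 3-sigma-ish bound for chi2 with 5 dof
        assert chi2 < 5 + 3 * np.sqrt(10)

    def test_without_replacement_distinct(self, rng):
        t = DihedralTable("ALA", counts=np.ones((36, 36)))
        idx = select_k_trials(rng.normal(0, 50, 10), rng.normal(0, 50, 10), t, 6, rng)
        assert len(set(idx.tolist())) == 6


class TestChiTable:
    def test_single_bin_returns_its_mean(self, rng):
        t = ChiTable("VAL", 1)
        for v in (178.0, 176.0, 177.0):
            t.add([v])
        draws = t.sample(rng, size=10)
        assert np.allclose(draws, 177.0)

    def test_sampling_frequency_tracks_counts(self, rng):
        t = ChiTable("SER", 1)
        for _ in range(90):
            t.add([-60.0])
        for _ in range(10):
            t.add([60.0])
        draws = t.sample(rng, size=5000).ravel()
        frac = np.mean(draws < 0)
        assert abs(frac - 0.9) < 0.03
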