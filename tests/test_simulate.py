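"""Dataset simulator: phenotype effects, allocation, transforms, MNAR."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq

from metabobench.simulate import (
    SimulationConfig,
    apply_realistic_transforms,
    draw_perturbed_means,
    draw_phenotype_allocation,
    ggd_quantile,
    impute_missing,
    simulate_baseline,
    simulate_dataset,
)


class TestPerturbedMeans:
    def test_reference_phenotype_is_zero(self, rng):
        cfg = SimulationConfig()
        truth = draw_perturbed_means(cfg, rng)
        assert np.all(truth.mu[0] == 0.0)

    def test_perturbed_block_count_support(self, rng):
        cfg = SimulationConfig()
        for _ in range(200):
            truth = draw_perturbed_means(cfg, rng)
            for g in range(1, cfg.n_phenotypes):
                assert 1 <= len(truth.perturbed_blocks[g]) <= 5

    def test_effect_magnitude_mean_is_two(self, rng):
        """theta ~ Exp(rate 1/2) has mean 2; Monte-Carlo over many draws."""
        cfg = SimulationConfig()
        mags = []
        for _ in range(2000):
            truth = draw_perturbed_means(cfg, rng)
            for g_thetas in truth.theta:
                mags.extend(abs(t) for t in g_thetas)
        assert len(mags) > 10_000
        assert np.mean(mags) == pytest.approx(2.0, abs=0.1)

    def test_unperturbed_columns_share_means_across_phenotypes(self, rng):
        cfg = SimulationConfig()
        truth = draw_perturbed_means(cfg, rng)
        perturbed = set()
        for blocks in truth.perturbed_blocks:
            perturbed.update(blocks)
        quiet = [
            j
            for j in range(cfg.n_metabolites)
            if j // cfg.block_size not in perturbed
        ]
        assert np.all(truth.mu[:, quiet] == 0.0)


class TestAllocation:
    def test_counts_sum_and_floor(self, rng):
        cfg = SimulationConfig()
        for _ in range(100):
            counts = draw_phenotype_allocation(cfg, rng)
            assert counts.sum() == cfg.total_samples
            assert counts.min() >= cfg.min_per_class

    def test_symmetric_dirichlet_is_balanced_in_expectation(self, rng):
        cfg = SimulationConfig(dirichlet_alpha=(1.0, 1.0, 1.0), min_per_class=1)
        counts = np.array([draw_phenotype_allocation(cfg, rng) for _ in range(5000)])
        props = counts.mean(axis=0) / cfg.total_samples
        assert np.allclose(props, 1 / 3, atol=0.02)

    def test_asymmetric_dirichlet_favors_heavy_class(self, rng):
        cfg = SimulationConfig(dirichlet_alpha=(8.0, 1.0, 1.0), min_per_class=1)
        counts = np.array([draw_phenotype_allocation(cfg, rng) for _ in range(1000)])
        means = counts.mean(axis=0)
        assert means[0] > means[1] and means[0] > means[2]

    def test_infeasible_allocation_rejected(self, rng):
        with pytest.raises(ValueError):
            SimulationConfig(total_samples=20, min_per_class=10)


class TestBaseline:
    def test_default_dimensions(self, small_baseline):
        assert small_baseline.X.shape[0] == 60

    def test_metabolite_count_is_blocks_times_size(self, rng):
        cfg = SimulationConfig()
        assert cfg.n_metabolites == 1000

    def test_reference_columns_standard_normal(self, rng):
        """Blocks of size one have trivial correlation; reference-class rows
        are then i.i.d. standard normal per column."""
        cfg = SimulationConfig(
            n_blocks=10, block_size=1, total_samples=900,
            dirichlet_alpha=(1.0, 1.0, 1.0),
        )
        ds = simulate_baseline(cfg, rng)
        ref = ds.X[ds.y == 0]
        assert np.allclose(ref.mean(axis=0), 0.0, atol=0.25)
        assert np.allclose(ref.var(axis=0, ddof=1), 1.0, atol=0.3)

    def test_sample_correlation_converges_to_population(self, rng):
        cfg = SimulationConfig(
            n_blocks=1, block_size=5, total_samples=5000,
            dirichlet_alpha=(1.0, 1.0, 1.0),
        )
        ds = simulate_baseline(cfg, rng)
        ref = ds.X[ds.y == 0]
        est = np.corrcoef(ref, rowvar=False)
        assert np.abs(est - ds.covariances[0].entries).max() < 0.08

    def test_cross_block_independence(self, rng):
        cfg = SimulationConfig(
            n_blocks=2, block_size=5, total_samples=3000,
            dirichlet_alpha=(1.0, 1.0, 1.0),
        )
        ds = simulate_baseline(cfg, rng)
        ref = ds.X[ds.y == 0]
        est = np.corrcoef(ref, rowvar=False)
        assert np.abs(est[:5, 5:]).max() < 0.09

    def test_no_missing_in_baseline(self, small_baseline):
        assert not small_baseline.missing_mask.any()
        assert not np.isnan(small_baseline.X).any()


class TestGGDQuantile:
    def test_median_is_zero(self):
        for kappa in (-0.5, 0.0, 0.7):
            assert ggd_quantile(0.5, kappa, 1.3) == pytest.approx(0.0, abs=1e-12)

    def test_kappa_zero_is_scaled_normal(self):
        u = stats.norm.cdf(1.0)
        assert ggd_quantile(u, 0.0, 2.0) == pytest.approx(2.0, abs=1e-9)

    def test_against_numeric_cdf_inversion(self):
        """Oracle: solve F(x) = u where F(x) = Phi(-(1/kappa) log(1 - kappa x / alpha))."""
        kappa, alpha, u = 0.5, 1.0, stats.norm.cdf(1.0)

        def cdf(x):
            return stats.norm.cdf(-(1.0 / kappa) * np.log(1.0 - kappa * x / alpha))

        oracle = brentq(lambda x: cdf(x) - u, -10, 1.999)
        assert ggd_quantile(u, kappa, alpha) == pytest.approx(oracle, abs=1e-9)
        assert ggd_quantile(u, kappa, alpha) == pytest.approx(0.7869, abs=1e-4)

    def test_continuity_in_kappa_at_zero(self):
        u = 0.8
        assert ggd_quantile(u, 1e-13, 1.0) == pytest.approx(
            ggd_quantile(u, 1e-7, 1.0), abs=1e-5
        )

    def test_invalid_u_rejected(self):
        for u in (0.0, 1.0, -0.2, 1.7):
            with pytest.raises(ValueError):
                ggd_quantile(u, 0.1, 1.0)


class TestRealisticTransforms:
    def test_rank_correlations_preserved_without_noise(self, rng):
        cfg = SimulationConfig(
            n_blocks=3, block_size=4, total_samples=60,
            ggd_kappa_range=(0.0, 0.0), outlier_rates=(0.0, 0.0),
            lod_quantile=0.0,
        )
        base = simulate_baseline(cfg, rng)
        real = apply_realistic_transforms(base, cfg, rng)
        rho_before = stats.spearmanr(base.X).statistic
        rho_after = stats.spearmanr(real.X).statistic
        assert np.allclose(rho_before, rho_after, atol=1e-12)

    def test_missing_fraction_matches_lod_quantile(self, rng):
        cfg = SimulationConfig(
            n_blocks=3, block_size=4, total_samples=200, lod_quantile=0.1,
            outlier_rates=(0.0, 0.0),
        )
        base = simulate_baseline(cfg, rng)
        real = apply_realistic_transforms(base, cfg, rng)
        frac = real.missing_mask.mean(axis=0)
        assert np.all(np.abs(frac - 0.1) < 0.02)

    def test_every_masked_value_below_threshold(self, rng):
        cfg = SimulationConfig(n_blocks=3, block_size=4, total_samples=120)
        base = simulate_baseline(cfg, rng)
        real = apply_realistic_transforms(base, cfg, rng)
        rows, cols = np.where(real.missing_mask)
        assert rows.size > 0
        assert np.all(real.X_premask[rows, cols] < real.lod_thresholds[cols])
        observed = real.X[~real.missing_mask]
        assert not np.isnan(observed).any()

    def test_biological_outlier_rate(self, rng):
        cfg = SimulationConfig(
            n_blocks=10, block_size=3, total_samples=400,
            outlier_rates=(0.05, 0.0), lod_quantile=0.0,
        )
        base = simulate_baseline(cfg, rng)
        real = apply_realistic_transforms(base, cfg, rng)
        rate = real.outlier_flags_biological.mean()
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_reproducibility_bit_identical(self):
        cfg = SimulationConfig(
            n_blocks=3, block_size=4, total_samples=60, scenario="realistic", seed=5
        )
        a, b = simulate_dataset(cfg), simulate_dataset(cfg)
        assert np.array_equal(a.X, b.X, equal_nan=True)
        assert np.array_equal(a.y, b.y)
        assert np.array_equal(a.missing_mask, b.missing_mask)


class TestImputation:
    def test_identity_without_missing(self):
        X = np.arange(12.0).reshape(4, 3)
        res = impute_missing(X)
        assert np.array_equal(res.X, X)
        assert res.dropped.size == 0

    def test_half_minimum_fill(self):
        X = np.array([[4.0, 1.0], [np.nan, 2.0], [8.0, np.nan]])
        res = impute_missing(X)
        assert res.X[1, 0] == 2.0  # half of observed min 4.0
        assert res.X[2, 1] == 0.5

    def test_all_missing_column_dropped(self):
        X = np.array([[1.0, np.nan], [2.0, np.nan]])
        res = impute_missing(X)
        assert res.X.shape == (2, 1)
        assert list(res.dropped) == [1]

    def test_imputed_values_stay_below_lod(self, rng):
        cfg = SimulationConfig(n_blocks=4, block_size=5, total_samples=120)
        base = simulate_baseline(cfg, rng)
        real = apply_realistic_transforms(base, cfg, rng)
        res = impute_missing(real.X)
        rows, cols = np.where(real.missing_mask)
        assert np.all(res.X[rows, cols] <= real.lod_thresholds[cols])
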