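"""Tests for the stratified pooling-study simulator."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolperm import (
    PoolDataError,
    ScenarioConfig,
    allocate_to_pools,
    build_difference_matrix,
    chi2_per_marker,
    default_stratum_model,
    draw_matched_sets,
    large_sample_pvalue,
    measure_pool,
    simulate_dataset,
    true_pool_frequency,
)


class TestMatching:
    def test_perfect_matching_shares_strata(self, rng):
        cfg = ScenarioConfig(n_cases=200, m=2, delta=0.0)
        model = default_stratum_model(cfg.L, rng=rng)
        sets = draw_matched_sets(model, cfg, rng)
        assert np.array_equal(
            sets.control_strata, np.repeat(sets.case_strata[:, None], 2, axis=1)
        )

    def test_random_matching_follows_population_weights(self, rng):
        # delta = 1: control strata are fresh draws from the (equal-weight)
        # population, independent of the risk-tilted case strata.
        cfg = ScenarioConfig(n_cases=3000, m=1, delta=1.0)
        model = default_stratum_model(cfg.L, rng=rng)
        sets = draw_matched_sets(model, cfg, rng)
        counts = np.bincount(sets.control_strata.ravel(), minlength=5)
        expected = 3000 / 5
        assert np.all(np.abs(counts - expected) < 4 * np.sqrt(expected))
        # cases, by contrast, are enriched in high-risk strata
        case_counts = np.bincount(sets.case_strata, minlength=5)
        assert case_counts[-1] > case_counts[0]

    def test_null_effect_balances_candidate_frequency(self, rng):
        # with perfect matching and no effect, case-control allele
        # frequency differences at the candidate average to zero
        cfg = ScenarioConfig(n_cases=2000, delta=0.0, effect_size=1.0)
        model = default_stratum_model(cfg.L, rng=rng)
        sets = draw_matched_sets(model, cfg, rng)
        diff = sets.case_genotypes[:, 0] - sets.control_genotypes[:, 0, 0]
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 3 * se + 1e-12

    def test_effect_size_raises_case_frequency(self, rng):
        cfg = ScenarioConfig(n_cases=4000, delta=0.0, effect_size=2.0)
        model = default_stratum_model(cfg.L, rng=rng)
        sets = draw_matched_sets(model, cfg, rng)
        assert sets.case_genotypes[:, 0].mean() > sets.control_genotypes[:, :, 0].mean()


class TestPooling:
    def test_every_pool_nonempty_and_uniform(self, rng):
        pool = allocate_to_pools(900, 10, rng)
        counts = np.bincount(pool, minlength=10)
        assert counts.min() > 0
        assert np.all(np.abs(counts - 90) < 5 * np.sqrt(90 * 0.9))

    def test_deterministic_given_seed(self):
        a = allocate_to_pools(100, 7, np.random.default_rng(5))
        b = allocate_to_pools(100, 7, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_too_few_sets_rejected(self):
        with pytest.raises(PoolDataError):
            allocate_to_pools(5, 10)

    @pytest.mark.parametrize(
        "genotypes, expected",
        [([0, 0, 0], 0.0), ([2, 2], 1.0), ([0, 1, 2], 0.5)],
    )
    def test_true_pool_frequency(self, genotypes, expected):
        assert true_pool_frequency(np.array(genotypes)) == expected

    def test_empty_pool_rejected(self):
        with pytest.raises(PoolDataError):
            true_pool_frequency(np.array([], dtype=int))


class TestMeasurement:
    def test_no_distortion_no_noise_is_identity(self):
        assert measure_pool(0.37, kappa=1.0, sigma=0.0) == pytest.approx(0.37)

    def test_closed_form_distortion(self):
        # kappa = 2 at p = 0.5: p' = 2*0.5 / (2*0.5 + 0.5) = 2/3
        assert measure_pool(0.5, kappa=2.0, sigma=0.0) == pytest.approx(2.0 / 3.0)

    def test_delta_method_sd_calibration(self, rng):
        draws = measure_pool(np.full(100_000, 0.5), 1.0, 0.05, rng)
        assert 0.045 <= draws.std() <= 0.055

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(0.01, 0.99),
        st.floats(0.01, 0.99),
        st.floats(1.0, 5.0),
        st.floats(1.0, 5.0),
    )
    def test_distortion_monotone_in_p_and_kappa(self, p1, p2, k1, k2):
        lo_p, hi_p = sorted((p1, p2))
        lo_k, hi_k = sorted((k1, k2))
        assert measure_pool(lo_p, hi_k, 0.0) <= measure_pool(hi_p, hi_k, 0.0)
        assert measure_pool(0.5, lo_k, 0.0) <= measure_pool(0.5, hi_k, 0.0)

    def test_monomorphic_passthrough_with_warning(self):
        with pytest.warns(RuntimeWarning, match="monomorphic"):
            assert measure_pool(0.0, 1.5, 0.05) == 0.0
        with pytest.warns(RuntimeWarning):
            assert measure_pool(1.0, 1.5, 0.05) == 1.0


class TestSimulateDataset:
    def test_reproducible_from_seed(self):
        cfg = ScenarioConfig(n_cases=120, J=4, L=3, seed=99)
        t1 = simulate_dataset(cfg)
        t2 = simulate_dataset(cfg)
        np.testing.assert_array_equal(t1.p1, t2.p1)
        np.testing.assert_array_equal(t1.p0, t2.p0)

    def test_shape_matches_scenario(self):
        cfg = ScenarioConfig(n_cases=900, m=1, J=10, L=10, seed=0)
        table = simulate_dataset(cfg)
        assert table.p1.shape == (11, 10)
        assert table.markers[0] == "candidate"

    def test_noiseless_limit_recovers_true_pool_frequencies(self):
        # sigma = 0, kappa = 1: measured frequencies are exact allele
        # fractions, i.e. multiples of 1/(2 * pool size)
        cfg = ScenarioConfig(
            n_cases=100, J=4, L=2, sigma=0.0, kappa_range=(1.0, 1.0), seed=3
        )
        table = simulate_dataset(cfg)

        def is_exact_allele_fraction(col):
            # equals copies / (2 * n_j) for some pool size n_j <= n_cases
            return any(
                np.allclose(col * 2 * nj, np.round(col * 2 * nj), atol=1e-9)
                for nj in range(1, 101)
            )

        assert all(is_exact_allele_fraction(table.p1[:, j]) for j in range(4))
        assert all(is_exact_allele_fraction(table.p0[:, j]) for j in range(4))

    def test_m2_averages_two_control_pools(self, rng):
        # with m = 2 and sigma = 0, kappa = 1, p0 is the mean of two exact
        # allele fractions, so 2 * 2 * pool-size * p0 is an integer
        cfg = ScenarioConfig(
            n_cases=50, m=2, J=2, L=2, sigma=0.0, kappa_range=(1.0, 1.0),
            delta=0.0, seed=8,
        )
        table = simulate_dataset(cfg)
        assert table.p0.shape == (3, 2)

    def test_null_differences_sign_balanced(self):
        """Under perfect matching, no effect and no measurement error the
        candidate pooled differences are symmetric about zero."""
        pos = tot = 0
        for s in range(500):
            cfg = ScenarioConfig(
                n_cases=60, J=3, L=2, delta=0.0, sigma=0.0,
                kappa_range=(1.0, 1.0), effect_size=1.0, seed=s,
            )
            table = simulate_dataset(cfg)
            d = (table.p1 - table.p0)[0]
            pos += (d > 0).sum()
            tot += (d != 0).sum()
        se = np.sqrt(tot * 0.25)
        assert abs(pos - tot / 2) <= 3 * se

    def test_confounding_inflates_naive_test(self):
        """With random matching (delta = 1) and aligned frequency/risk
        gradients, the candidate chi-square referred directly to its
        large-sample reference (no genomic control) rejects far above
        nominal — the bias this design corrects."""
        rej = 0
        n_rep = 200
        for s in range(n_rep):
            cfg = ScenarioConfig(
                n_cases=900, J=10, L=1, delta=1.0, sigma=0.0,
                kappa_range=(1.0, 1.0), effect_size=1.0, seed=10_000 + s,
            )
            table = simulate_dataset(cfg)
            chi2 = chi2_per_marker(build_difference_matrix(table))
            if large_sample_pvalue(chi2[0]) <= 0.05:
                rej += 1
        assert rej / n_rep > 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_model_marker_count_must_match(self, rng):
        cfg = ScenarioConfig(n_cases=100, J=4, L=5)
        model = default_stratum_model(3, rng=rng)
        with pytest.raises(PoolDataError, match="null markers"):
            simulate_dataset(cfg, model=model)
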