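"""Permutation tests: tie rules, enumeration oracles, determinism."""

import itertools

import numpy as np
import pytest

from gfpperm import (
    EmptyConditionError,
    GfppermError,
    IncompatibleDatasetsError,
    PairedGFPPermutation,
    PairedGFPTTest,
    TestConfig,
    UnbalancedGFPPermutation,
    conventional_paired_permutation_test,
    exhaustive_unbalanced_null,
    paired_t_test,
    subject_condition_gfps,
    two_tailed_p,
    unbalanced_paired_permutation_test,
)
from gfpperm.permutation import _shuffled_masks

from conftest import make_dataset


class TestTwoTailedP:
    def test_unique_maximum_of_2000(self):
        null = np.arange(2000.0)
        assert two_tailed_p(null, 1999.0) == pytest.approx(2 / 2000)

    def test_all_ties_capped_at_one(self):
        assert two_tailed_p(np.zeros(50), 0.0) == 1.0

    def test_direct_count(self):
        null = np.array([-3.0, -1.0, 0.0, 2.0, 5.0])
        assert two_tailed_p(null, 2.0) == pytest.approx(0.8)

    def test_observed_must_be_member(self):
        with pytest.raises(GfppermError):
            two_tailed_p(np.array([1.0, 2.0, 3.0]), 2.5)

    def test_p_on_attainable_grid(self):
        rng = np.random.default_rng(0)
        for n in (5, 16, 101):
            null = rng.standard_normal(n)
            p = two_tailed_p(null, null[0])
            assert 0 < p <= 1
            assert (p * n / 2) == pytest.approx(round(p * n / 2))


def brute_force_unbalanced_null(datasets, sign="A_minus_B"):
    """Independent enumeration oracle: every joint within-subject label
    assignment, plain-Python averaging, spatial SD by hand."""

    def gfp(values):
        dev = values - values.mean(axis=0, keepdims=True)
        return np.sqrt((dev**2).mean(axis=0))

    per_subject = []
    for ds in datasets:
        K, n_a = ds.n_trials, int((ds.labels == "A").sum())
        rows = []
        for combo in itertools.combinations(range(K), n_a):
            in_a = np.zeros(K, bool)
            in_a[list(combo)] = True
            d = gfp(ds.data[:, :, in_a].mean(axis=2)) - gfp(
                ds.data[:, :, ~in_a].mean(axis=2)
            )
            rows.append(d if sign == "A_minus_B" else -d)
        per_subject.append(rows)
    entries = []
    for joint in itertools.product(*per_subject):
        entries.append(np.mean(joint, axis=0))
    return np.array(entries)


def exact_p_from_null(entries, observed):
    n = entries.shape[0]
    n_le = (entries <= observed).sum(axis=0)
    n_ge = (entries >= observed).sum(axis=0)
    return np.minimum(1.0, 2 * np.minimum(n_le, n_ge) / n)


class TestUnbalancedTest:
    def test_degenerate_identical_trials(self):
        datasets = []
        for s in range(2):
            ds = make_dataset(C=3, S=4, K=6, n_a=2, seed=s)
            ds.data[:] = ds.data[:, :, :1]  # every trial the same
            datasets.append(ds)
        res = unbalanced_paired_permutation_test(datasets, TestConfig(n_resamples=200, seed=0))
        np.testing.assert_allclose(res.observed, 0.0, atol=1e-12)
        np.testing.assert_array_equal(res.p_values, 1.0)

    def test_matches_exhaustive_enumeration(self):
        # 2 subjects, one channel pair, 3 A + 2 B trials, 1 sample:
        # C(5,3)^2 = 100 joint label assignments
        datasets = [make_dataset(C=2, S=1, K=5, n_a=3, seed=s + 20) for s in range(2)]
        oracle = brute_force_unbalanced_null(datasets)
        assert oracle.shape[0] == 100

        def gfp(values):
            dev = values - values.mean(axis=0, keepdims=True)
            return np.sqrt((dev**2).mean(axis=0))

        observed = np.mean(
            [
                gfp(ds.data[:, :, ds.labels == "A"].mean(axis=2))
                - gfp(ds.data[:, :, ds.labels == "B"].mean(axis=2))
                for ds in datasets
            ],
            axis=0,
        )
        p_exact = exact_p_from_null(oracle, observed)

        R = 2000
        res = unbalanced_paired_permutation_test(datasets, TestConfig(n_resamples=R, seed=7))
        np.testing.assert_allclose(res.observed, observed, atol=1e-12)
        q = p_exact / 2  # smaller-tail proportion; p doubles it
        se = 2 * np.sqrt(q * (1 - q) / R)
        assert np.all(np.abs(res.p_values - p_exact) <= 3 * se + 2 / R)

        # the package's own exhaustive enumeration agrees with the oracle
        pkg_null = exhaustive_unbalanced_null(datasets)
        np.testing.assert_allclose(
            np.sort(pkg_null, axis=0), np.sort(oracle, axis=0), atol=1e-12
        )

    def test_default_resamples_is_2000(self):
        assert TestConfig().n_resamples == 2000
        assert TestConfig().alpha == 0.05

    def test_label_counts_conserved_in_every_resample(self):
        rng = np.random.default_rng(3)
        base = np.zeros(17, bool)
        base[:5] = True
        masks = _shuffled_masks(rng, base, 400)
        assert masks.shape == (400, 17)
        np.testing.assert_array_equal(masks.sum(axis=1), 5)

    def test_incompatible_datasets_rejected(self):
        a = make_dataset(C=3, S=4, K=6, n_a=2, seed=0)
        b = make_dataset(C=4, S=4, K=6, n_a=2, seed=1)
        with pytest.raises(IncompatibleDatasetsError):
            unbalanced_paired_permutation_test([a, b])

    def test_missing_condition_rejected(self):
        a = make_dataset(C=3, S=4, K=6, n_a=2, seed=0)
        b = make_dataset(C=3, S=4, K=6, n_a=0, seed=1)
        with pytest.raises(EmptyConditionError):
            unbalanced_paired_permutation_test([a, b])

    def test_determinism_and_model_front_end(self, miniature_group):
        cfg = TestConfig(n_resamples=300, seed=42)
        r1 = unbalanced_paired_permutation_test(miniature_group, cfg)
        r2 = unbalanced_paired_permutation_test(miniature_group, cfg)
        np.testing.assert_array_equal(r1.null_distribution, r2.null_distribution)
        np.testing.assert_array_equal(r1.p_values, r2.p_values)
        r3 = UnbalancedGFPPermutation(miniature_group, n_resamples=300).fit(seed=42)
        np.testing.assert_array_equal(r1.null_distribution, r3.null_distribution)

    def test_sign_convention_flips_observed_not_p(self, miniature_group):
        a = unbalanced_paired_permutation_test(
            miniature_group, TestConfig(n_resamples=200, seed=1, sign_convention="A_minus_B")
        )
        b = unbalanced_paired_permutation_test(
            miniature_group, TestConfig(n_resamples=200, seed=1, sign_convention="B_minus_A")
        )
        np.testing.assert_allclose(a.observed, -b.observed)
        np.testing.assert_array_equal(a.p_values, b.p_values)


class TestConventionalPermutation:
    def test_identical_conditions_give_p_one(self):
        g = np.random.default_rng(0).standard_normal((4, 3))
        res = conventional_paired_permutation_test(g, g, TestConfig(n_resamples=64))
        np.testing.assert_allclose(res.observed, 0.0)
        np.testing.assert_array_equal(res.p_values, 1.0)

    def test_three_subject_exhaustive(self):
        # differences [1, 2, 3]: 2^3 = 8 sign patterns, observed mean 2
        # attained once at the maximum -> two-tailed p = 2/8
        gfp_b = np.zeros((3, 1))
        gfp_a = np.array([[1.0], [2.0], [3.0]])
        res = conventional_paired_permutation_test(gfp_a, gfp_b, TestConfig(n_resamples=2000))
        assert res.null_distribution.shape == (8, 1)
        assert res.p_values[0] == pytest.approx(0.25)

    def test_thirteen_subjects_use_random_subset(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((2, 13, 2))
        res = conventional_paired_permutation_test(a, b, TestConfig(n_resamples=2000, seed=0))
        assert res.null_distribution.shape == (2000, 2)

    def test_monte_carlo_matches_enumeration(self):
        # N=12: 4096 > 2000 resamples forces the random-subset path
        rng = np.random.default_rng(8)
        N, R = 12, 2000
        a = rng.standard_normal((N, 2))
        b = rng.standard_normal((N, 2))
        diffs = a - b
        signs = 1 - 2 * ((np.arange(2**N)[:, None] >> np.arange(N)[None, :]) & 1)
        exact_null = signs @ diffs / N
        p_exact = exact_p_from_null(exact_null, diffs.mean(axis=0))
        res = conventional_paired_permutation_test(a, b, TestConfig(n_resamples=R, seed=5))
        q = p_exact / 2  # smaller-tail proportion; p doubles it
        se = 2 * np.sqrt(q * (1 - q) / R)
        assert np.all(np.abs(res.p_values - p_exact) <= 3 * se + 2 / R)

    def test_model_front_end_deterministic(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal((2, 13, 3))
        r1 = PairedGFPPermutation(a, b, n_resamples=500).fit(seed=9)
        r2 = PairedGFPPermutation(a, b, n_resamples=500).fit(seed=9)
        np.testing.assert_array_equal(r1.null_distribution, r2.null_distribution)


class TestPairedT:
    def test_zero_differences(self):
        g = np.ones((4, 3))
        res = paired_t_test(g, g)
        np.testing.assert_array_equal(res.t, 0.0)
        np.testing.assert_array_equal(res.p_values, 1.0)

    def test_hand_computed_t(self):
        gfp_b = np.zeros((3, 1))
        gfp_a = np.array([[1.0], [2.0], [3.0]])
        res = paired_t_test(gfp_a, gfp_b)
        assert res.df == 2
        assert res.t[0] == pytest.approx(2 * np.sqrt(3))
        from scipy import stats

        assert res.p_values[0] == pytest.approx(2 * stats.t.sf(2 * np.sqrt(3), 2))

    def test_df_is_subjects_minus_one(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal((2, 13, 4))
        assert paired_t_test(a, b).df == 12

    def test_zero_variance_nonzero_mean_flagged(self):
        a = np.full((3, 2), 2.0)
        b = np.zeros((3, 2))
        res = paired_t_test(a, b)
        assert np.all(res.zero_variance)
        np.testing.assert_array_equal(res.p_values, 0.0)

    def test_model_front_end(self, miniature_group):
        res = PairedGFPTTest.from_datasets(miniature_group).fit()
        gfp_a, gfp_b = subject_condition_gfps(miniature_group)
        ref = paired_t_test(gfp_a, gfp_b)
        np.testing.assert_allclose(res.t, ref.t)
        assert "p_value" in res.summary().columns
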