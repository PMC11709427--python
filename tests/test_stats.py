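"""Block permutation t-test and BY FDR: oracles, calibration, invariants."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from wormpheno.stats import (StatsConfig, benjamini_yekutieli,
                             block_permutation_matrix,
                             block_permutation_ttest,
                             block_permutation_ttest_matrix, compare_groups,
                             n_block_arrangements)
from wormpheno.synthetic_data import (EffectSpec, ExperimentDesign,
                                      generate_feature_experiment)


def exhaustive_p_oracle(x, y, days_x, days_y):
    """Brute-force two-sided exact p over all within-day label assignments."""
    vals = np.concatenate([x, y])
    days = np.concatenate([days_x, days_y])
    in_a = np.concatenate([np.ones(len(x), bool), np.zeros(len(y), bool)])

    def welch_t(mask):
        a, b = vals[mask], vals[~mask]
        return (a.mean() - b.mean()) / np.sqrt(
            a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))

    t_obs = abs(welch_t(in_a))
    per_day = []
    for d in np.unique(days):
        idx = np.flatnonzero(days == d)
        k = int(in_a[idx].sum())
        per_day.append(list(itertools.combinations(idx, k)))
    count = total = 0
    for combo in itertools.product(*per_day):
        mask = np.zeros(len(vals), bool)
        for c in combo:
            mask[list(c)] = True
        total += 1
        if abs(welch_t(mask)) >= t_obs - 1e-12:
            count += 1
    return count / total, total


def by_adjust_oracle(p):
    """Independent BY step-up: adj_(i) = min_{j>=i} min(1, c(m) m p_(j)/j)."""
    p = np.asarray(p, float)
    m = len(p)
    c = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p)
    raw = p[order] * c * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(raw[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


class TestPermutationTest:
    def test_identical_groups_null_identity(self):
        t, p = block_permutation_ttest([1, 2, 3, 4], [1, 2, 3, 4],
                                       [1, 1, 2, 2], [1, 1, 2, 2])
        assert t == 0.0
        assert p == 1.0

    def test_exhaustive_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.normal(1.0, 1.0, 6)
            y = rng.normal(0.0, 1.0, 6)
            days = np.array([1, 1, 2, 2, 3, 3])
            p_oracle, total = exhaustive_p_oracle(x, y, days, days)
            t, p = block_permutation_ttest(x, y, days, days)
            assert total == 6 ** 3  # C(4,2) per day over three days
            assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_monte_carlo_matches_exhaustive_within_binomial_error(self):
        rng = np.random.default_rng(1)
        days = np.array([1, 1, 2, 2])
        for i in range(20):
            x = rng.normal(0.8, 1.0, 4)
            y = rng.normal(0.0, 1.0, 4)
            _, p_ex = block_permutation_ttest(
                x, y, days, days, StatsConfig(exhaustive_threshold=100))
            cfg = StatsConfig(n_permutations=4000, exhaustive_threshold=1,
                              rng_seed=i)
            _, p_mc = block_permutation_ttest(x, y, days, days, cfg)
            se = math.sqrt(p_ex * (1 - p_ex) / 4000)
            assert abs(p_mc - p_ex) <= 3 * se + 1.5 / 4000

    def test_monte_carlo_p_never_zero(self):
        # complete separation: p bounded below by 1/(n_perm+1)
        x = np.arange(6) + 100.0
        y = np.arange(6) * 1.0
        days = np.array([1, 1, 2, 2, 3, 3])
        cfg = StatsConfig(n_permutations=200, exhaustive_threshold=1,
                          rng_seed=0)
        _, p = block_permutation_ttest(x, y, days, days, cfg)
        assert p >= 1.0 / 201
        # and the exhaustive minimum is 2/R (complement symmetry)
        _, p_ex = block_permutation_ttest(x, y, days, days,
                                          StatsConfig(exhaustive_threshold=10_000))
        assert p_ex == pytest.approx(2.0 / 6 ** 3)

    def test_permutations_respect_day_blocks(self):
        days = np.array([1, 1, 1, 2, 2, 2, 2, 3, 3])
        in_a = np.array([1, 1, 0, 1, 1, 0, 0, 1, 0], bool)
        for cfg in (StatsConfig(exhaustive_threshold=10_000),
                    StatsConfig(n_permutations=500, exhaustive_threshold=1)):
            P, _ = block_permutation_matrix(days, in_a, cfg)
            for d in np.unique(days):
                sel = days == d
                counts = P[:, sel].sum(axis=1)
                assert np.all(counts == in_a[sel].sum())

    def test_zero_variance_flagged_undefined(self):
        X = np.column_stack([np.ones(8), np.arange(8.0)])
        in_a = np.array([1, 1, 0, 0, 1, 1, 0, 0], bool)
        days = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        res = block_permutation_ttest_matrix(X, in_a, days)
        assert res.undefined[0]
        assert np.isnan(res.p[0])
        assert not res.undefined[1]

    def test_one_sided_day_warns(self):
        days = np.array([1, 1, 2, 2])
        in_a = np.array([1, 1, 1, 0], bool)
        with pytest.warns(UserWarning, match="one group"):
            block_permutation_matrix(days, in_a, StatsConfig())

    def test_welch_t_matches_scipy_on_observed_grouping(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 9), rng.normal(1, 2, 9)
        days = np.tile([1, 2, 3], 3)
        t, _ = block_permutation_ttest(x, y, days, days)
        t_ref = sps.ttest_ind(x, y, equal_var=False).statistic
        assert t == pytest.approx(t_ref, rel=1e-12)

    def test_monotone_power_in_effect_size(self):
        """Rejection rate at alpha=0.05 is non-decreasing in planted |d|."""
        rates = []
        for d in (0.0, 0.5, 1.0, 2.0, 3.0):
            rej = 0
            n_rep = 60
            rng = np.random.default_rng(int(d * 10))
            for _ in range(n_rep):
                days = np.tile([1, 2, 3], 3)
                x = rng.normal(d, 1.0, 9)
                y = rng.normal(0.0, 1.0, 9)
                _, p = block_permutation_ttest(x, y, days, days)
                rej += p < 0.05
            rates.append(rej / n_rep)
        assert all(b >= a - 0.1 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > 0.9
        assert rates[0] < 0.15


class TestBenjaminiYekutieli:
    def test_all_ones_no_rejections(self):
        adj, rej = benjamini_yekutieli(np.ones(20))
        assert not rej.any()

    def test_matches_bruteforce_formula(self):
        p = np.array([0.001, 0.01, 0.2, 0.9])
        adj, _ = benjamini_yekutieli(p)
        np.testing.assert_allclose(adj, by_adjust_oracle(p), atol=1e-12)

    def test_single_test_passthrough(self):
        adj, _ = benjamini_yekutieli([0.03])
        assert adj[0] == pytest.approx(0.03)  # c(1) = 1

    def test_random_vectors_match_oracle(self):
        rng = np.random.default_rng(3)
        for m in (5, 100, 1000):
            p = rng.uniform(size=m) ** 2
            adj, rej = benjamini_yekutieli(p, q=0.05)
            oracle = by_adjust_oracle(p)
            assert np.max(np.abs(adj - oracle)) < 1e-12
            np.testing.assert_array_equal(rej, oracle < 0.05)

    def test_adjusted_monotone_and_geq_raw(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=50)
        adj, _ = benjamini_yekutieli(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_nan_excluded_from_m(self):
        p = np.array([0.001, np.nan, 0.5])
        adj, rej = benjamini_yekutieli(p)
        assert np.isnan(adj[1]) and not rej[1]
        # m=2, c(2)=1.5
        assert adj[0] == pytest.approx(0.001 * 1.5 * 2 / 1)


class TestCompareGroups:
    def test_planted_feature_recovered(self, small_experiment):
        tables, meta, truth = small_experiment
        res = compare_groups(tables, meta, "mut_DMSO", "N2_DMSO")
        sig = set(res.significant_features)
        assert {"ft0001@prestim", "ft0001@bluelight",
                "ft0001@poststim"} <= sig
        # direction matches the planted positive shift
        assert res.table.loc["ft0001@prestim", "direction"] == 1.0

    def test_null_strains_no_significant_features(self, null_experiment):
        tables, meta, _ = null_experiment
        res = compare_groups(tables, meta, "mut_DMSO", "N2_DMSO")
        assert res.n_significant == 0

    def test_bad_wells_excluded(self, small_experiment):
        tables, meta, _ = small_experiment
        meta2 = meta.copy()
        flagged = meta2.loc[meta2["group"] == "mut_DMSO", "well_id"].iloc[0]
        meta2.loc[meta2["well_id"] == flagged, "bad_well"] = True
        res = compare_groups(tables, meta2, "mut_DMSO", "N2_DMSO")
        assert res.table["n_a"].iloc[0] == 8

    def test_missing_group_errors(self, small_experiment):
        tables, meta, _ = small_experiment
        with pytest.raises(ValueError, match="usable wells"):
            compare_groups(tables, meta, "nope", "N2_DMSO")

    def test_type_one_error_calibrated_quick(self):
        """Null features with strong day batch effects reject at ~alpha."""
        design = ExperimentDesign(n_features_per_period=400, seed=123)
        tables, meta, _ = generate_feature_experiment(
            design, EffectSpec(day_sd=2.0, noise_sd=1.0))
        res = compare_groups(tables, meta, "mut_DMSO", "N2_DMSO")
        rate = (res.table["p"] < 0.05).mean()  # 1200 null features
        se = math.sqrt(0.05 * 0.95 / len(res.table))
        assert abs(rate - 0.05) < 4 * se + 0.005
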