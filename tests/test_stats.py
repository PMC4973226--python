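"""Mann-Whitney U, cluster permutation test, induced duration, paired t."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from tmsalpha import (
    PowerTimecourse,
    SimulationConfig,
    cluster_permutation_test,
    compare_durations,
    induced_duration,
    mann_whitney_u,
    trial_envelope_profile,
)
from tmsalpha.stats import _u_statistic


def brute_force_mw_p(x, y):
    """Independent oracle: enumerate every labeling of the pooled sample."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n = x.size
    u_obs = _u_statistic(x, y)
    us = []
    for c in combinations(range(pooled.size), n):
        mask = np.zeros(pooled.size, bool)
        mask[list(c)] = True
        us.append(_u_statistic(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    p = 2 * min((us <= u_obs + 1e-12).mean(), (us >= u_obs - 1e-12).mean())
    return min(1.0, p)


class TestMannWhitney:
    def test_fully_separated_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert p == 1.0

    def test_singletons(self):
        u, p = mann_whitney_u([0], [1])
        assert (u, p) == (0.0, 1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_matches_scipy_cross_check(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=5), rng.normal(size=4)
        _, p = mann_whitney_u(x, y, mode="exact")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_exact_vs_normal_approx_close_at_n8(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            x, y = rng.normal(size=8), rng.normal(0.4, 1.0, size=8)
            pe = mann_whitney_u(x, y, mode="exact")[1]
            pa = mann_whitney_u(x, y, mode="approx")[1]
            assert abs(pe - pa) < 0.02

    def test_ties_handled_in_approximation(self):
        x = [1.0, 1.0, 2.0, 2.0, 3.0] * 3
        y = [1.0, 2.0, 2.0, 3.0, 3.0] * 3
        _, p = mann_whitney_u(x, y, mode="approx")
        assert 0.0 < p <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])


class TestClusterPermutation:
    def test_identical_conditions_give_no_clusters(self, rng):
        a = rng.standard_normal((6, 40))
        res = cluster_permutation_test(a, a.copy(), n_perm=500)
        assert res.clusters == []
        np.testing.assert_array_equal(res.t_trace, 0.0)

    def test_constant_shift_full_extent_exact_p(self, rng):
        a = np.tile(np.linspace(0, 1, 30), (8, 1)) + rng.normal(0, 0.1, (8, 30))
        res = cluster_permutation_test(a, a + 50.0, n_perm=10000)
        assert res.full_enumeration and res.n_permutations == 256
        assert len(res.clusters) == 1
        c = res.clusters[0]
        assert (c.start, c.stop) == (0, 29)
        assert c.p == pytest.approx(2 / 256)

    def test_subject_permutation_invariance(self, rng):
        a = rng.standard_normal((7, 50))
        b = a + rng.normal(0.5, 0.3, size=(7, 1))
        r1 = cluster_permutation_test(a, b, n_perm=5000)
        perm = rng.permutation(7)
        r2 = cluster_permutation_test(a[perm], b[perm], n_perm=5000)
        assert [(c.start, c.stop, c.p) for c in r1.clusters] == [
            (c.start, c.stop, c.p) for c in r2.clusters
        ]

    def test_full_enumeration_seed_independent(self, rng):
        a = rng.standard_normal((6, 40))
        b = a + rng.normal(0.4, 0.2, size=(6, 1))
        r1 = cluster_permutation_test(a, b, n_perm=1000, seed=1)
        r2 = cluster_permutation_test(a, b, n_perm=1000, seed=999)
        assert [c.p for c in r1.clusters] == [c.p for c in r2.clusters]

    def test_matches_full_sign_flip_enumeration_oracle(self, rng):
        # independent oracle: explicit loop over all 2^n sign patterns with
        # per-pattern scipy t-tests and a direct run scan
        n, t_len = 6, 25
        a = rng.standard_normal((n, t_len))
        b = a + rng.normal(0.6, 0.4, size=(n, t_len))
        res = cluster_permutation_test(a, b, n_perm=10000)
        diff = a - b
        thr = float(sps.t.ppf(0.975, n - 1))

        def max_mass(d):
            tt = sps.ttest_1samp(d, 0.0, axis=0).statistic
            best, cur, cur_sign = 0.0, 0.0, 0
            for v in tt:
                s = 1 if v > thr else (-1 if v < -thr else 0)
                if s != 0 and s == cur_sign:
                    cur += v
                elif s != 0:
                    cur, cur_sign = v, s
                else:
                    cur, cur_sign = 0.0, 0
                best = max(best, abs(cur))
            return best

        signs_iter = [
            [1 if s == 0 else -1 for s in pattern] for pattern in np.ndindex(*(2,) * n)
        ]
        null = np.array(
            [max_mass(np.array(s)[:, None] * diff) for s in signs_iter]
        )
        for c in res.clusters:
            expected = (null >= abs(c.mass) - 1e-9).mean()
            assert c.p == pytest.approx(expected, abs=1e-12)

    def test_full_enumeration_p_never_below_identity_bound(self, rng):
        # comparison against a constant reference with large offsets stresses
        # the sum-of-squares arithmetic; the identity sign pattern is part of
        # the enumerated null, so p >= 1/2^n always
        a = 100 + rng.standard_normal((10, 250)).cumsum(axis=1)
        b = np.tile(a.mean(axis=1, keepdims=True) - 30.0, (1, 250))
        res = cluster_permutation_test(a, b, n_perm=2000)
        assert res.full_enumeration
        assert res.clusters
        for c in res.clusters:
            assert c.p >= 1 / 1024

    def test_p_values_bounded_below(self, rng):
        a = rng.standard_normal((12, 30))
        b = a + 10.0 + rng.normal(0, 0.1, size=(12, 30))
        res = cluster_permutation_test(a, b, n_perm=999, seed=3)
        assert not res.full_enumeration
        for c in res.clusters:
            assert c.p >= 1 / (999 + 1)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="subjects"):
            cluster_permutation_test(np.ones((1, 10)), np.zeros((1, 10)))


def power_trace(values, fs=250.0):
    times = -2.0 + np.arange(len(values)) / fs
    return PowerTimecourse(np.asarray(values, float), times)


def profile_trace(duration, amp_pct=40.0, fs=250.0, ripple=0.02):
    """Rest level + deterministic ERD->ERS profile, tiny rest ripple for sd>0."""
    cfg = SimulationConfig(seed=0)
    times = -2.0 + np.arange(int(6 * fs)) / fs
    values = np.full(times.size, 5.0)
    values += 5.0 * ripple * np.sin(2 * np.pi * 1.7 * times)  # rest-window sd
    prof = trial_envelope_profile(7.0, 5.0, amp_pct, duration, cfg, sampling_rate=fs)
    i0 = int(np.searchsorted(times, 0.0))
    n = min(prof.size, times.size - i0)
    values[i0 : i0 + n] = prof[:n]
    return PowerTimecourse(values, times)


class TestInducedDuration:
    def test_sub_threshold_everywhere_gives_zero(self):
        # sinusoidal ripple peaks at sqrt(2) sigma < 1.96 sigma: never supra
        t = np.arange(1500) / 250.0
        est = induced_duration(power_trace(5.0 + 0.1 * np.sin(2 * np.pi * 1.3 * t)))
        assert est.duration == 0.0
        assert est.supra_runs == []

    def test_single_run_of_half_second(self):
        values = np.full(1500, 1.0)
        times = -2.0 + np.arange(1500) / 250.0
        values[(times >= -1.9) & (times <= -0.5)] += np.resize([0.01, -0.01], 351)
        values[(times > 1.0) & (times <= 1.5)] = 2.0  # 125 samples = 0.5 s
        est = induced_duration(PowerTimecourse(values, times))
        assert est.duration == pytest.approx(0.5, abs=1 / 250.0)

    def test_longest_run_rule_and_total_variant(self):
        values = np.full(1500, 1.0)
        times = -2.0 + np.arange(1500) / 250.0
        values[(times >= -1.9) & (times <= -0.5)] += np.resize([0.01, -0.01], 351)
        values[(times > 0.5) & (times <= 0.8)] = 2.0
        values[(times > 2.0) & (times <= 2.6)] = 2.0
        tc = PowerTimecourse(values, times)
        assert induced_duration(tc).duration == pytest.approx(0.6, abs=1 / 250.0)
        assert induced_duration(tc, rule="total").duration == pytest.approx(
            0.9, abs=2 / 250.0
        )

    def test_threshold_is_two_sided_five_percent_normal(self):
        est = induced_duration(profile_trace(1.0))
        assert est.threshold == pytest.approx(
            round(float(sps.norm.ppf(0.975)), 2)
        )

    def test_zero_rest_sd_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            induced_duration(power_trace(np.full(1500, 2.0)))

    def test_profile_duration_recovered(self):
        est = induced_duration(profile_trace(1.0))
        assert est.duration == pytest.approx(1.0, abs=0.15)

    def test_monotone_in_generating_duration(self):
        durations = [0.3, 0.5, 0.8, 1.08, 1.5, 2.0]
        estimates = [induced_duration(profile_trace(d)).duration for d in durations]
        assert all(a <= b + 1e-9 for a, b in zip(estimates, estimates[1:]))


class TestCompareDurations:
    def test_identical_gives_t_zero_p_one(self):
        d = np.array([1.0, 0.8, 1.2, 0.9])
        assert compare_durations(d, d) == (0.0, 1.0)

    def test_constant_difference_rejected(self):
        a = np.array([1.0, 2.0, 0.5, 1.5, 3.0])
        with pytest.raises(ValueError, match="variance"):
            compare_durations(a + 0.25, a)  # binary-exact constant shift

    def test_matches_closed_form_and_scipy(self):
        diff = np.array([0.1, 0.3, 0.2, 0.4, 0.5])
        b = np.array([1.0, 1.1, 0.9, 1.2, 1.0])
        t, p = compare_durations(b + diff, b)
        expected_t = diff.mean() / (diff.std(ddof=1) / np.sqrt(5))
        assert t == pytest.approx(expected_t)
        ref = sps.ttest_rel(b + diff, b)
        assert t == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))

    def test_near_equal_samples_give_large_p(self, rng):
        a = rng.normal(1.0, 0.3, size=8)
        t, p = compare_durations(a, a + rng.normal(0, 1e-3, size=8))
        assert p > 0.3
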