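"""Rescue-ratio statistics, rank-sum test and trajectory summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from spbkit.phospho_stats import (
    GroupComparison,
    classify_rescue,
    localization_breakdown,
    max_phospho_ratio,
    median_trajectory_ci,
    rank_sum_test,
    rescue_percentages,
)


def ranksum_enumeration_oracle(a, b):
    """Exhaustive-enumeration two-sided Mann-Whitney p for tie-free data.

    Enumerates every assignment of the pooled values into groups of sizes
    (n_a, n_b) and counts assignments at least as extreme (by tail
    probability) as observed.
    """
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n_a):
        grp = [pooled[i] for i in comb]
        rest = [pooled[i] for i in range(len(pooled)) if i not in comb]
        us.append(sum(1 for x in grp for y in rest if x > y))
    us = np.array(us)
    u_obs = sum(1 for x in a for y in b if x > y)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(lo, hi))


class TestMaxPhosphoRatio:
    def test_worked_example(self):
        assert max_phospho_ratio(
            [1.0, 1.5, 1.8, 1.6], [1.0, 1.2, 1.5, 1.4]
        ) == pytest.approx(1.2)

    def test_identical_trajectories_give_one(self):
        t = [1.0, 2.3, 0.7]
        assert max_phospho_ratio(t, t) == 1.0

    def test_matches_bruteforce_oracle_on_random_trajectories(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a = rng.lognormal(size=5)
            b = rng.lognormal(size=5)
            brute = max(a) / max(b)  # independent elementwise maximum
            assert max_phospho_ratio(a, b) == brute

    def test_mismatched_timepoints_error(self):
        with pytest.raises(ValueError):
            max_phospho_ratio([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_invariant_common_rescaling(self):
        rng = np.random.default_rng(1)
        a, b = rng.lognormal(size=5), rng.lognormal(size=5)
        r = max_phospho_ratio(a, b)
        assert max_phospho_ratio(3.7 * a, 3.7 * b) == pytest.approx(r, rel=1e-12)

    def test_monotonicity(self):
        a = np.array([1.0, 1.4, 1.2])
        b = np.array([1.0, 1.1, 1.3])
        r = max_phospho_ratio(a, b)
        a_up = a.copy()
        a_up[1] *= 1.5
        assert max_phospho_ratio(a_up, b) >= r
        b_up = b.copy()
        b_up[2] *= 1.5
        assert max_phospho_ratio(a, b_up) <= r


class TestClassifyRescue:
    @pytest.mark.parametrize(
        "r,expected",
        [(1.2, "increased"), (1.19, "not_increased"), (1.2 - 1e-9, "not_increased"),
         (5.0, "increased")],
    )
    def test_threshold_inclusive(self, r, expected):
        out = classify_rescue(pd.Series([r], index=["e1"]))
        assert out.loc[0, "rescue_class"] == expected

    def test_percentages_within_class(self):
        ratios = pd.Series(
            [1.3, 1.25, 1.0, 1.1, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
            index=[f"e{i}" for i in range(10)],
        )
        ann = pd.DataFrame(
            {"event_id": [f"e{i}" for i in range(10)],
             "hp_class": ["HP_sensitive"] * 10,
             "localization": ["unknown"] * 10}
        )
        res = classify_rescue(ratios, ann)
        assert rescue_percentages(res)["HP_sensitive"] == pytest.approx(20.0)


class TestRankSum:
    def test_separated_groups_exact(self):
        gc = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert gc.method == "exact"
        assert gc.U == 0
        assert gc.p_two_sided == pytest.approx(0.1)

    def test_interleaved_groups_p_one(self):
        gc = rank_sum_test([1, 4], [2, 3])
        assert gc.U == gc.n_a * gc.n_b / 2
        assert gc.p_two_sided == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n_a = rng.integers(1, 5)
            n_b = rng.integers(1, 11 - n_a)
            pooled = rng.permutation(np.arange(1, n_a + n_b + 1, dtype=float))
            a, b = pooled[:n_a], pooled[n_a:]
            gc = rank_sum_test(a, b, mode="exact")
            assert gc.p_two_sided == pytest.approx(
                ranksum_enumeration_oracle(a, b), abs=1e-12
            )

    def test_normal_close_to_exact_at_n10(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            pooled = rng.permutation(np.arange(1, 21, dtype=float))
            a, b = pooled[:10], pooled[10:]
            p_norm = rank_sum_test(a, b, mode="normal").p_two_sided
            p_exact = rank_sum_test(a, b, mode="exact").p_two_sided
            assert abs(p_norm - p_exact) < 0.01

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=8)
        b = rng.normal(size=6)
        g1 = rank_sum_test(a, b)
        g2 = rank_sum_test(b, a)
        assert g1.U + g2.U == pytest.approx(g1.n_a * g1.n_b)
        assert g1.p_two_sided == pytest.approx(g2.p_two_sided)

    def test_ties_force_normal_path(self):
        gc = rank_sum_test([1, 1, 2], [2, 3, 3], mode="auto")
        assert gc.method == "normal"

    def test_identical_values_warns_p_one(self):
        with pytest.warns(UserWarning):
            gc = rank_sum_test([2.0, 2.0], [2.0, 2.0, 2.0])
        assert gc.p_two_sided == 1.0


class TestMedianTrajectoryCI:
    def test_degenerate_identical_trajectories_zero_width(self):
        data = np.tile([1.0, 1.5, 2.0], (10, 1))
        out = median_trajectory_ci(data, n_boot=500, seed=0)
        assert np.allclose(out["ci_low"], out["median"])
        assert np.allclose(out["ci_high"], out["median"])

    def test_seeded_repeatability(self):
        rng = np.random.default_rng(0)
        data = rng.lognormal(size=(30, 4))
        a = median_trajectory_ci(data, n_boot=1000, seed=7)
        b = median_trajectory_ci(data, n_boot=1000, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_requires_two_trajectories(self):
        with pytest.raises(ValueError):
            median_trajectory_ci(np.ones((1, 4)), seed=0)

    def test_coverage_near_nominal(self):
        """95% percentile-bootstrap CI covers the true median ~95% of the
        time over simulation replicates (small-n demo of the invariant)."""
        rng = np.random.default_rng(123)
        curve = np.array([1.0, 1.4, 1.9, 2.1])
        covered = 0
        n_rep = 60
        for _ in range(n_rep):
            data = curve * rng.lognormal(
                mean=0.0, sigma=0.2, size=(50, 1)
            )
            out = median_trajectory_ci(data, n_boot=800,
                                       seed=int(rng.integers(2**31)))
            true_median = curve * 1.0  # median of lognormal factor is 1
            covered += np.mean(
                (out["ci_low"] <= true_median) & (true_median <= out["ci_high"])
            )
        coverage = covered / n_rep
        assert 0.85 <= coverage <= 1.0


class TestLocalizationBreakdown:
    def test_medians_and_partition(self):
        res = pd.DataFrame(
            {
                "event_id": list("abcdef"),
                "R": [1.0, 1.3, 1.5, 2.0, 0.9, 1.1],
                "rescue_class": ["x"] * 6,
                "hp_class": ["HP_sensitive"] * 6,
                "localization": ["SPB_MT"] * 3 + ["cytoplasm"] * 2 + ["unknown"],
            }
        )
        out = localization_breakdown(res)
        spb = out[out["localization"] == "SPB_MT"].iloc[0]
        assert spb["median_R"] == pytest.approx(1.3)
        assert out["n"].sum() == len(res)
        assert "nucleus" not in set(out["localization"])
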