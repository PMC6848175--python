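from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfnbs import (
    anova_f_from_summary,
    bh_fdr,
    glm_f,
    pairwise_posthoc,
    permutation_p,
    spearman_assoc,
    two_sample_t,
    two_sample_t_from_summary,
)
from tfnbs.glm import f_statistics


def _rss_oracle_f(y, groups, covariates=None):
    """Partial F via explicit projection matrices (independent route)."""
    y = np.asarray(y, float)
    levels = sorted(set(groups))
    dummies = np.column_stack([(np.asarray(groups) == g).astype(float) for g in levels[1:]])
    cov = () if covariates is None else (np.asarray(covariates, float).reshape(len(y), -1),)
    full = np.column_stack([np.ones(len(y)), dummies, *cov])
    reduced = np.column_stack([np.ones(len(y)), *cov])

    def rss(x):
        proj = x @ np.linalg.pinv(x)
        r = y - proj @ y
        return float(r @ r)

    df1 = len(levels) - 1
    df2 = len(y) - full.shape[1]
    return ((rss(reduced) - rss(full)) / df1) / (rss(full) / df2)


def _two_point_sample(mean, sd, n):
    """n values with exactly the requested mean and sample SD."""
    half = n // 2
    delta = sd * np.sqrt((n - 1) / n)
    values = np.r_[np.full(half, mean + delta), np.full(n - half, mean - delta)]
    if n % 2:  # odd n: adjust spread keeping the mean exact
        values = mean + (values - values.mean())
        values = mean + (values - mean) * sd / values.std(ddof=1)
    return values


class TestGlmF:
    def test_gender_distribution_statistic(self):
        """One-way GLM F on the 0/1 gender codes of the three groups."""
        y = np.r_[np.ones(26), np.zeros(28), np.ones(48), np.zeros(17), np.ones(19), np.zeros(12)]
        groups = np.r_[["HC"] * 54, ["PD"] * 65, ["MSA"] * 31]
        assert glm_f(y, groups) == pytest.approx(4.2921, abs=5e-4)

    def test_zero_between_group_variation_gives_zero(self):
        y = np.r_[1.0, 2.0, 1.0, 2.0, 1.0, 2.0]
        groups = np.array(["a", "a", "b", "b", "c", "c"])
        assert glm_f(y, groups) == pytest.approx(0.0, abs=1e-12)

    def test_matches_projection_matrix_oracle(self):
        rng = np.random.default_rng(0)
        groups = np.array(["a"] * 8 + ["b"] * 6 + ["c"] * 7)
        for _ in range(5):
            y = rng.normal(size=21)
            cov = rng.normal(size=21)
            assert glm_f(y, groups) == pytest.approx(_rss_oracle_f(y, groups), abs=1e-10)
            assert glm_f(y, groups, cov) == pytest.approx(
                _rss_oracle_f(y, groups, cov), abs=1e-10
            )

    @settings(max_examples=20, deadline=None)
    @given(
        a=st.floats(min_value=0.1, max_value=50),
        b=st.floats(min_value=-100, max_value=100),
    )
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(1)
        y = rng.normal(size=15)
        groups = np.array(["x"] * 5 + ["y"] * 5 + ["z"] * 5)
        assert glm_f(a * y + b, groups) == pytest.approx(glm_f(y, groups), rel=1e-9)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(12, 7))
        groups = np.array(["a"] * 6 + ["b"] * 6)
        f, df1, df2 = f_statistics(y, groups)
        assert df1 == 1 and df2 == 10
        for j in range(7):
            assert f[j] == pytest.approx(glm_f(y[:, j], groups), abs=1e-10)

    def test_rank_deficient_design_rejected(self):
        groups = np.array(["a"] * 4 + ["b"] * 4)
        cov = (groups == "b").astype(float)  # collinear with the group dummy
        with pytest.raises(ValueError):
            glm_f(np.arange(8.0), groups, cov)


class TestSummaryStatistics:
    def test_education_years_statistic(self):
        f = anova_f_from_summary([12.63, 12.48, 10.68], [4.3, 5.4, 3.8], [54, 65, 31])
        assert f == pytest.approx(1.9333, abs=0.01)  # printed inputs are rounded

    def test_equal_means_give_zero(self):
        assert anova_f_from_summary([5, 5, 5], [1, 2, 3], [10, 10, 10]) == 0.0

    def test_agrees_with_glm_on_exact_summary_data(self):
        means, sds, ns = [3.0, 5.0, 4.2], [1.1, 0.7, 2.0], [10, 12, 8]
        y = np.concatenate([_two_point_sample(m, s, n) for m, s, n in zip(means, sds, ns)])
        groups = np.concatenate([[g] * n for g, n in zip("abc", ns)])
        assert anova_f_from_summary(means, sds, ns) == pytest.approx(
            glm_f(y, groups), abs=1e-8
        )

    def test_disease_duration_statistic(self):
        t = two_sample_t_from_summary(8.26, 6.02, 65, 4.46, 2.75, 31)
        assert t == pytest.approx(3.3466, abs=0.01)

    def test_identical_samples_give_zero_t(self):
        assert two_sample_t([1, 2, 3, 4.0], [4, 3, 2, 1.0]) == pytest.approx(0.0)

    def test_t_squared_equals_two_group_f(self):
        t = two_sample_t_from_summary(8.26, 6.02, 65, 4.46, 2.75, 31)
        f = anova_f_from_summary([8.26, 4.46], [6.02, 2.75], [65, 31])
        assert t**2 == pytest.approx(f, rel=1e-10)

    def test_degenerate_variance_signalled(self):
        with pytest.raises(ValueError):
            anova_f_from_summary([1, 2], [0, 0], [5, 5])
        with pytest.raises(ValueError):
            two_sample_t_from_summary(1, 0, 5, 2, 0, 5)


class TestPermutationP:
    def test_constant_outcome_gives_p_one(self):
        y = np.ones(10)
        groups = np.array(["a"] * 5 + ["b"] * 5)
        stat, p = permutation_p(y, groups, n_permutations=99, seed=0)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_exact_enumeration_matches_brute_force(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=6)
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        stat, p = permutation_p(y, groups, method="exact")
        exceed = 0
        total = 0
        for perm in permutations(range(6)):
            total += 1
            exceed += glm_f(y, groups[list(perm)]) >= stat - 1e-12
        assert p == exceed / total

    def test_montecarlo_converges_to_exact(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=6)
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        _, p_exact = permutation_p(y, groups, method="exact")
        _, p_mc = permutation_p(y, groups, n_permutations=20000, seed=1)
        assert p_mc == pytest.approx(p_exact, abs=0.02)

    def test_strong_separation_hits_floor(self):
        y = np.r_[np.zeros(20), np.full(20, 5.0)] + np.random.default_rng(8).normal(
            scale=1.0, size=40
        )
        groups = np.array(["a"] * 20 + ["b"] * 20)
        _, p = permutation_p(y, groups, n_permutations=2000, seed=2)
        assert p == 1 / 2001

    def test_p_never_below_floor(self):
        y = np.arange(8.0)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        _, p = permutation_p(y, groups, n_permutations=50, seed=3)
        assert 1 / 51 <= p <= 1.0

    def test_null_rejection_rate_is_nominal(self):
        """Uncorrected permutation test rejects ~5% of null datasets."""
        rng = np.random.default_rng(9)
        groups = np.array(["a"] * 10 + ["b"] * 10)

        def mean_diff(y, g, _):
            return abs(y[g == "a"].mean() - y[g == "b"].mean())

        rejections = 0
        reps = 1000
        for _ in range(reps):
            y = rng.normal(size=20)
            _, p = permutation_p(
                y, groups, stat_fn=mean_diff, n_permutations=199, seed=int(rng.integers(2**31))
            )
            rejections += p <= 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestFdr:
    def test_all_ones_never_rejected(self):
        reject, adjusted = bh_fdr(np.ones(20))
        assert not reject.any()
        assert (adjusted == 1).all()

    def test_worked_example_matches_step_up_oracle(self):
        p = np.array([
            0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216,
            0.222, 0.251, 0.269, 0.275, 0.34, 0.341, 0.384, 0.569, 0.594, 0.696,
            0.762, 0.94, 0.942, 0.975, 0.986,
        ])
        reject, adjusted = bh_fdr(p, q=0.05)
        # direct step-up: largest k with p_(k) <= qk/m (here only k=1 since
        # p_(2)=0.008 > 2*0.05/25), then reject the k smallest p-values
        sorted_p = np.sort(p)
        k = max(
            (i + 1 for i in range(p.size) if sorted_p[i] <= 0.05 * (i + 1) / p.size),
            default=0,
        )
        assert k == 1
        assert reject.sum() == k
        assert reject[np.argsort(p)[:k]].all()
        # step-up adjusted p is monotone in the sorted order
        assert (np.diff(adjusted[np.argsort(p)]) >= -1e-12).all()

    def test_null_false_discovery_rate_controlled(self):
        rng = np.random.default_rng(10)
        fdp = []
        for _ in range(1000):
            p = rng.uniform(size=153)
            reject, _ = bh_fdr(p, q=0.05)
            fdp.append(reject.mean() > 0)  # any rejection is a false discovery
        assert np.mean(fdp) <= 0.07  # FWER = FDR under the global null

    def test_empty_and_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([]))
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.0, 0.5]))


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.array([1.0, 2, 3, 5, 8])
        r, _ = spearman_assoc(x, np.exp(x))
        assert r == pytest.approx(1.0)
        r, _ = spearman_assoc(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r, _ = spearman_assoc(x, y)
        rx = np.argsort(np.argsort(x)).astype(float)
        ry = np.argsort(np.argsort(y)).astype(float)
        assert r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_assoc(np.ones(5), np.arange(5.0))


class TestPairwisePosthoc:
    def test_two_group_contrast_reduces_to_pooled_t(self):
        rng = np.random.default_rng(12)
        values = rng.normal(size=(20, 1))
        groups = np.array(["HC"] * 10 + ["MSA"] * 10)
        frame = pairwise_posthoc(
            values, groups, gender=None, names=["e"], pairs=(("HC", "MSA"),),
            n_permutations=99, seed=0,
        )
        expected = two_sample_t(values[10:, 0], values[:10, 0])  # MSA minus HC
        assert frame.loc[0, "t"] == pytest.approx(expected, rel=1e-10)

    def test_identical_groups_rarely_significant(self):
        rng = np.random.default_rng(13)
        hits = 0
        for rep in range(40):
            values = rng.normal(size=(24, 5))
            groups = np.array(["HC"] * 8 + ["PD"] * 8 + ["MSA"] * 8)
            frame = pairwise_posthoc(
                values, groups, gender=None, names=list("abcde"),
                n_permutations=199, seed=rep,
            )
            hits += frame["significant"].any()
        assert hits <= 6  # ≥85% of null replicates are clean

    def test_missing_group_rejected(self):
        values = np.zeros((4, 1))
        groups = np.array(["HC"] * 4)
        with pytest.raises(ValueError):
            pairwise_posthoc(values, groups, None, ["e"], pairs=(("HC", "MSA"),))
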