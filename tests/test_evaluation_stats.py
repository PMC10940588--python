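"""Split protocol, combination harness, ranking and the statistical tests."""

import numpy as np
import pytest
from scipy import stats as spstats

from sozmark.evaluation_stats import (
    EvalResult,
    SplitSpec,
    accuracy,
    delong_test,
    majority_vote,
    make_splits,
    mann_whitney_test,
    mcnemar_test,
    roc_auc,
    run_combination,
    top_quantile_intersection,
)
from sozmark.gnn_classifier import GAConfig
from sozmark.pipeline import CohortFeatures


class TestMakeSplits:
    def test_exact_fractions_n10(self):
        train, test, verif = make_splits(10, SplitSpec(seed=0), 0)
        assert (len(train), len(test), len(verif)) == (7, 1, 2)

    def test_cohort79_rounding_rule(self):
        train, test, verif = make_splits(79, SplitSpec(seed=0), 0)
        assert (len(verif), len(test), len(train)) == (16, 8, 55)

    def test_verification_fixed_across_repeats(self):
        spec = SplitSpec(seed=4)
        _, _, v0 = make_splits(30, spec, 0)
        _, _, v1 = make_splits(30, spec, 1)
        assert np.array_equal(v0, v1)
        t0, _, _ = make_splits(30, spec, 0)
        t1, _, _ = make_splits(30, spec, 1)
        assert not np.array_equal(t0, t1)  # train/test re-divided per repeat

    def test_partitions_disjoint_and_exhaustive(self):
        train, test, verif = make_splits(23, SplitSpec(seed=2), 3)
        combined = np.sort(np.concatenate([train, test, verif]))
        assert np.array_equal(combined, np.arange(23))

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            make_splits(4, SplitSpec(seed=0), 0)


class TestAccuracy:
    def test_examples(self):
        assert accuracy([1, 1, 0, 1], [1, 1, 0, 0]) == 0.75
        assert accuracy([1, 0], [1, 0]) == 1.0

    def test_matches_count_oracle(self, rng):
        p = rng.integers(0, 2, 50)
        y = rng.integers(0, 2, 50)
        assert accuracy(p, y) == sum(int(a == b) for a, b in zip(p, y)) / 50

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy([], [])


def _signal_features(rng, n=30, noise=0.3):
    """CohortFeatures with a planted linear signal in two markers."""
    y = np.array([0, 1] * (n // 2))
    feats = {}
    for mk in ("pow_gamma", "fragility"):
        X = rng.standard_normal((n, 20))
        X[:, :3] += 2.0 * y[:, None] + noise * rng.standard_normal((n, 3))
        feats[mk] = X
    return CohortFeatures(
        patient_ids=[f"p{i}" for i in range(n)],
        y=y,
        features=feats,
        sex=["M"] * n,
        handedness=["R"] * n,
    )


class TestRunCombination:
    def test_deterministic_given_master_seed(self, rng):
        feats = _signal_features(rng)
        spec = SplitSpec(seed=1)
        kw = dict(repeats=3, ga_config=GAConfig(population_size=10, generations=10))
        r1 = run_combination("pow_gamma", "GNN", feats, spec, **kw)
        r2 = run_combination("pow_gamma", "GNN", feats, spec, **kw)
        assert r1.traintest_accuracies == r2.traintest_accuracies
        assert r1.verification_probabilities == r2.verification_probabilities

    def test_easy_signal_reaches_high_verification_accuracy(self, rng):
        feats = _signal_features(rng, noise=0.1)
        res = run_combination("pow_gamma", "LR", feats, SplitSpec(seed=3), repeats=5)
        assert res.mean_verification >= 0.9

    def test_shuffled_labels_fall_to_chance(self, rng):
        feats = _signal_features(rng)
        feats.y = np.random.default_rng(99).permutation(feats.y)
        res = run_combination("pow_gamma", "LR", feats, SplitSpec(seed=3), repeats=5)
        maj = max(feats.y.mean(), 1 - feats.y.mean())
        assert abs(res.mean_verification - maj) <= 0.35  # binomial noise at n_ver=6


def _result(cid, tt, ver):
    return EvalResult(combination=cid, marker_id=cid.split("+")[0],
                      model_id=cid.split("+")[1],
                      traintest_accuracies=[tt], verification_accuracies=[ver])


class TestTopQuantileIntersection:
    def test_identical_rankings_return_top_set(self):
        results = [_result(f"m{i}+LR", i / 10, i / 10) for i in range(8)]
        top = top_quantile_intersection(results, q=0.25)
        assert top == {"m7+LR", "m6+LR"}

    def test_disjoint_top_sets_intersect_empty(self):
        results = [
            _result("a+LR", 0.9, 0.1),
            _result("b+LR", 0.8, 0.2),
            _result("c+LR", 0.1, 0.9),
            _result("d+LR", 0.2, 0.8),
        ]
        assert top_quantile_intersection(results, q=0.25) == set()

    def test_constructed_overlap_of_three(self):
        # 12 combinations; top-3 by each metric share exactly c0, c1, c2
        results = []
        for i in range(3):
            results.append(_result(f"c{i}+LR", 0.9 + i / 100, 0.9 + i / 100))
        results.append(_result("ttonly+LR", 0.99, 0.1))
        results.append(_result("veronly+LR", 0.1, 0.99))
        for i in range(7):
            results.append(_result(f"mid{i}+LR", 0.5, 0.5))
        # top-3 tt: ttonly, c2, c1 ; top-3 ver: veronly, c2, c1 -> overlap c1,c2
        top = top_quantile_intersection(results, q=0.25)
        assert top == {"c1+LR", "c2+LR"}

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            top_quantile_intersection([])


class TestMcNemar:
    def test_symmetric_discordance_gives_p_one(self):
        a = np.array([True] * 3 + [False] * 3 + [True] * 4)
        b = np.array([False] * 3 + [True] * 3 + [True] * 4)
        stat, p = mcnemar_test(a, b)
        assert p == 1.0

    def test_exact_binomial_value(self):
        # b=1, c=9 -> p = 2 * P(X <= 1), X ~ Bin(10, 1/2) = 22/1024
        a = np.array([True] * 1 + [False] * 9 + [True] * 5)
        b = np.array([False] * 1 + [True] * 9 + [True] * 5)
        _, p = mcnemar_test(a, b)
        assert p == pytest.approx(22 / 1024, abs=1e-12)

    def test_no_discordance_convention(self):
        a = np.array([True, False, True])
        _, p = mcnemar_test(a, a)
        assert p == 1.0

    def test_matches_statsmodels_exact(self, rng):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        a = rng.random(40) < 0.6
        b = rng.random(40) < 0.6
        _, p = mcnemar_test(a, b)
        table = [
            [np.sum(a & b), np.sum(a & ~b)],
            [np.sum(~a & b), np.sum(~a & ~b)],
        ]
        sm = sm_mcnemar(table, exact=True)
        assert p == pytest.approx(float(sm.pvalue), abs=1e-12)


class TestDeLong:
    def test_identical_scores_give_p_one(self, rng):
        y = np.array([0, 1] * 10)
        s = rng.random(20)
        auc_a, auc_b, p = delong_test(s, s, y)
        assert auc_a == auc_b and p == 1.0

    def test_perfect_scores_have_unit_auc(self):
        y = np.array([0] * 5 + [1] * 5)
        s = np.concatenate([np.linspace(0, 0.4, 5), np.linspace(0.6, 1, 5)])
        auc_a, _, _ = delong_test(s, 1 - s, y)
        assert auc_a == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            delong_test([0.1, 0.2], [0.3, 0.4], [1, 1])

    def test_detects_clear_auc_difference(self):
        rng = np.random.default_rng(11)
        y = np.array([0, 1] * 100)
        good = y + 0.5 * rng.standard_normal(200)
        bad = rng.standard_normal(200)
        _, _, p = delong_test(good, bad, y)
        assert p < 0.001


class TestMannWhitney:
    def test_all_tied_groups_give_p_one(self):
        u, p = mann_whitney_test([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_fully_separated_five_vs_five(self):
        u, p = mann_whitney_test([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert u == 0.0
        assert p == pytest.approx(2 / 252, abs=1e-12)

    def test_u_statistics_sum_identity(self, rng):
        a = rng.standard_normal(9)
        b = rng.standard_normal(7)
        ua, _ = mann_whitney_test(a, b)
        ub, _ = mann_whitney_test(b, a)
        assert ua + ub == pytest.approx(len(a) * len(b))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_test([], [1.0])


class TestRocAuc:
    def test_perfect_and_inverted_classifiers(self):
        y = np.array([0, 0, 1, 1])
        (_, _), auc = roc_auc([0.1, 0.2, 0.8, 0.9], y)
        assert auc == 1.0
        (_, _), auc_inv = roc_auc([0.9, 0.8, 0.2, 0.1], y)
        assert auc_inv == 0.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(17)
        y = rng.integers(0, 2, 1000)
        (_, _), auc = roc_auc(rng.random(1000), y)
        assert 0.45 <= auc <= 0.55

    def test_equals_mann_whitney_identity(self, rng):
        y = np.array([0, 1] * 25)
        s = rng.random(50)
        (_, _), auc = roc_auc(s, y)
        u = spstats.mannwhitneyu(s[y == 1], s[y == 0], alternative="two-sided").statistic
        assert auc == pytest.approx(u / (25 * 25), abs=1e-12)


class TestTypeOneCalibration:
    def test_mcnemar_and_mannwhitney_hold_level_under_null(self):
        """Across 500 simulated nulls both tests reject at most ~5% of the
        time at alpha = 0.05."""
        rng = np.random.default_rng(123)
        rej_mc = rej_mw = 0
        n_sim = 500
        for _ in range(n_sim):
            a = rng.random(16) < 0.7
            b = rng.random(16) < 0.7
            if mcnemar_test(a, b)[1] < 0.05:
                rej_mc += 1
            x = rng.standard_normal(8)
            z = rng.standard_normal(8)
            if mann_whitney_test(x, z)[1] < 0.05:
                rej_mw += 1
        assert rej_mc / n_sim <= 0.06
        assert rej_mw / n_sim <= 0.06


class TestMajorityVote:
    def test_pools_repeats_per_patient(self):
        res = EvalResult(combination="x+LR", marker_id="x", model_id="LR",
                         verification_predictions=[[1, 0, 1], [1, 1, 0], [1, 0, 0]])
        assert majority_vote(res).tolist() == [1, 0, 0]
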