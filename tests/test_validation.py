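"""Split plans, balancing, grid search, metrics, calibration, statistics."""

import itertools
import time

import numpy as np
import pytest

from lfpdecode.baselines import ClassifierSpec, build_classifier
from lfpdecode.validation import (
    balance_by_downsampling,
    bootstrap_resample,
    evaluate_probabilities,
    fisher_exact_vs_chance,
    fit_platt,
    grid_search_cv,
    make_split_plan,
    measure_runtime,
    paired_wilcoxon,
    platt_calibrate,
)


class TestSplitPlan:
    def test_four_mice_ten_bootstraps_forty_evaluations(self):
        plan = make_split_plan(["a", "b", "c", "d"], n_bootstraps=10, seed=0)
        assert len(plan) == 40
        per_mouse = {m: 0 for m in "abcd"}
        for s in plan.splits:
            per_mouse[s.held_out_mouse] += 1
            assert s.held_out_mouse not in s.training_mice
        assert all(v == 10 for v in per_mouse.values())

    def test_two_mice_one_bootstrap(self):
        plan = make_split_plan(["a", "b"], n_bootstraps=1, seed=0)
        assert len(plan) == 2

    def test_single_mouse_rejected(self):
        with pytest.raises(ValueError, match="2 mice"):
            make_split_plan(["only"], seed=0)

    def test_plan_deterministic(self):
        a = make_split_plan(["a", "b", "c"], seed=5)
        b = make_split_plan(["a", "b", "c"], seed=5)
        assert a.splits == b.splits

    def test_training_multisets_identical_across_algorithms(self):
        """For a fixed split, the balance+bootstrap draw depends only on the
        bootstrap seed, so two consumers see byte-identical multisets."""
        labels = np.array([0] * 30 + [1] * 50)
        plan = make_split_plan(["a", "b"], n_bootstraps=3, seed=1)
        for split in plan.splits:
            draws = []
            for _consumer in range(2):
                rng = np.random.default_rng(split.bootstrap_seed)
                bal = balance_by_downsampling(labels, rng)
                draws.append(bootstrap_resample(bal, rng).tobytes())
            assert draws[0] == draws[1]


class TestBalancing:
    def test_majority_downsampled_to_minority(self, rng):
        labels = np.array([1] * 100 + [0] * 60)
        idx = balance_by_downsampling(labels, rng)
        assert (labels[idx] == 1).sum() == 60
        assert (labels[idx] == 0).sum() == 60

    def test_already_balanced_unchanged(self, rng):
        labels = np.repeat([0, 1], 50)
        idx = balance_by_downsampling(labels, rng)
        assert np.array_equal(idx, np.arange(100))

    def test_absent_class_rejected(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            balance_by_downsampling(np.zeros(10), rng)


class TestGridSearch:
    def _glm_builder(self, params):
        return build_classifier(ClassifierSpec("GLM", params))

    def test_singleton_grid_returned(self, rng):
        X = rng.standard_normal((30, 2))
        y = (X[:, 0] > 0).astype(int)
        best, _ = grid_search_cv(self._glm_builder, [{"C": 2.0}], X, y)
        assert best == {"C": 2.0}

    def test_degenerate_point_rejected_on_solvable_data(self, rng):
        """A stump cannot express XOR structure; the deeper tree wins."""
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]] * 15, dtype=float)
        X += rng.normal(0, 0.05, X.shape)
        y = np.array([0, 1, 1, 0] * 15)

        def build(params):
            return build_classifier(ClassifierSpec("DT", params, seed=0))

        grid = [{"max_depth": 1}, {"max_depth": 3}]
        best, table = grid_search_cv(build, grid, X, y, seed=0)
        assert best == {"max_depth": 3}
        assert table[1][1] > table[0][1]

    def test_same_seed_same_selection(self, rng):
        X = rng.standard_normal((40, 3))
        y = rng.integers(0, 2, 40)
        grid = [{"C": 0.1}, {"C": 1.0}]
        r1 = grid_search_cv(self._glm_builder, grid, X, y, seed=9)
        r2 = grid_search_cv(self._glm_builder, grid, X, y, seed=9)
        assert r1 == r2

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError, match="fold"):
            grid_search_cv(self._glm_builder, [{"C": 1.0}], np.zeros((2, 2)),
                           np.array([0, 1]), k=3)


def brute_roc_auc(proba, y):
    pos = proba[y == 1]
    neg = proba[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_average_precision(proba, y):
    order = np.argsort(-proba, kind="stable")
    proba, y = proba[order], y[order]
    ap, tp = 0.0, 0
    n_pos = y.sum()
    last_recall = 0.0
    for thr in np.unique(proba)[::-1]:
        mask = proba >= thr
        tp = y[mask].sum()
        precision = tp / mask.sum()
        recall = tp / n_pos
        ap += (recall - last_recall) * precision
        last_recall = recall
    return ap


class TestMetrics:
    def test_perfect_probabilities(self):
        y = np.array([0, 1, 1, 0, 1])
        rep = evaluate_probabilities(y.astype(float), y)
        assert rep.accuracy == 1.0 and rep.brier == 0.0 and rep.roc_auc == 1.0

    def test_uninformative_half_probability_brier(self):
        y = np.repeat([0, 1], 10)
        rep = evaluate_probabilities(np.full(20, 0.5), y)
        assert rep.brier == pytest.approx(0.25)

    def test_random_scores_auc_near_half(self):
        r = np.random.default_rng(3)
        y = np.repeat([0, 1], 1000)
        rep = evaluate_probabilities(r.uniform(size=2000), y)
        assert abs(rep.roc_auc - 0.5) < 0.03

    def test_single_class_test_set_warns(self):
        with pytest.warns(UserWarning, match="single-class"):
            rep = evaluate_probabilities(np.array([0.2, 0.8]), np.array([1, 1]))
        assert rep.roc_auc is None and rep.pr_auc is None

    def test_roc_pr_brier_match_brute_force(self):
        """sklearn-backed metrics equal exhaustive oracles on small inputs."""
        r = np.random.default_rng(11)
        for _ in range(20):
            n = int(r.integers(6, 50))
            y = np.zeros(n, dtype=int)
            y[r.choice(n, size=max(1, n // 3), replace=False)] = 1
            if y.sum() in (0, n):
                continue
            proba = r.uniform(size=n).round(2)  # ties included
            rep = evaluate_probabilities(proba, y)
            assert rep.roc_auc == pytest.approx(brute_roc_auc(proba, y), abs=1e-12)
            assert rep.pr_auc == pytest.approx(brute_average_precision(proba, y), abs=1e-12)
            assert rep.brier == pytest.approx(np.mean((proba - y) ** 2), abs=1e-12)


class TestPlatt:
    @staticmethod
    def _probs(n, rng, miscalibrated):
        true_p = rng.uniform(0.05, 0.95, n)
        y = (rng.uniform(size=n) < true_p).astype(int)
        if miscalibrated:  # overconfident: logits stretched x3
            logits = 3 * np.log(true_p / (1 - true_p))
            scores = 1 / (1 + np.exp(-logits))
        else:
            scores = true_p
        return scores, y

    def test_reduces_brier_of_overconfident_probabilities(self):
        rng = np.random.default_rng(0)
        scores, y = self._probs(2000, rng, miscalibrated=True)
        cal = fit_platt(scores, y)
        before = np.mean((scores - y) ** 2)
        after = np.mean((cal(scores) - y) ** 2)
        assert after < before

    def test_leaves_calibrated_probabilities_nearly_unchanged(self):
        rng = np.random.default_rng(1)
        scores, y = self._probs(2000, rng, miscalibrated=False)
        cal = fit_platt(scores, y)
        before = np.mean((scores - y) ** 2)
        after = np.mean((cal(scores) - y) ** 2)
        assert abs(after - before) < 0.02

    def test_calibrator_monotone(self):
        rng = np.random.default_rng(2)
        scores, y = self._probs(500, rng, miscalibrated=True)
        cal = fit_platt(scores, y)
        p = np.linspace(0, 1, 101)
        assert np.all(np.diff(cal(p)) >= 0)

    def test_primary_model_refit_on_two_thirds(self, rng):
        X = rng.standard_normal((300, 3))
        y = (X[:, 0] + 0.3 * rng.standard_normal(300) > 0).astype(int)
        seen = {}

        class Probe:
            def fit(self, Xf, yf):
                seen["n"] = len(yf)
                self._m = build_classifier(ClassifierSpec("GLM")).fit(Xf, yf)
                return self

            def predict_proba(self, Xp):
                return self._m.predict_proba(Xp)

        model, cal = platt_calibrate(Probe, X, y, seed=0)
        assert seen["n"] == 200  # 67 % of 300
        assert callable(cal)

    def test_single_class_holdout_rejected(self):
        X = np.zeros((12, 2))
        y = np.array([0] * 11 + [1])
        with pytest.raises(ValueError):
            platt_calibrate(lambda: build_classifier(ClassifierSpec("GLM")), X, y, seed=0)


def wilcoxon_exact_oracle(diffs):
    """Enumerate all sign assignments of |d| ranks; two-sided exact p."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    n = len(diffs)
    ranks = np.argsort(np.argsort(np.abs(diffs))) + 1.0
    t_plus = ranks[diffs > 0].sum()
    dist = []
    for signs in itertools.product([0, 1], repeat=n):
        dist.append(sum(r for s, r in zip(signs, ranks) if s))
    dist = np.array(dist)
    p_le = np.mean(dist <= t_plus)
    p_ge = np.mean(dist >= t_plus)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_identical_samples_undefined(self):
        assert paired_wilcoxon([1, 2, 3], [1, 2, 3]) is None

    def test_eight_positive_pairs_exact_p(self):
        a = np.arange(1, 9, dtype=float)
        b = a - np.linspace(0.5, 1.5, 8)
        assert paired_wilcoxon(a, b) == pytest.approx(2 / 256)

    def test_symmetry(self, rng):
        a = rng.standard_normal(12)
        b = rng.standard_normal(12)
        assert paired_wilcoxon(a, b) == pytest.approx(paired_wilcoxon(b, a))

    def test_matches_enumeration_oracle(self):
        r = np.random.default_rng(5)
        for _ in range(10):
            n = int(r.integers(4, 11))
            a = r.standard_normal(n)
            b = a + r.standard_normal(n)  # continuous: no ties, no zeros
            assert paired_wilcoxon(a, b) == pytest.approx(
                wilcoxon_exact_oracle(a - b), abs=1e-12
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_wilcoxon([1.0, 2.0], [1.0])


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by hypergeometric enumeration."""
    from math import comb

    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = comb(n, row1)

    def prob(x):
        return comb(col1, x) * comb(n - col1, row1 - x) / denom

    p_obs = prob(a)
    lo = max(0, row1 - (n - col1))
    hi = min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs + 1e-12)


class TestFisher:
    def test_exactly_chance_gives_p_one(self):
        assert fisher_exact_vs_chance(5, 10) == pytest.approx(1.0)

    def test_perfect_small_sample_matches_enumeration(self):
        p = fisher_exact_vs_chance(10, 10)
        assert p == pytest.approx(fisher_oracle(10, 0, 5, 5), abs=1e-12)

    def test_monotone_decreasing_above_chance(self):
        ps = [fisher_exact_vs_chance(c, 10) for c in range(5, 11)]
        assert all(q <= p + 1e-12 for p, q in zip(ps, ps[1:]))

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_vs_chance(0, 0)


class TestRuntime:
    def test_sleep_normalized_per_sample(self):
        _, per_sample = measure_runtime(lambda: time.sleep(0.2), 20)
        assert per_sample == pytest.approx(0.01, rel=0.2)

    def test_single_sample_is_raw_duration(self):
        _, per_sample = measure_runtime(lambda: time.sleep(0.05), 1)
        assert per_sample == pytest.approx(0.05, rel=0.3)

    def test_invalid_sample_count(self):
        with pytest.raises(ValueError):
            measure_runtime(lambda: None, 0)
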