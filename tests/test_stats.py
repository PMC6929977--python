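"""Statistical toolbox: agreement, ROC/Youden, CART, exact tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sersmeth.errors import CapacityError, DataError
from sersmeth.stats import (
    bland_altman,
    cart_fit,
    cart_predict,
    cohort_report,
    confusion_metrics,
    fisher_exact,
    roc_youden,
    tree_to_dict,
    tree_to_text,
)
from sersmeth.synthetic import CohortConfig, simulate_cohort


class TestBlandAltman:
    def test_identical_pairs(self):
        stats = bland_altman([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert stats.mean_diff == 0.0
        assert stats.max_abs_diff == 0.0

    def test_hand_arithmetic(self):
        stats = bland_altman([0.10, 0.50, 0.80], [0.12, 0.47, 0.80])
        assert stats.mean_diff == pytest.approx((-0.02 + 0.03 + 0.00) / 3)
        assert stats.max_abs_diff == pytest.approx(0.03)
        assert stats.max_abs_diff >= abs(stats.mean_diff)

    def test_limits_cover_95pct_of_gaussian_differences(self):
        rng = np.random.default_rng(0)
        n = 10_000
        truth = rng.uniform(0, 1, n)
        est = truth + rng.normal(0, 0.05, n)
        stats = bland_altman(est, truth)
        inside = np.mean(
            (stats.diffs >= stats.lower_limit) & (stats.diffs <= stats.upper_limit)
        )
        # binomial 3-sigma band around 0.95 at n=1e4
        assert inside >= 0.95 - 3 * math.sqrt(0.95 * 0.05 / n)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            bland_altman([0.1], [0.1, 0.2])


def exhaustive_youden(scores, labels):
    """Independent scan: evaluate J on every threshold between observations."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    candidates = [-np.inf, np.inf]
    srt = np.unique(s)
    candidates += [(a + b) / 2 for a, b in zip(srt[:-1], srt[1:])]
    best = None
    for t in sorted(candidates):
        pred = s >= t
        sens = (pred & y).sum() / y.sum()
        spec = (~pred & ~y).sum() / (~y).sum()
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    return best


class TestRocYouden:
    def test_perfect_separation(self):
        res = roc_youden([1, 2, 3, 4], [0, 0, 1, 1])
        assert 2 < res.youden_optimal_threshold < 3
        assert res.sensitivity_at_optimum == 1.0
        assert res.specificity_at_optimum == 1.0
        assert res.auc == pytest.approx(1.0)

    def test_tie_broken_toward_sensitivity(self):
        # two thresholds reach J=0.5; the lower one (sens=1, spec=0.5) wins
        res = roc_youden([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        j, t, sens, spec = exhaustive_youden([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert res.sensitivity_at_optimum + res.specificity_at_optimum - 1 == pytest.approx(j)
        assert res.sensitivity_at_optimum == 1.0
        assert res.specificity_at_optimum == 0.5
        assert res.youden_optimal_threshold == pytest.approx(t)

    def test_matches_exhaustive_scan_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = rng.integers(4, 50)
            scores = np.round(rng.normal(size=n), 2)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            res = roc_youden(scores, labels)
            j, t, sens, spec = exhaustive_youden(scores, labels)
            got_j = res.sensitivity_at_optimum + res.specificity_at_optimum - 1
            assert got_j == pytest.approx(j, abs=1e-12)
            assert res.youden_optimal_threshold == pytest.approx(t)

    def test_auc_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = rng.integers(10, 80)
            scores = rng.normal(size=n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            res = roc_youden(scores, labels)
            assert res.auc == pytest.approx(
                sklearn_metrics.roc_auc_score(labels, scores), abs=1e-10
            )

    def test_sensitivity_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        res = roc_youden(scores, labels)
        assert np.all(np.diff(res.sensitivity) <= 1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_youden([1.0, 2.0], [1, 1])


def exhaustive_gini_root(X: pd.DataFrame, y: np.ndarray):
    """Independent search over every (feature, midpoint) split at the root."""

    def gini(lbl):
        if lbl.size == 0:
            return 0.0
        _, c = np.unique(lbl, return_counts=True)
        p = c / lbl.size
        return 1 - (p**2).sum()

    best = None
    for feat in X.columns:
        v = X[feat].to_numpy(float)
        u = np.unique(v)
        for thr in (u[:-1] + u[1:]) / 2:
            mask = v < thr
            score = (mask.sum() * gini(y[mask]) + (~mask).sum() * gini(y[~mask])) / y.size
            if best is None or score < best[0] - 1e-15:
                best = (score, feat, thr)
    return best


class TestCart:
    def test_separable_single_feature(self):
        x = np.linspace(0, 1, 20)
        X = pd.DataFrame({"f": x})
        y = (x > 0.5).astype(int)
        tree = cart_fit(X, y, min_leaf=1, max_depth=5)
        assert not tree.is_leaf and tree.left.is_leaf and tree.right.is_leaf
        assert np.array_equal(cart_predict(tree, X), y)

    def test_xor_needs_depth_two(self):
        X = pd.DataFrame(
            {"a": [0, 0, 1, 1] * 3, "b": [0, 1, 0, 1] * 3}, dtype=float
        )
        y = (X["a"].to_numpy() != X["b"].to_numpy()).astype(int)
        tree = cart_fit(X, y, min_leaf=1, max_depth=2)
        assert np.array_equal(cart_predict(tree, X), y)
        # root split matches the exhaustive search (tie resolved by feature order)
        _, feat, thr = exhaustive_gini_root(X, y)
        assert tree.feature == feat
        assert tree.threshold == pytest.approx(thr)

    def test_pure_input_is_single_leaf(self):
        X = pd.DataFrame({"f": np.arange(10.0)})
        tree = cart_fit(X, np.ones(10, dtype=int), min_leaf=1, max_depth=3)
        assert tree.is_leaf
        assert tree.prediction == 1

    def test_root_split_matches_exhaustive_search_on_random_data(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["x1", "x2", "x3"])
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            tree = cart_fit(X, y, min_leaf=1, max_depth=1)
            best = exhaustive_gini_root(X, y)
            assert tree.feature == best[1]
            assert tree.threshold == pytest.approx(best[2])

    def test_training_accuracy_100pct_on_separable_data(self):
        sklearn_tree = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.uniform(size=(40, 2)), columns=["u", "v"])
        y = ((X["u"] > 0.4) & (X["v"] > 0.3)).astype(int).to_numpy()
        if y.min() == y.max():  # ensure both classes
            y[0] = 1 - y[0]
        tree = cart_fit(X, y, min_leaf=1, max_depth=10)
        assert np.array_equal(cart_predict(tree, X), y)
        # cross-check: sklearn CART also attains 100% under the same limits
        clf = sklearn_tree.DecisionTreeClassifier(random_state=0).fit(X, y)
        assert clf.score(X, y) == 1.0

    def test_min_leaf_respected(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"f": rng.normal(size=30)})
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        tree = cart_fit(X, y, min_leaf=5, max_depth=4)

        def check(node):
            if node.is_leaf:
                assert sum(node.counts.values()) >= 5
            else:
                check(node.left)
                check(node.right)

        check(tree)

    def test_serialization_round_trip_shapes(self):
        X = pd.DataFrame({"f": np.arange(20.0)})
        y = (np.arange(20) >= 10).astype(int)
        tree = cart_fit(X, y, min_leaf=1, max_depth=2)
        text = tree_to_text(tree)
        assert "if f <" in text
        d = tree_to_dict(tree)
        assert d["feature"] == "f"
        assert "left" in d and "right" in d

    def test_empty_features_rejected(self):
        with pytest.raises(DataError):
            cart_fit(pd.DataFrame(index=range(10)), np.zeros(10))


def brute_force_fisher(table: np.ndarray) -> float:
    """Independent enumeration via itertools over all candidate tables."""
    table = np.asarray(table, dtype=int)
    rows, cols = table.sum(1), table.sum(0)
    n = table.sum()

    def prob(t):
        num = sum(math.lgamma(x + 1) for x in rows) + sum(
            math.lgamma(x + 1) for x in cols
        )
        den = math.lgamma(n + 1) + sum(math.lgamma(x + 1) for x in t.flat)
        return math.exp(num - den)

    p_obs = prob(table)
    total = 0.0
    r, c = table.shape
    # only the top-left (r-1) x (c-1) block is free; margins force the rest
    free_ranges = [
        range(min(rows[i], cols[j]) + 1)
        for i in range(r - 1)
        for j in range(c - 1)
    ]
    for flat in itertools.product(*free_ranges):
        t = np.zeros((r, c), dtype=int)
        t[: r - 1, : c - 1] = np.array(flat).reshape(r - 1, c - 1)
        t[: r - 1, c - 1] = rows[: r - 1] - t[: r - 1, : c - 1].sum(1)
        t[r - 1, :] = cols - t[: r - 1, :].sum(0)
        if (t >= 0).all():
            p = prob(t)
            if p <= p_obs * (1 + 1e-9):
                total += p
    return total


class TestFisherExact:
    def test_uniform_table_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_enumeration_value_34_over_70(self):
        assert fisher_exact([[3, 1], [1, 3]]) == pytest.approx(34 / 70, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(DataError):
            fisher_exact([[0, 0], [1, 2]])

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            fisher_exact([[1, -1], [2, 3]])

    def test_matches_scipy_on_2x2(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            t = rng.integers(1, 12, size=(2, 2))
            ours = fisher_exact(t)
            _, scipy_p = sps.fisher_exact(t, alternative="two-sided")
            assert ours == pytest.approx(scipy_p, abs=1e-10)

    def test_matches_brute_force_on_rxc(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            t = rng.integers(1, 6, size=(rng.integers(2, 4), rng.integers(2, 4)))
            assert fisher_exact(t) == pytest.approx(brute_force_fisher(t), abs=1e-10)

    def test_capacity_guard(self):
        big = np.full((3, 4), 30)  # total 360 > budget
        with pytest.raises(CapacityError):
            fisher_exact(big)


class TestConfusionMetrics:
    def test_perfect(self):
        m = confusion_metrics([1, 0, 1], [1, 0, 1])
        assert m == {"sensitivity": 1.0, "specificity": 1.0, "accuracy": 1.0}

    def test_all_positive_on_48_51(self):
        actual = [1] * 48 + [0] * 51
        m = confusion_metrics([1] * 99, actual)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.0
        assert m["accuracy"] == pytest.approx(48 / 99)

    def test_hand_tabulated_example(self):
        predicted = [1, 1, 0, 0, 1, 0]
        actual = [1, 0, 1, 0, 1, 0]
        # TP=2 FN=1 FP=1 TN=2
        m = confusion_metrics(predicted, actual)
        assert m["sensitivity"] == pytest.approx(2 / 3)
        assert m["specificity"] == pytest.approx(2 / 3)
        assert m["accuracy"] == pytest.approx(4 / 6)


class TestCohortReport:
    def test_no_methylation_cohort(self):
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(12)],
                "group": ["cancer"] * 6 + ["control"] * 6,
                "gender": ["female", "male"] * 6,
                "level_p16": [0.0, 0.01, -0.02, 0.0, 0.01, 0.0] * 2,
                "level_MGMT": [0.0] * 12,
            }
        )
        report = cohort_report(df)
        assert (report["any_gene"]["fraction_any_gene_methylated"] == 0.0).all()

    def test_smoke_on_toy_cohort(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(30)],
                "group": ["cancer"] * 15 + ["control"] * 15,
                "gender": rng.choice(["female", "male"], 30),
                "level_p16": np.r_[rng.uniform(0, 0.4, 15), rng.uniform(-0.02, 0.06, 15)],
                "level_MGMT": np.r_[rng.uniform(0, 0.3, 15), rng.uniform(-0.02, 0.05, 15)],
                "level_RASSF1": np.r_[rng.uniform(0, 0.3, 15), rng.uniform(-0.02, 0.05, 15)],
            }
        )
        report = cohort_report(df)
        for key in ("group_summary", "any_gene", "roc", "fisher"):
            assert key in report and len(report[key]) > 0
        for key in ("cart_levels", "cart_states"):
            assert 0.0 <= report[key]["accuracy"] <= 1.0
            assert "predict" in report[key]["text"]

    def test_any_gene_fraction_within_binomial_band_of_design_target(self):
        cfg = CohortConfig(seed=6)
        df = simulate_cohort(cfg)
        report = cohort_report(df)
        got = dict(
            zip(
                report["any_gene"]["group"],
                report["any_gene"]["fraction_any_gene_methylated"],
            )
        )
        for group, n in (("cancer", cfg.n_cancer), ("control", cfg.n_control)):
            target = cfg.design_target_any_gene[group]
            band = 3 * math.sqrt(target * (1 - target) / n)
            assert abs(got[group] - target) <= band

    def test_missing_group_column_rejected(self):
        with pytest.raises(DataError, match="group"):
            cohort_report(pd.DataFrame({"level_p16": [0.1, 0.2]}))
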