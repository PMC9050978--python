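"""Survival forest: splitting, log-rank statistic, ensemble mortality,
score normalization, and cross-checks against independent implementations."""

import numpy as np
import pandas as pd
import pytest

import lungrad as lr
from lungrad.forest import (
    RSFHyperParams,
    _best_threshold,
    fit_rsf,
    forest_from_dict,
    forest_to_dict,
    logrank_split_stat,
    normalize_score,
    predict_mortality,
    split_cohort,
)

from conftest import gaussian_feature_cohort


def records(n):
    return pd.DataFrame({"x": np.arange(n)})


class TestSplitCohort:
    @pytest.mark.parametrize("n, n_train", [(9, 6), (143, 95), (3, 2)])
    def test_train_size_rule(self, n, n_train):
        train, test = split_cohort(records(n), seed=0)
        assert len(train) == n_train
        assert len(test) == n - n_train

    def test_disjoint_and_exhaustive(self):
        train, test = split_cohort(records(50), seed=1)
        combined = sorted(train["x"].tolist() + test["x"].tolist())
        assert combined == list(range(50))

    def test_deterministic(self):
        a = split_cohort(records(30), seed=5)[0]
        b = split_cohort(records(30), seed=5)[0]
        pd.testing.assert_frame_equal(a, b)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(records(2), seed=0)


class TestLogrankSplitStat:
    def test_identical_survival_both_sides_is_zero(self):
        times = np.array([1, 2, 3, 1, 2, 3], dtype=float)
        events = np.array([1, 1, 1, 1, 1, 1])
        left = np.array([True, True, True, False, False, False])
        assert logrank_split_stat(times, events, left) == pytest.approx(0.0)

    def test_matches_lifelines_chi_square(self):
        # standardized statistic squared equals the lifelines log-rank chi2
        from lifelines.statistics import logrank_test as ll

        rng = np.random.default_rng(7)
        times = rng.exponential(10, 40).round(2) + 0.01
        events = rng.integers(0, 2, 40)
        events[0] = 1
        left = rng.random(40) < 0.5
        left[:2] = [True, False]
        stat = logrank_split_stat(times, events, left)
        res = ll(times[left], times[~left],
                 event_observed_A=events[left], event_observed_B=events[~left])
        assert stat**2 == pytest.approx(res.test_statistic, rel=1e-6)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            logrank_split_stat([1, 2], [1, 1], np.array([True, True]))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_split_stat([1, 2], [0, 0], np.array([True, False]))

    def test_best_threshold_respects_nodesize(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        times = np.array([4.0, 3.0, 2.0, 1.0])
        events = np.ones(4, dtype=int)
        stat, thr = _best_threshold(x, times, events, nodesize=2)
        assert thr == pytest.approx(2.5)      # only the middle split is admissible
        _, thr1 = _best_threshold(x, times, events, nodesize=3)
        assert thr1 is None                   # no split leaves 3 on both sides


class TestFitRSF:
    def test_depth_zero_forest_is_constant(self):
        feats, rec = gaussian_feature_cohort(60, seed=1, log_hr={"longhem": 1.0})
        f = fit_rsf(feats, rec["time_months"], rec["event"],
                    RSFHyperParams(ntree=5, nodedepth=0, seed=0))
        with pytest.raises(ValueError):
            normalize_score(f, [1.0])          # degenerate training range
        risks = predict_mortality(f, feats)
        assert np.ptp(risks) == 0.0

    def test_prognostic_feature_recovered(self):
        feats, rec = gaussian_feature_cohort(500, seed=2, log_hr={"longhem": 1.0})
        f = fit_rsf(feats, rec["time_months"], rec["event"], RSFHyperParams(seed=3))
        c = lr.harrell_c(predict_mortality(f, feats),
                         rec["time_months"], rec["event"])
        assert c > 0.6

    def test_same_data_same_seed_identical_forest(self):
        feats, rec = gaussian_feature_cohort(80, seed=4, log_hr={"energy": 0.5})
        h = RSFHyperParams(ntree=10, seed=9)
        f1 = fit_rsf(feats, rec["time_months"], rec["event"], h)
        f2 = fit_rsf(feats, rec["time_months"], rec["event"], h)
        assert forest_to_dict(f1) == forest_to_dict(f2)

    def test_all_censored_rejected(self):
        feats, rec = gaussian_feature_cohort(40, seed=5)
        with pytest.raises(ValueError, match="censored"):
            fit_rsf(feats, rec["time_months"], np.zeros(40, dtype=int),
                    RSFHyperParams(ntree=2))

    def test_monotone_transform_leaves_structure_invariant(self):
        feats, rec = gaussian_feature_cohort(100, seed=6, log_hr={"kurtosis": 1.0})
        h = RSFHyperParams(ntree=5, seed=11)
        f1 = fit_rsf(feats, rec["time_months"], rec["event"], h)
        warped = feats.copy()
        for c in warped.columns:
            warped[c] = np.exp(warped[c])      # strictly increasing transform
        f2 = fit_rsf(warped, rec["time_months"], rec["event"], h)

        def structure(node):
            if node.is_leaf:
                return ("leaf", node.mortality)
            return (node.feature, structure(node.left), structure(node.right))

        for t1, t2 in zip(f1.trees, f2.trees):
            assert structure(t1) == structure(t2)

    def test_null_cohort_test_concordance_near_half(self):
        feats, rec = gaussian_feature_cohort(500, seed=7, log_hr={})
        table = feats.copy()
        table["time_months"] = rec["time_months"]
        table["event"] = rec["event"]
        train, test = split_cohort(table, seed=8)
        f = fit_rsf(train[lr.FEATURE_NAMES], train["time_months"], train["event"],
                    RSFHyperParams(seed=12))
        c = lr.harrell_c(predict_mortality(f, test[lr.FEATURE_NAMES]),
                         test["time_months"], test["event"])
        assert 0.4 <= c <= 0.6


class TestPredictAndScore:
    def test_single_split_tree_risk_is_step_function(self):
        # force single-feature trees of depth 1
        rng = np.random.default_rng(13)
        n = 60
        feats = pd.DataFrame({"x": np.concatenate([rng.uniform(0, 1, n // 2),
                                                   rng.uniform(2, 3, n // 2)])})
        times = np.concatenate([rng.exponential(50, n // 2),
                                rng.exponential(5, n // 2)]).round(2) + 0.01
        events = np.ones(n, dtype=int)
        f = fit_rsf(feats, times, events,
                    RSFHyperParams(ntree=3, nodedepth=1, nodesize=5, mtry=1, seed=0))
        grid = pd.DataFrame({"x": np.linspace(0, 3, 31)})
        risks = predict_mortality(f, grid)
        assert len(np.unique(risks)) <= 2 ** 1 + 1
        assert risks[-1] > risks[0]           # high x = short survival = high risk

    def test_two_tree_toy_forest_matches_hand_traversal(self):
        feats, rec = gaussian_feature_cohort(50, seed=14, log_hr={"variance": 1.0})
        f = fit_rsf(feats, rec["time_months"], rec["event"],
                    RSFHyperParams(ntree=2, nodedepth=2, nodesize=5, seed=15))
        x = feats.iloc[7]

        def traverse(node):
            while node.feature is not None:
                node = (node.left if x.iloc[node.feature] <= node.threshold
                        else node.right)
            return node.mortality

        expected = np.mean([traverse(t) for t in f.trees])
        got = predict_mortality(f, feats.iloc[[7]])[0]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_missing_feature_rejected(self):
        feats, rec = gaussian_feature_cohort(40, seed=16, log_hr={"energy": 1.0})
        f = fit_rsf(feats, rec["time_months"], rec["event"],
                    RSFHyperParams(ntree=2, seed=1))
        with pytest.raises(KeyError, match="longhem"):
            predict_mortality(f, feats.drop(columns=["longhem"]))

    def test_normalization_endpoints_and_clipping(self):
        feats, rec = gaussian_feature_cohort(60, seed=17, log_hr={"a_lre": 1.0})
        f = fit_rsf(feats, rec["time_months"], rec["event"],
                    RSFHyperParams(ntree=5, seed=2))
        lo, hi = f.train_risk_min, f.train_risk_max
        mid = (lo + hi) / 2
        out = normalize_score(f, [lo, hi, mid, hi + 10, lo - 10])
        np.testing.assert_allclose(out, [0, 100, 50, 100, 0])

    def test_serialization_round_trip(self):
        feats, rec = gaussian_feature_cohort(50, seed=18, log_hr={"energy": 0.8})
        f = fit_rsf(feats, rec["time_months"], rec["event"],
                    RSFHyperParams(ntree=3, seed=4))
        f2 = forest_from_dict(forest_to_dict(f))
        np.testing.assert_allclose(predict_mortality(f, feats),
                                   predict_mortality(f2, feats))


def test_concordance_comparable_to_scikit_survival_forest():
    """Independent cross-check: our forest's discrimination on a prognostic
    cohort is in the same range as scikit-survival's RandomSurvivalForest
    with matched hyperparameters."""
    sksurv = pytest.importorskip("sksurv.ensemble")
    from sksurv.util import Surv

    feats, rec = gaussian_feature_cohort(400, seed=19, log_hr={"longhem": 1.0})
    table = feats.copy()
    table["time_months"] = rec["time_months"]
    table["event"] = rec["event"]
    train, test = split_cohort(table, seed=20)

    ours = fit_rsf(train[lr.FEATURE_NAMES], train["time_months"], train["event"],
                   RSFHyperParams(seed=21))
    c_ours = lr.harrell_c(predict_mortality(ours, test[lr.FEATURE_NAMES]),
                          test["time_months"], test["event"])

    ref = sksurv.RandomSurvivalForest(
        n_estimators=50, min_samples_leaf=10, max_depth=4, max_features="sqrt",
        random_state=21)
    y_train = Surv.from_arrays(train["event"].astype(bool), train["time_months"])
    ref.fit(train[lr.FEATURE_NAMES], y_train)
    c_ref = lr.harrell_c(ref.predict(test[lr.FEATURE_NAMES]),
                         test["time_months"], test["event"])
    assert abs(c_ours - c_ref) < 0.1
    assert c_ours > 0.6 and c_ref > 0.6
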