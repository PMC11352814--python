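import numpy as np
import pytest

import protomort as pm
from protomort.conformal import (ConformalClassifierBundle, _bootstrap_split,
                                 REBALANCE_ALLKNN, REBALANCE_IHT)


def _two_blobs(rng, n0=40, n1=20, sep=6.0):
    X = np.vstack([rng.normal(0, 1, (n0, 4)),
                   rng.normal(sep, 1, (n1, 4))])
    y = np.array(["a"] * n0 + ["b"] * n1)
    return X, y


# ---------------------------------------------------------------------------
# rebalancing
# ---------------------------------------------------------------------------

def test_allknn_keeps_separated_classes(rng):
    X, y = _two_blobs(rng, sep=8.0)
    kept = pm.all_knn_indices(X, y)
    assert len(kept) == len(y)


def test_allknn_shrinks_majority_only(rng):
    X, y = _two_blobs(rng, n0=30, n1=12, sep=0.8)   # heavy overlap
    kept = pm.all_knn_indices(X, y)
    yk = y[kept]
    assert (yk == "b").sum() == 12                  # minority untouched
    assert (yk == "a").sum() < 30


def test_iht_balances_and_preserves_minority(rng):
    X, y = _two_blobs(rng, n0=23, n1=11, sep=1.0)
    kept = pm.instance_hardness_indices(X, y, seed=46)
    yk = y[kept]
    assert (yk == "b").sum() == 11
    assert (yk == "a").sum() == 11


def test_iht_identity_on_balanced_input(rng):
    X, y = _two_blobs(rng, n0=15, n1=15, sep=1.0)
    kept = pm.instance_hardness_indices(X, y, seed=46)
    assert len(kept) == 30


def test_rebalance_skips_tiny_class(rng):
    X = rng.normal(size=(10, 3))
    y = np.array(["a"] * 9 + ["b"])
    with pytest.warns(UserWarning):
        kept = pm.rebalance(X, y, REBALANCE_ALLKNN)
    assert len(kept) == 10


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def test_select_all_is_identity(rng):
    X = rng.normal(size=(30, 6))
    y = rng.integers(0, 2, 30)
    assert list(pm.select_k_best(X, y, 6)) == list(range(6))


def test_select_recovers_informative_features(rng):
    X = rng.normal(size=(60, 12))
    y = np.array([0] * 30 + [1] * 30)
    X[y == 1, :3] += 3.0
    sel = pm.select_k_best(X, y, 3)
    assert set(sel) == {0, 1, 2}


def test_constant_feature_never_beats_informative(rng):
    X = rng.normal(size=(40, 5))
    X[:, 4] = 1.0
    y = np.array([0] * 20 + [1] * 20)
    X[y == 1, 0] += 2.0
    sel = pm.select_k_best(X, y, 4)
    assert 4 not in sel


# ---------------------------------------------------------------------------
# conformal p-values
# ---------------------------------------------------------------------------

class _StubModel:
    """Fixed-probability classifier standing in for a fitted forest."""

    def __init__(self, proba, classes):
        self._proba = np.asarray(proba)
        self.classes_ = np.asarray(classes)

    def predict_proba(self, X):
        return np.tile(self._proba, (len(X), 1))


def _stub_bundle(cal_scores, proba, confidence=0.8):
    cfg = pm.ModelConfig(confidence=confidence, n_acp_models=1)
    b = ConformalClassifierBundle(config=cfg, classes=np.array(["a", "b"]))
    b.models = [_StubModel(proba, ["a", "b"])]
    b.calibration = [{None: np.sort(cal_scores),
                      "a": np.sort(cal_scores), "b": np.sort(cal_scores)}]
    return b


def test_conformal_p_rank_formula():
    """Calibration {0.1,0.2,0.3,0.4} and test score 0.25 -> p = 3/5."""
    b = _stub_bundle([0.1, 0.2, 0.3, 0.4], proba=[0.75, 0.25])
    p = b.aggregated_p(np.zeros((1, 2)))
    assert p[0, 0] == pytest.approx(3 / 5)          # alpha = 1-0.75 = 0.25


def test_conformal_p_maximal_when_score_below_all():
    b = _stub_bundle([0.1, 0.2, 0.3, 0.4], proba=[0.99, 0.01])
    p = b.aggregated_p(np.zeros((1, 2)))
    assert p[0, 0] == pytest.approx(1.0)            # alpha = 0.01 below all


def test_prediction_set_thresholding():
    """p=(0.9, 0.05) -> singleton conclusive; p=(0.5, 0.5) -> inconclusive."""
    b = _stub_bundle([0.05, 0.2, 0.5, 0.8, 0.95], proba=[0.97, 0.03])
    sets = pm.predict_set(b, np.zeros((1, 2)))
    assert sets[0].conclusive
    assert sets[0].prediction_set == ("a",)
    b2 = _stub_bundle([0.4, 0.45, 0.5, 0.55, 0.6], proba=[0.5, 0.5])
    sets2 = pm.predict_set(b2, np.zeros((1, 2)))
    assert not sets2[0].conclusive
    assert len(sets2[0].prediction_set) == 2


def test_regression_quantile_rank_arithmetic():
    """Scores {1,2,3,4} at confidence 0.8 -> q = 4 ((n+1) convention)."""
    assert pm.calibration_quantile([1, 2, 3, 4], 0.8) == 4.0
    assert pm.calibration_quantile([1, 2, 3, 4, 5, 6, 7, 8, 9], 0.8) == 8.0


def test_median_aggregation_bounded_by_submodels(rng, fast_config):
    X, y = _two_blobs(rng, n0=30, n1=20, sep=2.0)
    bundle = pm.fit_acp_classifier(X, y, fast_config)
    per_model = bundle.p_values_per_model(X[:10])
    agg = bundle.aggregated_p(X[:10])
    assert np.all(agg >= per_model.min(axis=0) - 1e-12)
    assert np.all(agg <= per_model.max(axis=0) + 1e-12)


def test_classifier_determinism(rng, fast_config):
    X, y = _two_blobs(rng, sep=2.0)
    a = pm.fit_acp_classifier(X, y, fast_config).aggregated_p(X[:8])
    b = pm.fit_acp_classifier(X, y, fast_config).aggregated_p(X[:8])
    assert np.array_equal(a, b)


def test_bootstrap_split_keeps_all_classes(rng):
    y = np.array(["a"] * 12 + ["b"] * 4)
    for _ in range(10):
        train, oob = _bootstrap_split(16, rng, y)
        assert set(y[train]) == {"a", "b"}
        assert set(y[oob]) == {"a", "b"}
        assert len(np.intersect1d(train, oob)) == 0


def test_constant_outcome_gives_tight_intervals(rng, fast_config):
    X = rng.normal(size=(40, 3))
    y = np.full(40, 500.0)
    bundle = pm.fit_acp_regressor(X, y, fast_config)
    sets = pm.predict_interval(bundle, X[:5])
    for s in sets:
        assert s.interval[1] - s.interval[0] < 1.0
        assert s.contains(500.0)


def test_regressor_interval_orientation(rng, fast_config):
    X = rng.normal(size=(60, 4))
    y = 100.0 + 30.0 * X[:, 0] + rng.normal(0, 5, 60)
    bundle = pm.fit_acp_regressor(X, y, fast_config)
    for s in pm.predict_interval(bundle, X[:10]):
        lo, hi = s.interval
        assert lo <= s.point <= hi
        assert s.conclusive


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def test_leave_one_out_partition(rng):
    """folds = n on a 10-sample toy: every sample predicted exactly once."""
    X = rng.normal(size=(10, 3))
    X[5:, 0] += 4.0
    y = np.array(["a"] * 5 + ["b"] * 5)
    cfg = pm.ModelConfig(n_trees=25, n_acp_models=3, k_best=2,
                         n_permutations=2, rebalance="none", seed=46)
    cv = pm.cross_validate(X, y, cfg, folds=5)
    assert all(ps is not None for ps in cv.prediction_sets)
    assert len(cv.prediction_sets) == 10


def test_no_leakage_from_heldout_outcome(rng, fast_config):
    """A leak-detector column equal to the outcome only in held-out rows
    must never be selected: selection is refit inside each training fold,
    where that column is pure noise."""
    n = 60
    X = rng.normal(size=(n, 15))
    y = np.array(["a"] * 40 + ["b"] * 20)
    X[y == "b", :4] += 2.0                       # genuine signal
    leak = 14
    # the leak column correlates with y only through rows each fold holds out
    from sklearn.model_selection import StratifiedKFold
    skf = StratifiedKFold(n_splits=5, shuffle=True,
                          random_state=fast_config.seed)
    X[:, leak] = rng.normal(size=n)
    for _, test_idx in skf.split(X, y):
        X[test_idx, leak] = (y[test_idx] == "b") * 5.0
    cv = pm.cross_validate(X, y, fast_config, task="classification")
    for sel in cv.fold_selected:
        assert leak not in sel


def test_importances_flag_planted_signal(rng):
    X = rng.normal(size=(80, 10))
    y = np.array(["a"] * 50 + ["b"] * 30)
    X[y == "b", 0] += 3.0
    X[y == "b", 1] += 3.0
    cfg = pm.ModelConfig(n_trees=50, n_acp_models=5, k_best=4,
                         n_permutations=5, rebalance="none", seed=46)
    cv = pm.cross_validate(X, y, cfg, task="classification")
    top2 = set(cv.importances.sort_values(ascending=False).index[:2])
    assert top2 == {0, 1}


def test_bundle_roundtrips_through_archive(tmp_path, rng, fast_config):
    X, y = _two_blobs(rng, sep=2.0)
    bundle = pm.fit_acp_classifier(X, y, fast_config)
    path = tmp_path / "model.joblib"
    pm.save_bundle(bundle, path)
    loaded = pm.load_bundle(path)
    assert np.array_equal(bundle.aggregated_p(X[:6]),
                          loaded.aggregated_p(X[:6]))


def test_label_permutation_kills_importance(rng):
    """With permuted labels, pooled accuracy hovers near the majority rate
    and importances collapse toward zero."""
    X = rng.normal(size=(60, 8))
    y = rng.permutation(np.array(["a"] * 40 + ["b"] * 20))
    cfg = pm.ModelConfig(n_trees=40, n_acp_models=4, k_best=4,
                         n_permutations=5, rebalance="none", seed=46)
    cv = pm.cross_validate(X, y, cfg, task="classification")
    assert cv.importances.abs().max() < 0.25
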