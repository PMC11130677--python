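"""Classifier family training, grouped tuning, selection, persistence."""

import numpy as np
import pytest

from anochem import classify
from anochem.classify import (
    FAMILIES,
    ClassifierSpec,
    TrainedClassifier,
    predict_proba,
    select_best_family,
    train_family,
    tune_grouped,
)

SMALL_SPACES = {
    "gbt": {"n_estimators": [20], "learning_rate": [0.3], "max_depth": [3],
            "min_child_weight": [1], "subsample": [1.0], "colsample_bytree": [1.0],
            "gamma": [0.0]},
    "rf": {"n_estimators": [50], "max_depth": [None], "max_leaf_nodes": [None],
           "min_samples_split": [2], "min_samples_leaf": [1]},
    "logreg": {"penalty": ["l2"], "solver": ["lbfgs"], "max_iter": [500], "C": [1.0]},
    "ffnn": {"hidden": [(32,)], "dropout": [0.0], "learning_rate": [1e-2],
             "batch_size": [64], "max_epochs": [200], "patience": [50]},
}


def _separable(rng, n=600, d=64):
    """Label equals bit 0; remaining bits are noise."""
    X = (rng.random((n, d)) < 0.3).astype(np.uint8)
    y = X[:, 0].astype(int)
    return X[: n // 2], y[: n // 2], X[n // 2 :], y[n // 2 :]


class TestTrainFamily:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_separable_task_is_learned_by_every_family(self, family, rng):
        X_tr, y_tr, X_val, y_val = _separable(rng)
        clf = train_family(family, X_tr, y_tr, X_val, y_val,
                           search_space=SMALL_SPACES[family], seed=0)
        assert clf.validation_auroc >= 0.99

    def test_permuted_labels_give_chance_auroc(self, rng):
        """Mean validation AUROC over 10 seeds sits at chance on a null task."""
        aucs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = (r.random((200, 32)) < 0.3).astype(np.uint8)
            y = r.permutation(np.repeat([0, 1], 100))
            clf = train_family("logreg", X[:100], y[:100], X[100:], y[100:],
                               search_space=SMALL_SPACES["logreg"], seed=seed)
            aucs.append(clf.validation_auroc)
        assert abs(float(np.mean(aucs)) - 0.5) <= 0.1

    def test_singleton_space_returns_those_hyperparameters(self, rng):
        X_tr, y_tr, X_val, y_val = _separable(rng)
        clf = train_family("rf", X_tr, y_tr, X_val, y_val,
                           search_space=SMALL_SPACES["rf"], seed=0)
        assert clf.spec.hyperparameters == {k: v[0] for k, v in SMALL_SPACES["rf"].items()}

    def test_single_class_partition_rejected(self, rng):
        X_tr, y_tr, X_val, y_val = _separable(rng)
        with pytest.raises(ValueError):
            train_family("logreg", X_tr, np.zeros_like(y_tr), X_val, y_val)


class TestTuneGrouped:
    def test_all_singleton_grids_return_anchored_defaults(self, rng):
        X_tr, y_tr, X_val, y_val = _separable(rng, n=200, d=32)
        spec = tune_grouped(X_tr, y_tr, X_val, y_val,
                            search_space=SMALL_SPACES["gbt"], seed=0)
        assert spec.hyperparameters == {k: v[0] for k, v in SMALL_SPACES["gbt"].items()}

    def test_single_round_equals_exhaustive_search(self, rng):
        """One round over the whole grid reduces to exhaustive grid search."""
        from sklearn.metrics import roc_auc_score
        import itertools
        import xgboost as xgb

        X_tr, y_tr, X_val, y_val = _separable(rng, n=240, d=32)
        space = {"max_depth": [2, 4], "n_estimators": [10, 30]}
        spec = tune_grouped(X_tr, y_tr, X_val, y_val,
                            groups=(("max_depth", "n_estimators"),),
                            search_space=space, seed=0)
        best, best_auc = None, -1
        for md, ne in itertools.product(space["max_depth"], space["n_estimators"]):
            m = xgb.XGBClassifier(max_depth=md, n_estimators=ne, tree_method="hist",
                                  n_jobs=1, random_state=0, eval_metric="logloss")
            m.fit(X_tr, y_tr)
            auc = roc_auc_score(y_val, m.predict_proba(X_val)[:, 1])
            if auc > best_auc:
                best, best_auc = {"max_depth": md, "n_estimators": ne}, auc
        assert spec.hyperparameters == best

    def test_rounds_reach_known_optimum_corner(self, rng, monkeypatch):
        """With a response surface peaking at a grid corner, rounds find it."""
        X_tr, y_tr, X_val, y_val = _separable(rng, n=100, d=8)
        noise = np.random.default_rng(42).random(len(y_val))

        def fake_fit(family, params, *args):
            return params

        def fake_proba(family, params, X):
            q = params["max_depth"] / 6 * 0.5 + params["gamma"] * 0.5  # peak at (6, 1)
            return q * y_val + noise  # class overlap shrinks as q grows

        monkeypatch.setattr(classify, "_fit_candidate", fake_fit)
        monkeypatch.setattr(classify, "_proba", fake_proba)
        space = {"max_depth": [2, 6], "gamma": [0.0, 1.0]}
        spec = tune_grouped(X_tr, y_tr, X_val, y_val,
                            groups=(("max_depth",), ("gamma",)), search_space=space)
        assert spec.hyperparameters == {"max_depth": 6, "gamma": 1.0}

    def test_empty_group_rejected(self, rng):
        X_tr, y_tr, X_val, y_val = _separable(rng, n=100, d=8)
        with pytest.raises(ValueError):
            tune_grouped(X_tr, y_tr, X_val, y_val, groups=((), ("max_depth",)),
                         search_space={"max_depth": [2]})

    def test_groups_must_cover_space_exactly(self, rng):
        X_tr, y_tr, X_val, y_val = _separable(rng, n=100, d=8)
        with pytest.raises(ValueError):
            tune_grouped(X_tr, y_tr, X_val, y_val, groups=(("max_depth", "max_depth"),),
                         search_space={"max_depth": [2], "gamma": [0.0]})

    def test_tuning_never_degrades_default_spec(self, rng):
        """Coordinate-wise tuning's final AUROC >= the anchored default's."""
        from sklearn.metrics import roc_auc_score

        X_tr, y_tr, X_val, y_val = _separable(rng, n=240, d=32)
        space = {"n_estimators": [20, 50], "learning_rate": [0.1, 0.3],
                 "max_depth": [3, 6], "min_child_weight": [1], "subsample": [1.0],
                 "colsample_bytree": [1.0], "gamma": [0.0]}
        clf = train_family("gbt", X_tr, y_tr, X_val, y_val, search_space=space, seed=0)
        default = {k: (classify.GBT_DEFAULTS[k] if classify.GBT_DEFAULTS.get(k) in v else v[0])
                   for k, v in space.items()}
        base = classify._fit_candidate("gbt", default, X_tr, y_tr, X_val, y_val, 0)
        base_auc = roc_auc_score(y_val, base.predict_proba(X_val)[:, 1])
        assert clf.validation_auroc >= base_auc - 1e-12


class TestSelection:
    def _stub(self, family, auc):
        return TrainedClassifier(spec=ClassifierSpec(family=family),
                                 model=None, validation_auroc=auc, n_features=8)

    def test_single_candidate_returned(self):
        c = self._stub("rf", 0.7)
        assert select_best_family([c]) is c

    def test_argmax_selected(self):
        cs = [self._stub("logreg", 0.8), self._stub("rf", 0.9), self._stub("ffnn", 0.7)]
        assert select_best_family(cs) is cs[1]

    def test_tie_breaks_by_declared_family_order(self):
        rf = self._stub("rf", 0.9)
        gbt = self._stub("gbt", 0.9)
        assert select_best_family([rf, gbt]) is gbt

    def test_never_returns_dominated_candidate(self, rng):
        for _ in range(20):
            cs = [self._stub(f, float(rng.random())) for f in FAMILIES]
            best = select_best_family(cs)
            assert all(best.validation_auroc >= c.validation_auroc for c in cs)


class TestPredict:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_probabilities_on_correct_side_for_separable_task(self, family, rng):
        X_tr, y_tr, X_val, y_val = _separable(rng)
        clf = train_family(family, X_tr, y_tr, X_val, y_val,
                           search_space=SMALL_SPACES[family], seed=0)
        p = predict_proba(clf, X_tr)
        assert np.all((p >= 0) & (p <= 1))
        assert np.mean((p >= 0.5) == (y_tr == 1)) > 0.97

    def test_empty_batch(self, rng):
        X_tr, y_tr, X_val, y_val = _separable(rng, n=100, d=16)
        clf = train_family("logreg", X_tr, y_tr, X_val, y_val,
                           search_space=SMALL_SPACES["logreg"], seed=0)
        assert predict_proba(clf, np.zeros((0, 16))).size == 0

    def test_repeated_rows_get_identical_probabilities(self, rng):
        X_tr, y_tr, X_val, y_val = _separable(rng, n=100, d=16)
        clf = train_family("gbt", X_tr, y_tr, X_val, y_val,
                           search_space=SMALL_SPACES["gbt"], seed=0)
        X = np.tile(X_tr[:1], (5, 1))
        assert len(set(predict_proba(clf, X))) == 1

    def test_width_mismatch_rejected(self, rng):
        X_tr, y_tr, X_val, y_val = _separable(rng, n=100, d=16)
        clf = train_family("logreg", X_tr, y_tr, X_val, y_val,
                           search_space=SMALL_SPACES["logreg"], seed=0)
        with pytest.raises(ValueError):
            predict_proba(clf, np.zeros((3, 8)))


class TestPersistence:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_round_trip_preserves_predictions(self, family, rng, tmp_path):
        X_tr, y_tr, X_val, y_val = _separable(rng, n=120, d=16)
        clf = train_family(family, X_tr, y_tr, X_val, y_val,
                           search_space=SMALL_SPACES[family], seed=0)
        classify.save_classifier(clf, str(tmp_path / family))
        loaded = classify.load_classifier(str(tmp_path / family))
        assert np.allclose(predict_proba(clf, X_val), predict_proba(loaded, X_val),
                           atol=1e-9)
        assert loaded.spec.family == family
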