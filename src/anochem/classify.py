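"""Real-vs-generated fingerprint classifiers.

Four model families are trained on the 2048-bit fingerprint and compete
on validation AUROC: gradient-boosted trees (XGBoost), a feed-forward
network with dropout and AUROC early stopping, a random forest, and
logistic regression. The winner supplies the probability feature
``p_real_clf`` to the ensemble stage. XGBoost hyperparameters are tuned
coordinate-wise in four rounds over grouped parameters, mirroring how
interacting tree parameters are usually co-tuned.
"""

from __future__ import annotations

import itertools
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
import xgboost as xgb
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from ._nn import MLP

logger = logging.getLogger(__name__)

#: Declared family order; also the tie-break order in model selection.
FAMILIES = ("gbt", "ffnn", "rf", "logreg")

GBT_DEFAULTS = {
    "n_estimators": 100,
    "learning_rate": 0.3,
    "max_depth": 6,
    "min_child_weight": 1,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
    "gamma": 0.0,
}

#: Coordinate-wise tuning rounds for gbt: interacting parameters share a group.
GBT_GROUPS: tuple[tuple[str, ...], ...] = (
    ("n_estimators", "learning_rate"),
    ("max_depth", "min_child_weight"),
    ("subsample", "colsample_bytree"),
    ("gamma",),
)

DEFAULT_SEARCH_SPACES: dict[str, dict[str, list]] = {
    "gbt": {
        "n_estimators": [100, 200],
        "learning_rate": [0.1, 0.3],
        "max_depth": [4, 6],
        "min_child_weight": [1, 5],
        "subsample": [0.8, 1.0],
        "colsample_bytree": [0.8, 1.0],
        "gamma": [0.0, 1.0],
    },
    "rf": {
        "n_estimators": [200],
        "max_depth": [None, 16],
        "max_leaf_nodes": [None],
        "min_samples_split": [2],
        "min_samples_leaf": [1],
    },
    "logreg": {
        "penalty": ["l2"],
        "solver": ["lbfgs", "liblinear"],
        "max_iter": [1000],
        "C": [0.1, 1.0, 10.0],
    },
    "ffnn": {
        "hidden": [(512, 128)],
        "dropout": [0.0, 0.2, 0.5],
        "learning_rate": [1e-3, 1e-4],
    },
}


@dataclass(frozen=True)
class ClassifierSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class TrainedClassifier:
    spec: ClassifierSpec
    model: object = field(repr=False)
    validation_auroc: float
    n_features: int


class MLPBinaryClassifier:
    """Feed-forward binary classifier on the NumPy MLP core.

    Early stopping monitors validation AUROC (patience 5); the best
    epoch's weights are restored after training.
    """

    def __init__(self, hidden=(512, 128), dropout=0.0, learning_rate=1e-3,
                 batch_size=128, max_epochs=30, patience=5, seed=0):
        self.hidden = tuple(hidden)
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed
        self.net: MLP | None = None

    def fit(self, X, y, X_val, y_val):
        X = np.asarray(X, dtype=np.float32)
        Y = np.asarray(y, dtype=np.float32).reshape(-1, 1)
        self.net = MLP((X.shape[1], *self.hidden, 1), dropout=self.dropout, seed=self.seed)
        rng = np.random.default_rng(self.seed + 1)
        best_auc, best_state, stale = -np.inf, self.net.state_dict(), 0
        for _ in range(self.max_epochs):
            self.net.fit_epoch(X, Y, self.learning_rate, self.batch_size, rng)
            auc = roc_auc_score(y_val, self.predict_proba(X_val))
            if auc > best_auc + 1e-6:
                best_auc, best_state, stale = auc, self.net.state_dict(), 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
        self.net.load_state_dict(best_state)
        return self

    def predict_proba(self, X) -> np.ndarray:
        if self.net is None:
            raise RuntimeError("classifier not fitted")
        return self.net.predict(np.asarray(X, dtype=np.float32)).ravel().astype(np.float64)


def _fit_candidate(family: str, params: dict, X_tr, y_tr, X_val, y_val, seed: int):
    """Fit one hyperparameter cell; returns (fitted model, predict_proba fn input→p1)."""
    if family == "gbt":
        model = xgb.XGBClassifier(
            **params, tree_method="hist", n_jobs=1, random_state=seed,
            eval_metric="logloss",
        )
        model.fit(X_tr, y_tr)
    elif family == "rf":
        model = RandomForestClassifier(**params, n_jobs=1, random_state=seed)
        model.fit(X_tr, y_tr)
    elif family == "logreg":
        params = dict(params)
        if params.get("penalty", "l2") == "l2":
            params.pop("penalty", None)  # sklearn default; passing it is deprecated
        model = LogisticRegression(**params, random_state=seed)
        model.fit(X_tr, y_tr)
    elif family == "ffnn":
        model = MLPBinaryClassifier(**params, seed=seed)
        model.fit(X_tr, y_tr, X_val, y_val)
    else:
        raise ValueError(f"unknown family {family!r}")
    return model


def _proba(family: str, model, X) -> np.ndarray:
    X = np.asarray(X)
    if X.shape[0] == 0:
        return np.zeros(0, dtype=np.float64)
    if family == "ffnn":
        return model.predict_proba(X)
    n_expected = getattr(model, "n_features_in_", None)
    if n_expected is not None and X.shape[1] != n_expected:
        raise ValueError(f"feature width {X.shape[1]} != model width {n_expected}")
    return model.predict_proba(X)[:, 1].astype(np.float64)


def _check_partitions(y_tr, y_val):
    for name, y in (("train", y_tr), ("validation", y_val)):
        if len(np.unique(y)) < 2:
            raise ValueError(f"{name} partition contains a single class")


def _grid_cells(space: dict[str, list]):
    keys = sorted(space)
    for combo in itertools.product(*(space[k] for k in keys)):
        yield dict(zip(keys, combo))


def train_family(
    family: str,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    search_space: dict[str, list] | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Grid-search one family; best hyperparameters by validation AUROC.

    The gbt family is tuned coordinate-wise over :data:`GBT_GROUPS`
    instead of exhaustively (its full grid has 128 cells).
    """
    _check_partitions(y_tr, y_val)
    space = search_space if search_space is not None else DEFAULT_SEARCH_SPACES[family]
    if family == "gbt" and any(len(v) > 1 for v in space.values()):
        spec, model, auc = _tune_grouped(X_tr, y_tr, X_val, y_val, space=space, seed=seed)
        return TrainedClassifier(spec=spec, model=model, validation_auroc=auc,
                                 n_features=X_tr.shape[1])
    best = None
    for params in _grid_cells(space):
        try:
            model = _fit_candidate(family, params, X_tr, y_tr, X_val, y_val, seed)
        except Exception as exc:  # a bad cell must not kill the search
            logger.warning("%s cell %s failed: %s", family, params, exc)
            continue
        auc = roc_auc_score(y_val, _proba(family, model, X_val))
        if not np.isfinite(auc):
            continue
        if best is None or auc > best[2]:
            best = (params, model, float(auc))
    if best is None:
        raise RuntimeError(f"every grid cell failed for family {family!r}")
    params, model, auc = best
    logger.info("%s: best validation AUROC %.4f at %s", family, auc, params)
    return TrainedClassifier(
        spec=ClassifierSpec(family=family, hyperparameters=params, seed=seed),
        model=model, validation_auroc=auc, n_features=X_tr.shape[1],
    )


def _tune_grouped(X_tr, y_tr, X_val, y_val, space=None, groups=None, seed=0):
    space = space if space is not None else DEFAULT_SEARCH_SPACES["gbt"]
    groups = tuple(tuple(g) for g in (groups if groups is not None else GBT_GROUPS))
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty hyperparameter group")
    flat = [p for g in groups for p in g]
    if sorted(flat) != sorted(space) or len(flat) != len(set(flat)):
        raise ValueError("groups must cover the search-space parameters exactly once")
    current = {k: (space[k][0] if k not in GBT_DEFAULTS else GBT_DEFAULTS[k]) for k in space}
    for k in current:  # anchor the start point inside the declared grid
        if current[k] not in space[k]:
            current[k] = space[k][0]
    best_model, best_auc = None, -np.inf
    for grp in groups:
        round_best = None
        for combo in itertools.product(*(space[k] for k in grp)):
            params = {**current, **dict(zip(grp, combo))}
            model = _fit_candidate("gbt", params, X_tr, y_tr, X_val, y_val, seed)
            auc = roc_auc_score(y_val, _proba("gbt", model, X_val))
            if round_best is None or auc > round_best[2]:
                round_best = (params, model, float(auc))
        current = round_best[0]
        best_model, best_auc = round_best[1], round_best[2]
        logger.info("gbt round %s: AUROC %.4f at %s", grp, best_auc,
                    {k: current[k] for k in grp})
    return ClassifierSpec(family="gbt", hyperparameters=current, seed=seed), best_model, best_auc


def tune_grouped(
    X_tr, y_tr, X_val, y_val,
    groups: tuple[tuple[str, ...], ...] | None = None,
    search_space: dict[str, list] | None = None,
    seed: int = 0,
) -> ClassifierSpec:
    """Coordinate-wise rounds over grouped gbt hyperparameters.

    Each round grid-searches one group while holding the others at their
    current best; the spec after the final round is returned.
    """
    _check_partitions(y_tr, y_val)
    spec, _, _ = _tune_grouped(X_tr, y_tr, X_val, y_val, space=search_space,
                               groups=groups, seed=seed)
    return spec


def select_best_family(candidates: list[TrainedClassifier]) -> TrainedClassifier:
    """Argmax validation AUROC; ties break by the declared family order."""
    if not candidates:
        raise ValueError("no candidates")
    return max(candidates,
               key=lambda c: (c.validation_auroc, -FAMILIES.index(c.spec.family)))


def predict_proba(clf: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """P(real) for each fingerprint row; order-preserving and deterministic."""
    X = np.asarray(X)
    if X.size and X.shape[1] != clf.n_features:
        raise ValueError(f"feature width {X.shape[1]} != model width {clf.n_features}")
    return _proba(clf.spec.family, clf.model, X)


# -------------------------------------------------------------- persistence


def save_classifier(clf: TrainedClassifier, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    meta = {"spec": asdict(clf.spec), "validation_auroc": clf.validation_auroc,
            "n_features": clf.n_features}
    fam = clf.spec.family
    if fam == "ffnn":
        m: MLPBinaryClassifier = clf.model
        np.savez(os.path.join(path, "model.npz"), **m.net.state_dict())
        meta["ffnn"] = {"hidden": list(m.hidden), "dropout": m.dropout,
                        "learning_rate": m.learning_rate, "seed": m.seed}
    else:
        joblib.dump(clf.model, os.path.join(path, "model.joblib"))
    with open(os.path.join(path, "spec.json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def load_classifier(path: str) -> TrainedClassifier:
    with open(os.path.join(path, "spec.json")) as fh:
        meta = json.load(fh)
    sd = meta["spec"]
    hp = dict(sd["hyperparameters"])
    fam = sd["family"]
    if fam == "ffnn":
        cfg = meta["ffnn"]
        model = MLPBinaryClassifier(hidden=tuple(cfg["hidden"]), dropout=cfg["dropout"],
                                    learning_rate=cfg["learning_rate"], seed=cfg["seed"])
        model.net = MLP((meta["n_features"], *model.hidden, 1), dropout=model.dropout,
                        seed=model.seed)
        with np.load(os.path.join(path, "model.npz")) as z:
            model.net.load_state_dict({k: z[k] for k in z.files})
        hp = {k: (tuple(v) if isinstance(v, list) else v) for k, v in hp.items()}
    else:
        model = joblib.load(os.path.join(path, "model.joblib"))
    spec = ClassifierSpec(family=fam, hyperparameters=hp, seed=sd["seed"])
    return TrainedClassifier(spec=spec, model=model,
                             validation_auroc=meta["validation_auroc"],
                             n_features=meta["n_features"])
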