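"""Logistic-regression ensemble producing the final score P_Real.

The ensemble stacks the anomaly-model recovery score (``l_ecfp4``), the
classifier probability (``p_real_clf``) and molecular properties into a
standardized logistic regression. Which properties enter is decided by
enumerating all subsets of {sascore, qed, mw, logp} on the ensemble
validation split; ties prefer the smaller set, then the declared feature
order. P_Real is the fitted probability of the "real" class, in [0, 1].
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from . import anomaly, chem, classify

logger = logging.getLogger(__name__)

FEATURE_ORDER = ("l_ecfp4", "p_real_clf", "sascore", "qed", "mw", "logp")
BASE_FEATURES = ("l_ecfp4", "p_real_clf")
OPTIONAL_FEATURES = ("sascore", "qed", "mw", "logp")


@dataclass
class EnsembleModel:
    feature_set: tuple[str, ...]
    coef: np.ndarray  # logistic coefficients on standardized features
    intercept: float
    mean: np.ndarray  # per-feature standardization mean
    scale: np.ndarray  # per-feature standardization sd
    seed: int = 0


def build_features(
    molecules,
    anomaly_model: anomaly.TrainedAnomalyModel,
    classifier: classify.TrainedClassifier,
    fps: np.ndarray | None = None,
) -> pd.DataFrame:
    """One feature row per valid molecule; invalid rows are skipped with a warning.

    Columns cover every candidate feature; selection happens later.
    """
    mols = list(molecules)
    valid_idx = [i for i, m in enumerate(mols) if m.valid]
    if len(valid_idx) < len(mols):
        logger.warning("skipping %d invalid molecules in feature building",
                       len(mols) - len(valid_idx))
    if not valid_idx:
        return pd.DataFrame(columns=["index"] + list(FEATURE_ORDER)).set_index("index")
    kept = [mols[i] for i in valid_idx]
    if fps is None:
        X = chem.fingerprint_matrix(kept, n_bits=anomaly_model.n_bits)
    else:
        X = np.asarray(fps)[valid_idx]
    l_ecfp4 = anomaly.score_batch(anomaly_model, X)
    p_clf = classify.predict_proba(classifier, X)
    props = [chem.properties(m) for m in kept]
    return pd.DataFrame(
        {
            "l_ecfp4": l_ecfp4,
            "p_real_clf": p_clf,
            "sascore": [p.sascore for p in props],
            "qed": [p.qed for p in props],
            "mw": [p.mw for p in props],
            "logp": [p.logp for p in props],
        },
        index=pd.Index(valid_idx, name="index"),
    )


def _standardize_fit(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = F.mean(axis=0)
    scale = F.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return mean, scale


def _fit_lr(F: np.ndarray, y: np.ndarray, seed: int) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    mean, scale = _standardize_fit(F)
    Z = (F - mean) / scale
    lr = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000, random_state=seed)
    lr.fit(Z, y)
    return lr.coef_.ravel().copy(), float(lr.intercept_[0]), mean, scale


def select_feature_set(
    F_train: pd.DataFrame,
    y_train: np.ndarray,
    F_val: pd.DataFrame,
    y_val: np.ndarray,
    base: tuple[str, ...] = BASE_FEATURES,
    optional: tuple[str, ...] = OPTIONAL_FEATURES,
    seed: int = 0,
) -> tuple[str, ...]:
    """Enumerate base ∪ S for every subset S of the optional features.

    Winner is the highest validation AUROC; exact ties go to the smaller
    set, then to earlier subsets in declared feature order. Constant
    (zero-variance) optional features are dropped before enumeration.
    """
    optional = tuple(f for f in optional if f in F_train.columns)
    kept = []
    for f in optional:
        if float(F_train[f].std()) == 0.0:
            logger.warning("dropping constant feature %r before selection", f)
        else:
            kept.append(f)
    best: tuple[tuple[str, ...], float] | None = None
    for size in range(len(kept) + 1):
        for subset in itertools.combinations(kept, size):
            feats = tuple(base) + subset
            coef, b0, mean, scale = _fit_lr(F_train[list(feats)].to_numpy(), y_train, seed)
            z = (F_val[list(feats)].to_numpy() - mean) / scale
            p = 1.0 / (1.0 + np.exp(-(z @ coef + b0)))
            auc = roc_auc_score(y_val, p)
            if best is None or auc > best[1] + 1e-12:
                best = (feats, float(auc))
    assert best is not None
    logger.info("selected ensemble features %s (validation AUROC %.4f)", best[0], best[1])
    return best[0]


def train_ensemble(
    feature_set: tuple[str, ...],
    F_train: pd.DataFrame,
    y_train: np.ndarray,
    seed: int = 0,
) -> EnsembleModel:
    """Standardized logistic fit on the selected features; seeded and reproducible."""
    y = np.asarray(y_train)
    if len(np.unique(y)) < 2:
        raise ValueError("ensemble training data contains a single class")
    missing = [f for f in feature_set if f not in F_train.columns]
    if missing:
        raise KeyError(f"missing ensemble features: {missing}")
    F = F_train[list(feature_set)].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite values in ensemble features")
    coef, b0, mean, scale = _fit_lr(F, y, seed)
    return EnsembleModel(feature_set=tuple(feature_set), coef=coef, intercept=b0,
                         mean=mean, scale=scale, seed=seed)


def predict_p_real(model: EnsembleModel, features: pd.DataFrame | dict) -> np.ndarray:
    """P_Real in [0, 1] for each feature row."""
    if isinstance(features, dict):
        features = pd.DataFrame({k: np.atleast_1d(v) for k, v in features.items()})
    for f in model.feature_set:
        if f not in features.columns:
            raise KeyError(f"missing ensemble feature {f!r}")
    F = features[list(model.feature_set)].to_numpy(dtype=np.float64)
    z = (F - model.mean) / model.scale
    return 1.0 / (1.0 + np.exp(-(z @ model.coef + model.intercept)))


def classify_real(p_real: np.ndarray | float, threshold: float = 0.5):
    """Boolean real/generated call; p_real >= threshold counts as real."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    arr = np.asarray(p_real)
    out = arr >= threshold
    return bool(out) if np.isscalar(p_real) else out
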