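"""Model/Results surface tying the three scoring stages together.

:class:`AnoChem` is constructed from two molecule pools (real and
generated) and ``fit()`` runs the full study: dataset curation with the
moderate-similarity window, autoencoder training on real fingerprints,
classifier family selection, ensemble feature selection and fitting.
The returned :class:`AnoChemResults` carries the fitted stages, the
held-out metrics, a ``summary()`` table, and ``score()`` for new SMILES.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import anomaly, chem, classify, datasets, ensemble, evaluate
from .datasets import LabeledSet, SplitDataset

logger = logging.getLogger(__name__)


_SCORE_COLUMNS = ["id", "canonical_smiles", "l_ecfp4", "p_real_clf", "sascore",
                  "qed", "mw", "logp", "p_real", "predicted_label"]


def score_smiles(
    smiles_list,
    anomaly_model: anomaly.TrainedAnomalyModel,
    classifier: classify.TrainedClassifier,
    ensemble_model: ensemble.EnsembleModel,
    n_bits: int,
    radius: int,
    threshold: float,
) -> pd.DataFrame:
    """Run the three fitted stages over raw SMILES; invalid entries are skipped."""
    mols, _ = chem.parse_many(smiles_list)
    valid = [(i, m) for i, m in enumerate(mols) if m.valid]
    if not valid:
        logger.warning("no valid molecules to score")
        return pd.DataFrame(columns=_SCORE_COLUMNS)
    kept = [m for _, m in valid]
    fps = chem.fingerprint_matrix(kept, n_bits=n_bits, radius=radius)
    F = ensemble.build_features(kept, anomaly_model, classifier, fps=fps)
    p_real = ensemble.predict_p_real(ensemble_model, F)
    out = F.copy()
    out.insert(0, "canonical_smiles", [m.smiles_canonical for m in kept])
    out.insert(0, "id", [str(i) for i, _ in valid])
    out["p_real"] = p_real
    out["predicted_label"] = np.where(
        ensemble.classify_real(p_real, threshold), "real", "generated"
    )
    return out.reset_index(drop=True)


class AnoChem:
    """Real-vs-generated structure scoring model.

    Parameters
    ----------
    real, generated
        Deduplicated molecule pools with labels 1 and 0.
    n_bits, radius
        Fingerprint folding length and Morgan radius (ECFP4 at radius 2).
    window
        Moderate maximal-similarity window [lo, hi) selecting the
        classification dataset.
    ratio
        Train/validation/test ratio for both datasets.
    families
        Classifier families to train and compare.
    threshold
        P_Real cut for the final real/generated call.
    """

    def __init__(
        self,
        real: LabeledSet,
        generated: LabeledSet,
        *,
        n_bits: int = chem.DEFAULT_N_BITS,
        radius: int = chem.DEFAULT_RADIUS,
        window: tuple[float, float] = (0.3, 0.6),
        ratio: tuple[int, int, int] = (9, 1, 1),
        ae_grid=None,
        families: tuple[str, ...] = classify.FAMILIES,
        search_spaces: dict | None = None,
        threshold: float = 0.5,
    ):
        self.real = real
        self.generated = generated
        self.n_bits = n_bits
        self.radius = radius
        self.window = window
        self.ratio = ratio
        self.ae_grid = ae_grid
        self.families = families
        self.search_spaces = search_spaces or {}
        self.threshold = threshold

    @classmethod
    def from_smiles(cls, real_smiles, generated_smiles, **kwargs) -> "AnoChem":
        """Build from raw SMILES iterables; invalid and duplicate entries are dropped."""
        real, _ = datasets.dedupe_and_filter(real_smiles, label=datasets.REAL, source_tag="real")
        gen, _ = datasets.dedupe_and_filter(generated_smiles, label=datasets.GENERATED,
                                            source_tag="generated")
        return cls(real, gen, **kwargs)

    # ------------------------------------------------------------------ fit
    def fit(self, seed: int = 0) -> "AnoChemResults":
        for ls in (self.real, self.generated):
            if ls.fingerprints is None or ls.fingerprints.shape[1] != self.n_bits:
                ls.compute_fingerprints(n_bits=self.n_bits, radius=self.radius)

        pairings = datasets.pair_by_max_similarity(self.generated, self.real)
        d_cls = datasets.build_classification_dataset(
            pairings, self.generated, self.real, seed=seed,
            lo=self.window[0], hi=self.window[1], ratio=self.ratio,
        )
        d_ens = datasets.build_ensemble_dataset(
            d_cls, pairings, self.generated, self.real, seed=seed + 1, ratio=self.ratio,
        )

        # Anomaly stage: train on real fingerprints, holding out the real
        # molecules of the final test partition so the headline metrics
        # are computed on structures the autoencoder never saw.
        ens_test_smiles = set(
            d_ens.manifest.loc[d_ens.manifest["partition"] == "test", "canonical_smiles"]
        )
        ae_rows = [
            i for i, s in enumerate(self.real.canonical_smiles) if s not in ens_test_smiles
        ]
        anomaly_model = anomaly.train_autoencoder(
            self.real.fingerprints[ae_rows], grid=self.ae_grid, seed=seed,
        )

        # Classification stage: family competition on D_cls.
        X_tr, y_tr, _ = d_cls.part("train")
        X_val, y_val, _ = d_cls.part("validation")
        candidates = [
            classify.train_family(
                fam, X_tr, y_tr, X_val, y_val,
                search_space=self.search_spaces.get(fam), seed=seed,
            )
            for fam in self.families
        ]
        best_clf = classify.select_best_family(candidates)
        logger.info("selected classifier family %r (validation AUROC %.4f)",
                    best_clf.spec.family, best_clf.validation_auroc)

        # Ensemble stage: feature selection + logistic fit on D_ens.
        mol_by_id = {}
        for ls in (self.real, self.generated):
            for i, mid in enumerate(ls.ids):
                mol_by_id[mid] = ls.molecules[i]
        feats = {}
        ys = {}
        for part in datasets.PARTS:
            X, y, sub = d_ens.part(part)
            mols = [mol_by_id[mid] for mid in sub["id"]]
            feats[part] = ensemble.build_features(mols, anomaly_model, best_clf, fps=X)
            ys[part] = y
        feature_set = ensemble.select_feature_set(
            feats["train"], ys["train"], feats["validation"], ys["validation"], seed=seed,
        )
        ens_model = ensemble.train_ensemble(feature_set, feats["train"], ys["train"], seed=seed)

        # Held-out evaluation on the D_ens test partition.
        X_te, y_te, sub_te = d_ens.part("test")
        p_real = ensemble.predict_p_real(ens_model, feats["test"])
        p_clf = feats["test"]["p_real_clf"].to_numpy()
        sources = np.where(y_te == datasets.REAL, "real", "generated")
        metrics_ens = evaluate.compute_metrics(y_te, p_real, self.threshold, sources=sources)
        metrics_clf = evaluate.compute_metrics(y_te, p_clf, self.threshold, sources=sources)

        return AnoChemResults(
            model=self,
            seed=seed,
            pairings=pairings,
            d_cls=d_cls,
            d_ens=d_ens,
            anomaly_model=anomaly_model,
            classifiers=candidates,
            classifier=best_clf,
            feature_set=feature_set,
            ensemble_model=ens_model,
            metrics_ensemble=metrics_ens,
            metrics_classifier=metrics_clf,
            test_scores=pd.DataFrame(
                {"id": sub_te["id"].to_numpy(), "label": y_te, "p_real": p_real,
                 "p_real_clf": p_clf}
            ),
        )


@dataclass
class AnoChemResults:
    """Fitted three-stage model plus held-out diagnostics."""

    model: AnoChem
    seed: int
    pairings: list = field(repr=False)
    d_cls: SplitDataset = field(repr=False)
    d_ens: SplitDataset = field(repr=False)
    anomaly_model: anomaly.TrainedAnomalyModel = field(repr=False)
    classifiers: list[classify.TrainedClassifier] = field(repr=False)
    classifier: classify.TrainedClassifier = field(repr=False)
    feature_set: tuple[str, ...]
    ensemble_model: ensemble.EnsembleModel = field(repr=False)
    metrics_ensemble: evaluate.MetricsReport
    metrics_classifier: evaluate.MetricsReport
    test_scores: pd.DataFrame = field(repr=False)

    # ------------------------------------------------------------- scoring
    def score(self, smiles_list, threshold: float | None = None) -> pd.DataFrame:
        """Score new SMILES; invalid entries are skipped with a warning.

        Returns one row per valid molecule: canonical SMILES, the three
        stage outputs, the properties, P_Real and the real/generated call.
        """
        return score_smiles(
            smiles_list, self.anomaly_model, self.classifier, self.ensemble_model,
            self.model.n_bits, self.model.radius,
            self.model.threshold if threshold is None else threshold,
        )

    # ------------------------------------------------------------- summary
    def summary(self) -> str:
        m, c = self.metrics_ensemble, self.metrics_classifier
        lines = [
            "Real-vs-generated structure scoring",
            "=" * 58,
            f"molecules (real / generated): {len(self.model.real)} / {len(self.model.generated)}",
            f"D_cls: {len(self.d_cls)}   D_ens: {len(self.d_ens)}"
            f"   window [{self.model.window[0]}, {self.model.window[1]})",
            f"autoencoder: widths {self.anomaly_model.spec.layer_widths},"
            f" lr {self.anomaly_model.spec.learning_rate:g},"
            f" held-out BCE {self.anomaly_model.test_loss:.4f}",
            f"classifier: {self.classifier.spec.family}"
            f" (validation AUROC {self.classifier.validation_auroc:.4f})",
            f"ensemble features: {', '.join(self.feature_set)}",
            "-" * 58,
            f"{'test metric':<16}{'ensemble':>12}{'classifier':>12}",
        ]
        for name in ("accuracy", "auroc", "precision", "recall", "f1", "mcc"):
            lines.append(f"{name:<16}{getattr(m, name):>12.4f}{getattr(c, name):>12.4f}")
        for src in m.per_source_accuracy:
            lines.append(
                f"{'acc (' + src + ')':<16}{m.per_source_accuracy[src]:>12.4f}"
                f"{c.per_source_accuracy.get(src, float('nan')):>12.4f}"
            )
        lines.append(f"{'n (test)':<16}{m.n:>12d}{c.n:>12d}")
        lines.append("=" * 58)
        return "\n".join(lines)

    # --------------------------------------------------------- persistence
    def save(self, path: str) -> None:
        """Bundle all three stages + manifest JSON into a directory."""
        os.makedirs(path, exist_ok=True)
        anomaly.save_model(self.anomaly_model, os.path.join(path, "anomaly"))
        classify.save_classifier(self.classifier, os.path.join(path, "classifier"))
        np.savez(
            os.path.join(path, "ensemble.npz"),
            coef=self.ensemble_model.coef,
            intercept=np.array([self.ensemble_model.intercept]),
            mean=self.ensemble_model.mean,
            scale=self.ensemble_model.scale,
        )
        manifest = {
            "seed": self.seed,
            "n_bits": self.model.n_bits,
            "radius": self.model.radius,
            "window": list(self.model.window),
            "ratio": list(self.model.ratio),
            "threshold": self.model.threshold,
            "feature_set": list(self.feature_set),
            "classifier_family": self.classifier.spec.family,
            "metrics": {
                "ensemble": self.metrics_ensemble.to_frame().to_dict("records"),
                "classifier": self.metrics_classifier.to_frame().to_dict("records"),
            },
        }
        with open(os.path.join(path, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)


@dataclass
class ScoringBundle:
    """The persisted stages needed to score new molecules (no training data)."""

    anomaly_model: anomaly.TrainedAnomalyModel
    classifier: classify.TrainedClassifier
    ensemble_model: ensemble.EnsembleModel
    n_bits: int
    radius: int
    threshold: float

    @classmethod
    def load(cls, path: str) -> "ScoringBundle":
        with open(os.path.join(path, "manifest.json")) as fh:
            manifest = json.load(fh)
        with np.load(os.path.join(path, "ensemble.npz")) as z:
            ens = ensemble.EnsembleModel(
                feature_set=tuple(manifest["feature_set"]),
                coef=z["coef"], intercept=float(z["intercept"][0]),
                mean=z["mean"], scale=z["scale"],
            )
        return cls(
            anomaly_model=anomaly.load_model(os.path.join(path, "anomaly")),
            classifier=classify.load_classifier(os.path.join(path, "classifier")),
            ensemble_model=ens,
            n_bits=manifest["n_bits"],
            radius=manifest["radius"],
            threshold=manifest["threshold"],
        )

    def score(self, smiles_list, threshold: float | None = None) -> pd.DataFrame:
        return score_smiles(
            smiles_list, self.anomaly_model, self.classifier, self.ensemble_model,
            self.n_bits, self.radius,
            self.threshold if threshold is None else threshold,
        )
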