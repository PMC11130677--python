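"""Evaluation: classification metrics, correlations, importance, bit co-occurrence.

Threshold metrics come from the confusion matrix at a fixed cut; AUROC is
rank-based (midranks for ties). Fingerprint-bit co-occurrence compares the
observed joint count of two bits against the independence expectation

    E[co-occurrence] = p_Ba * p_Bb * n

where p_Bx is the marginal frequency of bit x over n molecules; the ratio
observed/expected is tested with a chi-squared test on the 2x2 contingency
table and with Fisher's exact test. Undefined quantities (single-class
AUROC/MCC, zero-variance correlations, zero-marginal bits) are reported as
NaN sentinels, never silently as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
    roc_auc_score,
)

logger = logging.getLogger(__name__)

NA = float("nan")


@dataclass
class MetricsReport:
    accuracy: float
    auroc: float
    precision: float
    recall: float
    f1: float
    mcc: float
    n: int
    per_source_accuracy: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("accuracy", self.accuracy)]
        rows += [(f"accuracy ({s})", a) for s, a in self.per_source_accuracy.items()]
        rows += [("auroc", self.auroc), ("precision", self.precision),
                 ("recall", self.recall), ("f1", self.f1), ("mcc", self.mcc),
                 ("n", self.n)]
        return pd.DataFrame(rows, columns=["metric", "value"])


def compute_metrics(
    labels: np.ndarray,
    scores: np.ndarray,
    threshold: float = 0.5,
    sources: np.ndarray | None = None,
) -> MetricsReport:
    """Confusion-matrix metrics at ``threshold`` plus rank-based AUROC.

    With a single class present, AUROC and MCC are NaN; the remaining
    metrics are still computed.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.size < 2:
        raise ValueError("labels and scores must be equal-length with n >= 2")
    pred = (s >= threshold).astype(int)
    two_classes = len(np.unique(y)) == 2
    rep = MetricsReport(
        accuracy=float(accuracy_score(y, pred)),
        auroc=float(roc_auc_score(y, s)) if two_classes else NA,
        precision=float(precision_score(y, pred, zero_division=0)),
        recall=float(recall_score(y, pred, zero_division=0)),
        f1=float(f1_score(y, pred, zero_division=0)),
        mcc=float(matthews_corrcoef(y, pred)) if two_classes else NA,
        n=int(y.size),
    )
    if sources is not None:
        sources = np.asarray(sources)
        for src in pd.unique(sources):
            m = sources == src
            rep.per_source_accuracy[str(src)] = float(accuracy_score(y[m], pred[m]))
    return rep


def correlations(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(Pearson r, Spearman rho); NaN sentinels when either side is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        return NA, NA
    return float(stats.pearsonr(x, y).statistic), float(stats.spearmanr(x, y).statistic)


@dataclass
class ImportanceReport:
    """Impurity-importance ranking of fingerprint bits from a random forest."""

    table: pd.DataFrame  # bit, importance; sorted descending, filtered/capped
    n_above_threshold: int
    cumulative_counts: dict[float, int]  # mass -> bits needed to reach it


def cumulative_importance_count(importances: np.ndarray, mass: float) -> int:
    """Smallest number of top bits whose importances sum to >= mass."""
    cs = np.cumsum(np.sort(importances)[::-1])
    idx = np.searchsorted(cs, mass)
    return int(idx + 1) if idx < cs.size else int(cs.size)


def feature_importance_topk(
    rf_model, threshold: float = 0.01, top_k: int | None = 12
) -> ImportanceReport:
    """Rank fingerprint bits by random-forest impurity importance.

    Importances sum to 1 before filtering; ``threshold`` drops weak bits
    and ``top_k`` caps the list. Cumulative counts report how many top
    bits reach 0.5 and 0.9 of the total importance mass.
    """
    imp = getattr(rf_model, "feature_importances_", None)
    if imp is None:
        raise ValueError("model is not a fitted random forest (no feature_importances_)")
    imp = np.asarray(imp, dtype=float)
    order = np.argsort(-imp, kind="stable")
    df = pd.DataFrame({"bit": order, "importance": imp[order]})
    n_above = int((df["importance"] > threshold).sum())
    df = df[df["importance"] > threshold]
    if top_k is not None:
        df = df.head(top_k)
    return ImportanceReport(
        table=df.reset_index(drop=True),
        n_above_threshold=n_above,
        cumulative_counts={m: cumulative_importance_count(imp, m) for m in (0.5, 0.9)},
    )


@dataclass
class CooccurrenceRecord:
    bit_a: int
    bit_b: int
    n: int
    observed: int
    expected: float  # p_Ba * p_Bb * n under independence
    ratio: float  # observed / expected; NaN when a marginal is zero
    chi2_p: float
    fisher_p: float
    contingency: np.ndarray = field(repr=False, default=None)  # [[both, a_only], [b_only, neither]]


def cooccurrence(
    bit_matrix: np.ndarray,
    bit_pairs: list[tuple[int, int]],
    chi2_correction: str = "auto",
) -> list[CooccurrenceRecord]:
    """Observed vs expected co-occurrence for the given bit pairs.

    ``chi2_correction``: "auto" applies Yates continuity correction when
    any expected cell is below 5, "always"/"never" force it on or off.
    Pairs where either bit never (or always) fires get NaN ratio/p-values.
    """
    X = np.asarray(bit_matrix)
    if X.ndim != 2:
        raise ValueError("bit matrix must be 2-D")
    n = X.shape[0]
    out: list[CooccurrenceRecord] = []
    for a, b in bit_pairs:
        if a == b or not (0 <= a < X.shape[1] and 0 <= b < X.shape[1]):
            raise ValueError(f"invalid bit pair ({a}, {b})")
        ca, cb = X[:, a].astype(bool), X[:, b].astype(bool)
        na, nb = int(ca.sum()), int(cb.sum())
        both = int((ca & cb).sum())
        table = np.array([[both, na - both], [nb - both, n - na - nb + both]])
        expected = (na / n) * (nb / n) * n if n else 0.0
        if na == 0 or nb == 0 or na == n or nb == n:
            logger.warning("bit pair (%d, %d): degenerate marginal; tests skipped", a, b)
            out.append(CooccurrenceRecord(a, b, n, both, expected, NA, NA, NA, table))
            continue
        exp_cells = np.outer(table.sum(1), table.sum(0)) / n
        if chi2_correction == "auto":
            correction = bool((exp_cells < 5).any())
        elif chi2_correction in ("always", "never"):
            correction = chi2_correction == "always"
        else:
            raise ValueError(f"unknown chi2_correction {chi2_correction!r}")
        chi2_p = float(stats.chi2_contingency(table, correction=correction).pvalue)
        fisher_p = float(stats.fisher_exact(table).pvalue)
        out.append(CooccurrenceRecord(a, b, n, both, expected, both / expected,
                                      chi2_p, fisher_p, table))
    return out


def cooccurrence_frame(records: list[CooccurrenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"bit_a": r.bit_a, "bit_b": r.bit_b, "n": r.n, "observed": r.observed,
             "expected": r.expected, "ratio": r.ratio, "chi2_p": r.chi2_p,
             "fisher_p": r.fisher_p}
            for r in records
        ]
    )


def audit_report(
    scored_sets: dict[str, np.ndarray], threshold: float = 0.5, n_hist_bins: int = 10
) -> pd.DataFrame:
    """Per-set summary of final scores: fraction predicted real, mean ± SD, histogram.

    Empty sets are skipped with a warning.
    """
    rows = []
    for name, scores in scored_sets.items():
        s = np.asarray(scores, dtype=float)
        if s.size == 0:
            logger.warning("score set %r is empty; skipped", name)
            continue
        hist, _ = np.histogram(s, bins=n_hist_bins, range=(0.0, 1.0))
        rows.append(
            {
                "set": name,
                "n": int(s.size),
                "fraction_real": float(np.mean(s >= threshold)),
                "mean_p_real": float(s.mean()),
                "sd_p_real": float(s.std()),
                "histogram": hist.tolist(),
            }
        )
    return pd.DataFrame(rows, columns=["set", "n", "fraction_real", "mean_p_real",
                                       "sd_p_real", "histogram"])
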