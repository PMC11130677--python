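"""Training-set construction for real-vs-generated scoring.

The curation recipe: drop invalid and duplicate structures; pair every
generated molecule with its most similar real molecule by ECFP4 Tanimoto;
keep the generated molecules of moderate maximal similarity
(0.6 > S_T >= 0.3) together with their matched real counterparts as the
classification dataset D_cls; everything not used to train or validate
the classifier becomes the ensemble dataset D_ens. Both are split
9:1:1 into train/validation/test, stratified by label and seeded.

Datasets are carried as a manifest ``pandas.DataFrame`` (one row per
molecule: id, canonical_smiles, label, s_t, counterpart_id, partition)
plus a row-aligned fingerprint matrix.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import chem
from .chem import Molecule

logger = logging.getLogger(__name__)

REAL, GENERATED = 1, 0
PARTS = ("train", "validation", "test")


@dataclass
class FilterReport:
    """Bookkeeping for dedupe_and_filter; counts satisfy n_in = n_invalid + n_duplicate + n_out."""

    n_in: int
    n_invalid: int
    n_duplicate: int
    n_out: int


@dataclass
class LabeledSet:
    """Unique valid molecules sharing one binary label (1 = real, 0 = generated)."""

    molecules: list[Molecule]
    label: int
    source_tag: str = ""
    ids: list[str] = field(default_factory=list)
    fingerprints: np.ndarray | None = None  # (n, n_bits) uint8, row-aligned

    def __post_init__(self):
        if not self.ids:
            self.ids = [f"{self.source_tag or 'mol'}_{i}" for i in range(len(self.molecules))]
        if len(self.ids) != len(self.molecules):
            raise ValueError("ids and molecules length mismatch")

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def canonical_smiles(self) -> list[str]:
        return [m.smiles_canonical for m in self.molecules]  # type: ignore[misc]

    def compute_fingerprints(self, n_bits: int = chem.DEFAULT_N_BITS, radius: int = chem.DEFAULT_RADIUS):
        self.fingerprints = chem.fingerprint_matrix(self.molecules, n_bits=n_bits, radius=radius)
        return self.fingerprints


@dataclass(frozen=True)
class SimilarityPairing:
    """A generated molecule and the real molecule attaining its maximal Tanimoto."""

    generated_id: str
    real_id: str
    s_t: float


@dataclass
class SplitDataset:
    """Manifest + aligned fingerprints for one dataset (D_cls or D_ens)."""

    manifest: pd.DataFrame  # id, canonical_smiles, label, s_t, counterpart_id, partition
    fingerprints: np.ndarray

    def part(self, which: str) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
        """(X, y, manifest rows) for one partition."""
        if which not in PARTS:
            raise ValueError(f"unknown partition {which!r}")
        mask = (self.manifest["partition"] == which).to_numpy()
        sub = self.manifest.loc[mask]
        return self.fingerprints[mask], sub["label"].to_numpy(), sub

    def __len__(self) -> int:
        return len(self.manifest)


def dedupe_and_filter(
    raw: Iterable[str], label: int, source_tag: str = "", ids: Sequence[str] | None = None
) -> tuple[LabeledSet, FilterReport]:
    """Keep valid, unique-by-canonical-SMILES molecules; report the counts.

    Raises
    ------
    ValueError
        If nothing survives filtering (there would be nothing to train on).
    """
    raw = list(raw)
    mols, n_invalid = chem.parse_many(raw)
    seen: set[str] = set()
    kept: list[Molecule] = []
    kept_ids: list[str] = []
    n_dup = 0
    for i, m in enumerate(mols):
        if not m.valid:
            continue
        if m.smiles_canonical in seen:
            n_dup += 1
            continue
        seen.add(m.smiles_canonical)  # type: ignore[arg-type]
        kept.append(m)
        kept_ids.append(ids[i] if ids is not None else f"{source_tag or 'mol'}_{i}")
    report = FilterReport(n_in=len(raw), n_invalid=n_invalid, n_duplicate=n_dup, n_out=len(kept))
    assert report.n_in == report.n_invalid + report.n_duplicate + report.n_out
    logger.info(
        "filter[%s]: %d in, %d invalid, %d duplicate, %d out",
        source_tag, report.n_in, report.n_invalid, report.n_duplicate, report.n_out,
    )
    if not kept:
        raise ValueError(f"no valid unique molecules left in set {source_tag!r}")
    return LabeledSet(molecules=kept, label=label, source_tag=source_tag, ids=kept_ids), report


def pair_by_max_similarity(generated: LabeledSet, real: LabeledSet) -> list[SimilarityPairing]:
    """For each generated molecule, its maximal Tanimoto against the real set.

    Ties on the maximum are broken toward the real molecule with the
    lexicographically smallest canonical SMILES, which makes the pairing
    independent of input order.
    """
    if len(generated) == 0 or len(real) == 0:
        raise ValueError("both sets must be non-empty")
    if generated.fingerprints is None or real.fingerprints is None:
        raise ValueError("fingerprints must be computed before pairing")
    order = np.argsort(np.asarray(real.canonical_smiles, dtype=object), kind="stable")
    sim = chem.tanimoto_matrix(generated.fingerprints, real.fingerprints[order])
    best = np.argmax(sim, axis=1)  # first max in SMILES-sorted order = smallest SMILES
    return [
        SimilarityPairing(
            generated_id=generated.ids[i],
            real_id=real.ids[order[best[i]]],
            s_t=float(sim[i, best[i]]),
        )
        for i in range(len(generated))
    ]


def moderate_window(
    pairs: Sequence[SimilarityPairing],
    generated: LabeledSet,
    real: LabeledSet,
    lo: float = 0.3,
    hi: float = 0.6,
) -> pd.DataFrame:
    """Classification pool: generated molecules with lo <= S_T < hi plus their counterparts.

    The real counterparts are deduplicated (several generated molecules may
    share one nearest real neighbour). Returns an unsplit manifest.
    """
    if not lo <= hi:
        raise ValueError("window bounds must satisfy lo <= hi")
    gen_idx = {gid: i for i, gid in enumerate(generated.ids)}
    real_idx = {rid: i for i, rid in enumerate(real.ids)}
    rows = []
    seen_real: set[str] = set()
    for p in pairs:
        if not (lo <= p.s_t < hi):
            continue
        gi = gen_idx[p.generated_id]
        rows.append(
            {
                "id": p.generated_id,
                "canonical_smiles": generated.molecules[gi].smiles_canonical,
                "label": GENERATED,
                "s_t": p.s_t,
                "counterpart_id": p.real_id,
            }
        )
        if p.real_id not in seen_real:
            seen_real.add(p.real_id)
            ri = real_idx[p.real_id]
            rows.append(
                {
                    "id": p.real_id,
                    "canonical_smiles": real.molecules[ri].smiles_canonical,
                    "label": REAL,
                    "s_t": np.nan,
                    "counterpart_id": "",
                }
            )
    if not rows:
        logger.warning("moderate similarity window [%.2f, %.2f) retained nothing", lo, hi)
        return pd.DataFrame(columns=["id", "canonical_smiles", "label", "s_t", "counterpart_id"])
    return pd.DataFrame(rows)


def split_9_1_1(
    manifest: pd.DataFrame, seed: int, ratio: tuple[int, int, int] = (9, 1, 1)
) -> pd.DataFrame:
    """Assign train/validation/test partitions, label-stratified and seeded.

    Partition sizes are exact integers (largest-remainder on the global
    counts), so n = 1100 at 9:1:1 gives 900/100/100.
    """
    n = len(manifest)
    if n < sum(ratio) + 2:
        raise ValueError(f"dataset too small to split: n={n}")
    total = sum(ratio)
    raw = [n * r / total for r in ratio]
    sizes = [int(np.floor(x)) for x in raw]
    rem = np.argsort([-(x - s) for x, s in zip(raw, sizes)], kind="stable")
    for i in range(n - sum(sizes)):
        sizes[rem[i]] += 1
    idx = np.arange(n)
    y = manifest["label"].to_numpy()

    def _strat(labels):  # sklearn needs >= 2 members per class to stratify
        vals, counts = np.unique(labels, return_counts=True)
        return labels if len(vals) > 1 and counts.min() >= 2 else None

    tr, rest = train_test_split(idx, train_size=sizes[0], random_state=seed, stratify=_strat(y))
    val, te = train_test_split(rest, train_size=sizes[1], random_state=seed,
                               stratify=_strat(y[rest]))
    part = np.empty(n, dtype=object)
    part[tr], part[val], part[te] = "train", "validation", "test"
    out = manifest.copy()
    out["partition"] = part
    return out


def build_classification_dataset(
    pairs: Sequence[SimilarityPairing],
    generated: LabeledSet,
    real: LabeledSet,
    seed: int,
    lo: float = 0.3,
    hi: float = 0.6,
    ratio: tuple[int, int, int] = (9, 1, 1),
) -> SplitDataset:
    """Moderate-window manifest, split 9:1:1, with aligned fingerprints (D_cls)."""
    manifest = moderate_window(pairs, generated, real, lo=lo, hi=hi)
    if len(manifest) == 0:
        return SplitDataset(manifest=manifest.assign(partition=pd.Series(dtype=object)),
                            fingerprints=np.zeros((0, 0), dtype=np.uint8))
    manifest = split_9_1_1(manifest, seed=seed, ratio=ratio)
    fps = _gather_fps(manifest, generated, real)
    return SplitDataset(manifest=manifest.reset_index(drop=True), fingerprints=fps)


def build_ensemble_dataset(
    d_cls: SplitDataset,
    pairs: Sequence[SimilarityPairing],
    generated: LabeledSet,
    real: LabeledSet,
    seed: int,
    ratio: tuple[int, int, int] = (9, 1, 1),
) -> SplitDataset:
    """Everything not in D_cls train/validation, split 9:1:1 (D_ens).

    Exclusion is by canonical SMILES; the no-leakage property
    D_ens ∩ (D_cls-train ∪ D_cls-validation) = ∅ is asserted.
    """
    used = set(
        d_cls.manifest.loc[d_cls.manifest["partition"].isin(["train", "validation"]),
                           "canonical_smiles"]
    )
    s_t_of = {p.generated_id: p.s_t for p in pairs}
    counterpart_of = {p.generated_id: p.real_id for p in pairs}
    rows = []
    for ls in (real, generated):
        for i, m in enumerate(ls.molecules):
            if m.smiles_canonical in used:
                continue
            rows.append(
                {
                    "id": ls.ids[i],
                    "canonical_smiles": m.smiles_canonical,
                    "label": ls.label,
                    "s_t": s_t_of.get(ls.ids[i], np.nan),
                    "counterpart_id": counterpart_of.get(ls.ids[i], ""),
                }
            )
    manifest = pd.DataFrame(rows, columns=["id", "canonical_smiles", "label", "s_t", "counterpart_id"])
    if len(manifest) == 0:
        logger.warning("ensemble dataset is empty: classification stage used every molecule")
        return SplitDataset(manifest=manifest.assign(partition=pd.Series(dtype=object)),
                            fingerprints=np.zeros((0, 0), dtype=np.uint8))
    assert not (set(manifest["canonical_smiles"]) & used), "leakage between D_ens and D_cls train/val"
    manifest = split_9_1_1(manifest, seed=seed, ratio=ratio)
    fps = _gather_fps(manifest, generated, real)
    return SplitDataset(manifest=manifest.reset_index(drop=True), fingerprints=fps)


def _gather_fps(manifest: pd.DataFrame, generated: LabeledSet, real: LabeledSet) -> np.ndarray:
    by_id: dict[str, tuple[LabeledSet, int]] = {}
    for ls in (generated, real):
        for i, mid in enumerate(ls.ids):
            by_id[mid] = (ls, i)
    n_bits = (generated.fingerprints if generated.fingerprints is not None else real.fingerprints).shape[1]
    out = np.zeros((len(manifest), n_bits), dtype=np.uint8)
    for row, mid in enumerate(manifest["id"]):
        ls, i = by_id[mid]
        if ls.fingerprints is None:
            raise ValueError("fingerprints missing")
        out[row] = ls.fingerprints[i]
    return out


def write_manifest(ds: SplitDataset, csv_path: str, sidecar: dict | None = None) -> None:
    """Dataset manifest CSV plus a JSON sidecar (seed, window, ratio, counts)."""
    ds.manifest.to_csv(csv_path, index=False)
    if sidecar is not None:
        with open(csv_path + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2, default=str)
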