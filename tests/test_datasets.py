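"""Dataset curation: filtering, similarity pairing, window, splits, leakage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from anochem import datasets
from anochem.chem import Molecule
from anochem.datasets import (
    GENERATED,
    REAL,
    LabeledSet,
    SimilarityPairing,
    build_ensemble_dataset,
    dedupe_and_filter,
    moderate_window,
    pair_by_max_similarity,
    split_9_1_1,
)

VALID_POOL = ["CCO", "OCC", "c1ccccc1", "CC(=O)O", "CCN", "CCC", "CCCC", "C1CCCCC1"]
INVALID_POOL = ["C1CC", "xyz", "C(("]


def _synthetic_set(n, n_bits, rng, label=REAL, tag="s"):
    """LabeledSet with synthetic fingerprints and placeholder structures."""
    mols = [Molecule(smiles_input=f"M{i}", smiles_canonical=f"M{i:04d}", valid=True)
            for i in range(n)]
    ls = LabeledSet(molecules=mols, label=label, source_tag=tag)
    ls.fingerprints = (rng.random((n, n_bits)) < 0.3).astype(np.uint8)
    # avoid all-zero rows
    ls.fingerprints[:, 0] = 1
    return ls


class TestDedupe:
    def test_duplicates_and_invalid_dropped(self):
        ls, rep = dedupe_and_filter(["CCO", "OCC", "C1CC"], label=REAL)
        assert len(ls) == 1 and rep.n_invalid == 1 and rep.n_duplicate == 1

    def test_distinct_valid_all_kept(self):
        ls, rep = dedupe_and_filter(VALID_POOL[2:], label=REAL)
        assert rep.n_out == len(VALID_POOL) - 2 and rep.n_invalid == 0

    def test_empty_result_raises(self):
        with pytest.raises(ValueError):
            dedupe_and_filter(["C1CC"], label=REAL)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.lists(st.sampled_from(VALID_POOL + INVALID_POOL), min_size=1, max_size=15))
    def test_count_conservation_and_uniqueness(self, raw):
        try:
            ls, rep = dedupe_and_filter(raw, label=GENERATED)
        except ValueError:
            assert not any(s in VALID_POOL for s in raw)
            return
        assert rep.n_in == rep.n_invalid + rep.n_duplicate + rep.n_out
        smiles = ls.canonical_smiles
        assert len(smiles) == len(set(smiles))


class TestPairing:
    def test_exact_copy_pairs_at_unit_similarity(self):
        real, _ = dedupe_and_filter(["CCO", "c1ccccc1"], label=REAL, source_tag="r")
        gen, _ = dedupe_and_filter(["OCC"], label=GENERATED, source_tag="g")
        real.compute_fingerprints()
        gen.compute_fingerprints()
        (p,) = pair_by_max_similarity(gen, real)
        assert p.s_t == 1.0 and p.real_id == real.ids[0]

    def test_matches_exhaustive_scan(self, rng):
        """Pairing equals a brute-force all-pairs argmax on 50x50 fingerprints."""
        real = _synthetic_set(50, 128, rng, REAL, "r")
        gen = _synthetic_set(50, 128, rng, GENERATED, "g")
        pairs = pair_by_max_similarity(gen, real)
        from anochem.chem import tanimoto_matrix

        S = tanimoto_matrix(gen.fingerprints, real.fingerprints)
        for i, p in enumerate(pairs):
            assert p.s_t == pytest.approx(S[i].max(), abs=1e-12)

    def test_tie_breaks_to_smallest_canonical_smiles(self, rng):
        real = _synthetic_set(2, 32, rng, REAL, "r")
        real.fingerprints = np.tile(real.fingerprints[:1], (2, 1))  # identical rows
        gen = _synthetic_set(1, 32, rng, GENERATED, "g")
        gen.fingerprints = real.fingerprints[:1].copy()
        (p,) = pair_by_max_similarity(gen, real)
        winner = min(zip(real.canonical_smiles, real.ids))[1]
        assert p.real_id == winner

    def test_missing_fingerprints_rejected(self):
        real, _ = dedupe_and_filter(["CCO"], label=REAL)
        gen, _ = dedupe_and_filter(["CCN"], label=GENERATED)
        with pytest.raises(ValueError):
            pair_by_max_similarity(gen, real)


class TestModerateWindow:
    def _sets(self, rng, n_gen=4):
        real = _synthetic_set(n_gen, 32, rng, REAL, "r")
        gen = _synthetic_set(n_gen, 32, rng, GENERATED, "g")
        return real, gen

    def test_boundary_semantics_lower_closed_upper_open(self, rng):
        real, gen = self._sets(rng)
        pairs = [SimilarityPairing(gen.ids[i], real.ids[i], s)
                 for i, s in enumerate([0.29, 0.30, 0.59, 0.60])]
        m = moderate_window(pairs, gen, real)
        retained = m.loc[m["label"] == GENERATED, "s_t"].tolist()
        assert sorted(retained) == [0.30, 0.59]

    def test_all_identical_yields_empty(self, rng):
        real, gen = self._sets(rng)
        pairs = [SimilarityPairing(gen.ids[i], real.ids[i], 1.0) for i in range(4)]
        assert len(moderate_window(pairs, gen, real)) == 0

    def test_counterparts_deduplicated(self, rng):
        real, gen = self._sets(rng)
        pairs = [SimilarityPairing(gen.ids[i], real.ids[0], 0.4) for i in range(4)]
        m = moderate_window(pairs, gen, real)
        assert (m["label"] == REAL).sum() == 1 and (m["label"] == GENERATED).sum() == 4

    def test_widening_is_monotone(self, rng):
        real, gen = self._sets(rng, n_gen=50)
        s_values = rng.random(50)
        pairs = [SimilarityPairing(gen.ids[i], real.ids[i], float(s_values[i]))
                 for i in range(50)]
        narrow = set(moderate_window(pairs, gen, real, 0.3, 0.6)["id"])
        wide = set(moderate_window(pairs, gen, real, 0.2, 0.8)["id"])
        assert narrow <= wide

    def test_retained_count_matches_brute_force(self, rng):
        real = _synthetic_set(1000, 32, rng, REAL, "r")
        gen = _synthetic_set(1000, 32, rng, GENERATED, "g")
        s = rng.random(1000)
        pairs = [SimilarityPairing(gen.ids[i], real.ids[i], float(s[i])) for i in range(1000)]
        m = moderate_window(pairs, gen, real)
        assert (m["label"] == GENERATED).sum() == int(np.sum((s >= 0.3) & (s < 0.6)))


class TestSplit:
    def _manifest(self, n, frac_pos=0.5):
        labels = np.zeros(n, dtype=int)
        labels[: int(n * frac_pos)] = 1
        return pd.DataFrame({"id": [str(i) for i in range(n)], "label": labels})

    @pytest.mark.parametrize("frac_pos", [0.5, 0.4])
    def test_exact_sizes_at_1100(self, frac_pos):
        out = split_9_1_1(self._manifest(1100, frac_pos), seed=0)
        counts = out["partition"].value_counts()
        assert counts["train"] == 900 and counts["validation"] == 100 and counts["test"] == 100

    def test_same_seed_reproduces_assignment(self):
        m = self._manifest(200)
        a = split_9_1_1(m, seed=3)["partition"]
        b = split_9_1_1(m, seed=3)["partition"]
        assert a.equals(b)

    def test_rounding_at_115(self):
        out = split_9_1_1(self._manifest(115), seed=0)
        counts = out["partition"].value_counts()
        assert counts.sum() == 115
        assert abs(counts["train"] - 94.1) <= 1
        assert abs(counts["validation"] - 10.45) <= 1
        assert abs(counts["test"] - 10.45) <= 1

    def test_stratification_preserves_class_balance(self):
        out = split_9_1_1(self._manifest(1100, 0.3), seed=1)
        for part in datasets.PARTS:
            sub = out[out["partition"] == part]
            assert abs(sub["label"].mean() - 0.3) < 0.02

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            split_9_1_1(self._manifest(10), seed=0)


class TestEnsembleDataset:
    def test_no_leakage_against_classification_split(self, rng):
        real = _synthetic_set(120, 64, rng, REAL, "r")
        gen = _synthetic_set(120, 64, rng, GENERATED, "g")
        pairs = pair_by_max_similarity(gen, real)
        d_cls = datasets.build_classification_dataset(pairs, gen, real, seed=0, lo=0.35, hi=0.5)
        d_ens = build_ensemble_dataset(d_cls, pairs, gen, real, seed=1)
        used = set(d_cls.manifest.loc[d_cls.manifest["partition"].isin(["train", "validation"]),
                                      "canonical_smiles"])
        assert not (set(d_ens.manifest["canonical_smiles"]) & used)

    def test_disjoint_input_passes_through(self, rng):
        real = _synthetic_set(30, 64, rng, REAL, "r")
        gen = _synthetic_set(30, 64, rng, GENERATED, "g")
        pairs = pair_by_max_similarity(gen, real)
        # empty window -> empty D_cls -> D_ens contains everything
        d_cls = datasets.build_classification_dataset(pairs, gen, real, seed=0, lo=2.0, hi=2.0)
        d_ens = build_ensemble_dataset(d_cls, pairs, gen, real, seed=1)
        assert len(d_ens) == 60

    def test_every_record_traces_to_one_source_molecule(self, rng):
        real = _synthetic_set(100, 64, rng, REAL, "r")
        gen = _synthetic_set(100, 64, rng, GENERATED, "g")
        pairs = pair_by_max_similarity(gen, real)
        d_cls = datasets.build_classification_dataset(pairs, gen, real, seed=0, lo=0.35, hi=0.5)
        d_ens = build_ensemble_dataset(d_cls, pairs, gen, real, seed=1)
        all_ids = set(real.ids) | set(gen.ids)
        for ds in (d_cls, d_ens):
            assert set(ds.manifest["id"]) <= all_ids
            assert not ds.manifest["id"].duplicated().any()
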