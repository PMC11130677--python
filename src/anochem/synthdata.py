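"""Synthetic study inputs: fixture molecules, structure mutation, fingerprint simulation.

Everything the framework needs to train and test without downloading any
corpus. Three generators:

* a packaged list of drug-like SMILES (``data/drug_like.smi``) standing in
  for "real" molecules, expanded at run time into a larger analog pool by
  conservative substituent decoration (mimicking the analog series that
  populate real screening libraries);
* a structure-mutation generator that corrupts real molecules with random
  graph edits (atom substitution, bond-order change, ring break, fragment
  swap), standing in for machine-generated structures — more edits push
  the fingerprint further from the parent;
* a fingerprint-population simulator whose "real" class activates chosen
  bit groups jointly while its "generated" class draws the same marginal
  frequencies independently — identical per-bit statistics, different
  joint structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from rdkit import Chem

from . import chem
from .chem import Molecule
from .datasets import GENERATED, REAL, LabeledSet, SimilarityPairing, pair_by_max_similarity

logger = logging.getLogger(__name__)

EDIT_OPS = ("atom_substitute", "bond_order_change", "ring_break", "fragment_swap")
_HETERO = (6, 7, 8, 16)  # C, N, O, S
#: Substituents used both for benign decoration (real analogs) and fragment swaps.
_SUBSTITUENTS = ("C", "O", "N", "F", "Cl", "OC", "C(F)(F)F", "N(C)C", "C=O", "CO", "C#N")


# ------------------------------------------------------------ fixture pool


def load_fixture_smiles() -> list[str]:
    """The packaged drug-like SMILES list (one per line, ``SMILES<TAB>name``)."""
    text = resources.files("anochem.data").joinpath("drug_like.smi").read_text()
    out = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split()[0])
    return out


def _attach(rdmol: Chem.Mol, rng: np.random.Generator) -> Chem.Mol | None:
    """Attach a random small substituent at a random atom with a free valence."""
    frag_smiles = _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
    frag = Chem.MolFromSmiles(frag_smiles)
    candidates = [a.GetIdx() for a in rdmol.GetAtoms() if a.GetTotalNumHs() > 0]
    if not candidates:
        return None
    site = int(candidates[rng.integers(len(candidates))])
    combined = Chem.RWMol(Chem.CombineMols(rdmol, frag))
    combined.AddBond(site, rdmol.GetNumAtoms(), Chem.BondType.SINGLE)
    return combined.GetMol()


def expand_real_pool(fixture: list[Molecule], n_target: int, seed: int) -> LabeledSet:
    """Grow the fixture into an analog pool of ``n_target`` unique molecules.

    Decoration attaches one or two common substituents to a random fixture
    parent — the kind of close analog a medicinal-chemistry series
    contains — keeping only structures that sanitize.
    """
    rng = np.random.default_rng(seed)
    mols: list[Molecule] = []
    seen: set[str] = set()
    for m in fixture:
        if m.valid and m.smiles_canonical not in seen:
            seen.add(m.smiles_canonical)
            mols.append(m)
    attempts = 0
    max_attempts = 60 * n_target
    while len(mols) < n_target and attempts < max_attempts:
        attempts += 1
        parent = mols[rng.integers(len(mols) if len(mols) < len(fixture) else len(fixture))]
        rdmol = parent.rdmol
        for _ in range(int(rng.integers(1, 3))):
            nxt = _attach(rdmol, rng)
            if nxt is None:
                break
            try:
                Chem.SanitizeMol(nxt)
            except Exception:
                break
            rdmol = nxt
        smi = Chem.MolToSmiles(rdmol)
        if smi in seen:
            continue
        mol = chem.parse_and_canonicalize(smi)
        if mol.valid and mol.smiles_canonical not in seen:
            seen.add(mol.smiles_canonical)
            mols.append(mol)
    if len(mols) < n_target:
        logger.warning("analog expansion reached %d of %d requested", len(mols), n_target)
    return LabeledSet(molecules=mols[:n_target], label=REAL, source_tag="real")


# ------------------------------------------------------------- mutations


@dataclass(frozen=True)
class MutationSpec:
    """Number and kind of random graph edits applied per molecule."""

    n_edits: int = 4
    edit_ops: tuple[str, ...] = EDIT_OPS
    validity_retries: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_edits < 1:
            raise ValueError("n_edits must be >= 1")
        bad = set(self.edit_ops) - set(EDIT_OPS)
        if bad or not self.edit_ops:
            raise ValueError(f"unknown or empty edit_ops: {bad or self.edit_ops}")


def _edit_once(rdmol: Chem.Mol, op: str, rng: np.random.Generator) -> Chem.Mol | None:
    """One raw graph edit; returns an unsanitized candidate or None."""
    rw = Chem.RWMol(rdmol)
    if op == "atom_substitute":
        idxs = [a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() in _HETERO]
        if not idxs:
            return None
        atom = rw.GetAtomWithIdx(int(idxs[rng.integers(len(idxs))]))
        choices = [z for z in _HETERO if z != atom.GetAtomicNum()]
        atom.SetAtomicNum(int(choices[rng.integers(len(choices))]))
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(False)
    elif op == "bond_order_change":
        bonds = [b.GetIdx() for b in rw.GetBonds() if not b.GetIsAromatic()]
        if not bonds:
            return None
        bond = rw.GetBondWithIdx(int(bonds[rng.integers(len(bonds))]))
        bond.SetBondType(
            Chem.BondType.DOUBLE if bond.GetBondType() == Chem.BondType.SINGLE
            else Chem.BondType.SINGLE
        )
    elif op == "ring_break":
        ring_bonds = [b.GetIdx() for b in rw.GetBonds() if b.IsInRing()]
        if not ring_bonds:
            return None
        b = rw.GetBondWithIdx(int(ring_bonds[rng.integers(len(ring_bonds))]))
        rw.RemoveBond(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    elif op == "fragment_swap":
        if rng.random() < 0.5:
            term = [a.GetIdx() for a in rw.GetAtoms() if a.GetDegree() == 1]
            if term and rw.GetNumAtoms() > 3:
                rw.RemoveAtom(int(term[rng.integers(len(term))]))
            else:
                return None
        else:
            return _attach(rw.GetMol(), rng)
    else:  # pragma: no cover - guarded by MutationSpec
        raise ValueError(op)
    return rw.GetMol()


def mutate_molecule(
    mol: Molecule, n_edits: int, ops: tuple[str, ...], retries: int, rng: np.random.Generator
) -> Molecule | None:
    """Apply ``n_edits`` sequential valid edits; None if retries are exhausted."""
    current = mol.rdmol
    for _ in range(n_edits):
        done = False
        for _ in range(retries):
            op = ops[rng.integers(len(ops))]
            cand = _edit_once(current, op, rng)
            if cand is None:
                continue
            try:
                frags = Chem.GetMolFrags(cand, asMols=True, sanitizeFrags=True)
            except Exception:
                continue
            cand = max(frags, key=lambda m: m.GetNumAtoms())  # keep largest piece
            if cand.GetNumAtoms() < 3:
                continue
            current = cand
            done = True
            break
        if not done:
            return None
    out = chem.parse_and_canonicalize(Chem.MolToSmiles(current))
    if not out.valid or out.smiles_canonical == mol.smiles_canonical:
        return None
    return out


def mutate_structures(real: LabeledSet, spec: MutationSpec) -> tuple[LabeledSet, int]:
    """Mutated copies of the real set (label 0); returns (set, n_dropped)."""
    if len(real) == 0:
        raise ValueError("real set is empty")
    rng = np.random.default_rng(spec.seed)
    out: list[Molecule] = []
    seen: set[str] = set(real.canonical_smiles)
    dropped = 0
    for parent in real.molecules:
        child = mutate_molecule(parent, spec.n_edits, spec.edit_ops,
                                spec.validity_retries, rng)
        if child is None or child.smiles_canonical in seen:
            dropped += 1
            continue
        seen.add(child.smiles_canonical)
        out.append(child)
    if dropped:
        logger.info("mutation dropped %d of %d parents", dropped, len(real))
    return LabeledSet(molecules=out, label=GENERATED, source_tag="generated"), dropped


# --------------------------------------------------- fingerprint simulator


@dataclass(frozen=True)
class FingerprintSimSpec:
    """Two fingerprint populations with equal marginals, different joint structure.

    ``cooccur_groups`` lists (bits, q): in the real class each group copies
    a shared Bernoulli(marginal_p) latent with coupling probability q, so
    its bits co-occur far more often than independence predicts; the
    generated class always samples independently.
    """

    n_bits: int = 2048
    n_samples: int = 1000  # per class
    active_bits: tuple[int, ...] = tuple(range(64))
    marginal_p: float = 0.2
    cooccur_groups: tuple[tuple[tuple[int, ...], float], ...] = (((0, 1), 1.0),)
    seed: int = 0

    def __post_init__(self):
        if not self.active_bits:
            raise ValueError("no active bits: degenerate simulation")
        if not 0.0 < self.marginal_p < 1.0:
            raise ValueError("marginal_p must be in (0, 1)")
        active = set(self.active_bits)
        for bits, q in self.cooccur_groups:
            if not set(bits) <= active:
                raise ValueError(f"group {bits} not within active_bits")
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"coupling q must be in [0, 1], got {q}")


def simulate_fingerprints(spec: FingerprintSimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (X, labels): rows 0..n-1 real (label 1), rows n..2n-1 generated (label 0)."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.marginal_p
    grouped = {b for bits, _ in spec.cooccur_groups for b in bits}
    free = [b for b in spec.active_bits if b not in grouped]

    X = np.zeros((2 * n, spec.n_bits), dtype=np.uint8)
    labels = np.concatenate([np.ones(n, dtype=np.int8), np.zeros(n, dtype=np.int8)])
    if free:
        X[:, free] = rng.random((2 * n, len(free))) < p
    for bits, q in spec.cooccur_groups:
        bits = list(bits)
        # real class: with prob q all bits copy one shared draw
        shared = (rng.random((n, 1)) < p).astype(np.uint8)
        independent = (rng.random((n, len(bits))) < p).astype(np.uint8)
        couple = rng.random((n, 1)) < q
        X[:n, bits] = np.where(couple, shared, independent)
        # generated class: always independent, same marginal
        X[n:, bits] = rng.random((n, len(bits))) < p
    return X, labels


# ----------------------------------------------------------- full corpus


@dataclass
class BenchmarkCorpus:
    """A complete desk-scale study: real pool, generated pool, and pairings."""

    real: LabeledSet
    generated: LabeledSet
    pairings: list[SimilarityPairing] = field(repr=False)
    seed: int = 0
    window_yield: int = 0  # generated molecules inside [0.3, 0.6)


def benchmark_corpus(
    seed: int,
    n_real: int = 2000,
    n_generated: int = 2000,
    n_bits: int = chem.DEFAULT_N_BITS,
    radius: int = chem.DEFAULT_RADIUS,
    edit_choices: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8),
    min_window_yield: int = 200,
    window: tuple[float, float] = (0.3, 0.6),
) -> BenchmarkCorpus:
    """Build the synthetic study: analog pool, mutated pool, max-similarity pairings.

    Edit counts are drawn uniformly from ``edit_choices`` so that a
    substantial fraction of generated molecules lands in the moderate
    similarity window. If fewer than ``min_window_yield`` do, the edit
    mixture is widened to include single edits and the pool is topped up.
    """
    rng = np.random.default_rng(seed)
    fixture, _ = chem.parse_many(load_fixture_smiles())
    real = expand_real_pool([m for m in fixture if m.valid], n_real, seed=int(rng.integers(2**31 - 1)))
    real.compute_fingerprints(n_bits=n_bits, radius=radius)

    def _generate(parents: list[Molecule], choices, seen: set[str]) -> list[Molecule]:
        out = []
        for parent in parents:
            k = int(choices[rng.integers(len(choices))])
            child = mutate_molecule(parent, k, EDIT_OPS, retries=20, rng=rng)
            if child is not None and child.smiles_canonical not in seen:
                seen.add(child.smiles_canonical)
                out.append(child)
        return out

    seen = set(real.canonical_smiles)
    parents = [real.molecules[int(i)] for i in rng.integers(len(real), size=n_generated)]
    gen_mols = _generate(parents, edit_choices, seen)
    while len(gen_mols) < n_generated:
        need = n_generated - len(gen_mols)
        parents = [real.molecules[int(i)] for i in rng.integers(len(real), size=need)]
        more = _generate(parents, edit_choices, seen)
        if not more:
            break
        gen_mols.extend(more)
    generated = LabeledSet(molecules=gen_mols[:n_generated], label=GENERATED,
                           source_tag="generated")
    generated.compute_fingerprints(n_bits=n_bits, radius=radius)
    pairings = pair_by_max_similarity(generated, real)

    lo, hi = window
    window_yield = sum(lo <= p.s_t < hi for p in pairings)
    attempts = 0
    while window_yield < min_window_yield and attempts < 4:
        attempts += 1
        logger.warning(
            "moderate-window yield %d < %d; widening edit mixture to include single edits",
            window_yield, min_window_yield,
        )
        n_extra = max(50, 3 * (min_window_yield - window_yield))
        extra_parents = [real.molecules[int(i)] for i in rng.integers(len(real), size=n_extra)]
        extra = _generate(extra_parents, (1, 2, 3), seen)
        if not extra:
            break
        generated = LabeledSet(molecules=generated.molecules + extra, label=GENERATED,
                               source_tag="generated")
        generated.compute_fingerprints(n_bits=n_bits, radius=radius)
        pairings = pair_by_max_similarity(generated, real)
        window_yield = sum(lo <= p.s_t < hi for p in pairings)
    logger.info("benchmark corpus: %d real, %d generated, %d in window",
                len(real), len(generated), window_yield)
    return BenchmarkCorpus(real=real, generated=generated, pairings=pairings,
                           seed=seed, window_yield=window_yield)
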