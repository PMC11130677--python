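"""Molecule parsing, canonicalization, fingerprints and properties.

Everything downstream works on canonical structures: a SMILES string is
parsed and sanitized by RDKit, canonicalized, and encoded as a binary
ECFP4 (Morgan radius-2) fingerprint. Molecular properties are the four
drug-design staples: QED, molecular weight, logP and the fragment-based
synthetic accessibility score (SAscore, 1 = easy to 10 = hard).
"""

from __future__ import annotations

import logging
import os
import sys
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, QED, rdFingerprintGenerator

logger = logging.getLogger(__name__)

# RDKit reports every unparsable SMILES on stderr; batch filtering handles
# and counts those, so silence the C++-side chatter.
RDLogger.DisableLog("rdApp.error")

_SA_DIR = os.path.join(Chem.RDConfig.RDContribDir, "SA_Score")
if _SA_DIR not in sys.path:
    sys.path.append(_SA_DIR)
import sascorer  # noqa: E402  (RDKit contrib, fragment-contribution SAscore)

import rdkit  # noqa: E402

logger.info("SAscore: RDKit contrib fragment-contribution implementation, rdkit %s", rdkit.__version__)

DEFAULT_N_BITS = 2048
DEFAULT_RADIUS = 2


@dataclass(frozen=True)
class Molecule:
    """A parsed structure; ``valid`` is False when sanitization failed."""

    smiles_input: str
    smiles_canonical: str | None
    valid: bool
    rdmol: Chem.Mol | None = field(default=None, repr=False, compare=False)


@dataclass(frozen=True)
class Fingerprint:
    """Binary folded circular fingerprint."""

    bits: np.ndarray  # uint8 vector of length n_bits
    radius: int = DEFAULT_RADIUS

    @property
    def n_bits(self) -> int:
        return int(self.bits.shape[0])

    @property
    def n_on(self) -> int:
        return int(self.bits.sum())


@dataclass(frozen=True)
class MoleculeProperties:
    qed: float  # drug-likeness desirability, in [0, 1]
    mw: float  # molecular weight, g/mol
    logp: float  # Wildman-Crippen octanol/water partition estimate
    sascore: float  # synthetic accessibility, in [1, 10]


def parse_and_canonicalize(smiles: str) -> Molecule:
    """Parse one SMILES; invalid structures yield ``valid=False``, not an error.

    Raises
    ------
    ValueError
        If ``smiles`` is empty or whitespace only.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)  # sanitizes; None on failure
    if mol is None:
        return Molecule(smiles_input=smiles, smiles_canonical=None, valid=False)
    return Molecule(
        smiles_input=smiles,
        smiles_canonical=Chem.MolToSmiles(mol),
        valid=True,
        rdmol=mol,
    )


def parse_many(smiles_list: Iterable[str]) -> tuple[list[Molecule], int]:
    """Parse a batch; returns (all molecules, number invalid) and warns once."""
    mols = [parse_and_canonicalize(s) for s in smiles_list]
    n_invalid = sum(not m.valid for m in mols)
    if n_invalid:
        logger.warning("%d of %d SMILES failed to parse/sanitize", n_invalid, len(mols))
    return mols, n_invalid


def _require_valid(mol: Molecule) -> Chem.Mol:
    if not mol.valid or mol.rdmol is None:
        raise ValueError(f"invalid molecule: {mol.smiles_input!r}")
    return mol.rdmol


def ecfp4(mol: Molecule, n_bits: int = DEFAULT_N_BITS, radius: int = DEFAULT_RADIUS) -> Fingerprint:
    """Binary Morgan fingerprint of the canonical structure (ECFP4 at radius 2)."""
    if n_bits < 1024:
        raise ValueError(f"n_bits must be >= 1024, got {n_bits}")
    rdmol = _require_valid(mol)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bits = np.asarray(gen.GetFingerprintAsNumPy(rdmol), dtype=np.uint8)
    return Fingerprint(bits=bits, radius=radius)


def fingerprint_matrix(
    mols: Sequence[Molecule], n_bits: int = DEFAULT_N_BITS, radius: int = DEFAULT_RADIUS
) -> np.ndarray:
    """Stack fingerprints of valid molecules into an (n, n_bits) uint8 matrix."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out = np.zeros((len(mols), n_bits), dtype=np.uint8)
    for i, m in enumerate(mols):
        out[i] = gen.GetFingerprintAsNumPy(_require_valid(m))
    return out


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two equal-length fingerprints."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    inter = int(np.sum(a.bits & b.bits))
    union = int(np.sum(a.bits | b.bits))
    if union == 0:
        logger.warning("Tanimoto of two all-zero fingerprints; defined as 0.0")
        return 0.0
    return inter / union


def tanimoto_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """All-pairs Tanimoto between the rows of two binary matrices.

    Rows with no set bits get similarity 0 to everything.
    """
    if A.shape[1] != B.shape[1]:
        raise ValueError("fingerprint length mismatch")
    Af = A.astype(np.float32)
    Bf = B.astype(np.float32)
    # 0/1 products with partial sums < 2^24 accumulate exactly in float32
    inter = (Af @ Bf.T).astype(np.float64)
    union = Af.sum(axis=1, dtype=np.float64)[:, None] + Bf.sum(axis=1, dtype=np.float64)[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(union > 0, inter / union, 0.0)


def properties(mol: Molecule) -> MoleculeProperties:
    """QED, MW, logP and SAscore of a valid molecule (pure in the canonical SMILES)."""
    rdmol = _require_valid(mol)
    return MoleculeProperties(
        qed=float(QED.qed(rdmol)),
        mw=float(Descriptors.MolWt(rdmol)),
        logp=float(Crippen.MolLogP(rdmol)),
        sascore=float(sascorer.calculateScore(rdmol)),
    )


# ---------------------------------------------------------------------- I/O


def read_smiles(path: str) -> pd.DataFrame:
    """Read SMILES from .smi/.txt (one per line, optional ID column), CSV, or SDF.

    Returns a DataFrame with columns ``id``, ``smiles`` (+ ``label`` if present).
    """
    lower = path.lower()
    if lower.endswith(".csv"):
        df = pd.read_csv(path)
        if "smiles" not in df.columns:
            raise ValueError(f"{path}: CSV must have a 'smiles' column")
        out = pd.DataFrame({"smiles": df["smiles"].astype(str)})
        out["id"] = df["id"].astype(str) if "id" in df.columns else [str(i) for i in range(len(df))]
        if "label" in df.columns:
            out["label"] = df["label"]
        return out[["id", "smiles"] + (["label"] if "label" in out.columns else [])]
    if lower.endswith(".sdf"):
        rows = []
        for i, rdmol in enumerate(Chem.SDMolSupplier(path, sanitize=True)):
            if rdmol is None:
                continue
            name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") and rdmol.GetProp("_Name") else str(i)
            rows.append({"id": name, "smiles": Chem.MolToSmiles(rdmol)})
        return pd.DataFrame(rows, columns=["id", "smiles"])
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            rows.append({"id": parts[1].strip() if len(parts) > 1 else str(i), "smiles": parts[0]})
    return pd.DataFrame(rows, columns=["id", "smiles"])


def write_properties_csv(mols: Sequence[Molecule], path: str) -> pd.DataFrame:
    """Write canonical SMILES + properties for the valid molecules; returns the table."""
    rows = []
    for i, m in enumerate(mols):
        if not m.valid:
            continue
        p = properties(m)
        rows.append(
            {
                "id": str(i),
                "canonical_smiles": m.smiles_canonical,
                "qed": p.qed,
                "mw": p.mw,
                "logp": p.logp,
                "sascore": p.sascore,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def write_fingerprints_csv(fps: np.ndarray, path: str, radius: int = DEFAULT_RADIUS) -> None:
    """Dense 0/1 CSV with a JSON-style header comment recording n_bits and radius."""
    with open(path, "w") as fh:
        fh.write('# {"n_bits": %d, "radius": %d}\n' % (fps.shape[1], radius))
        np.savetxt(fh, fps, fmt="%d", delimiter=",")
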