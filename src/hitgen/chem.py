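"""SMILES handling, molecular descriptors, fingerprints and file I/O.

All parsing, canonicalization and descriptor computation is delegated to
RDKit.  A :class:`MoleculeRecord` bundles the raw string, canonical
isomeric SMILES, a validity flag and (for valid molecules) molecular
weight, logP and the synthetic accessibility score (SAS, 1 = easy to
10 = practically impossible).
"""

from __future__ import annotations

import importlib.util
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Crippen, DataStructs, Descriptors, RDConfig

RDLogger.DisableLog("rdApp.*")

# RDKit ships the fragment-contribution synthetic-accessibility scorer in its
# contrib tree rather than as an importable module.
_sa_path = os.path.join(RDConfig.RDContribDir, "SA_Score", "sascorer.py")
_spec = importlib.util.spec_from_file_location("sascorer", _sa_path)
_sascorer = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_sascorer)


class DescriptorError(ValueError):
    """Raised when descriptors are requested for an invalid molecule."""


@dataclass
class FingerprintVector:
    """Hashed circular (Morgan/ECFP) fingerprint as a binary vector."""

    bits: np.ndarray
    radius: int
    nbits: int

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.size != self.nbits:
            raise ValueError("bit vector length does not match nbits")


@dataclass
class MoleculeRecord:
    smiles_raw: str
    smiles_canonical: str | None = None
    valid: bool = False
    mw: float | None = None
    logp: float | None = None
    sas: float | None = None
    fingerprint: FingerprintVector | None = field(default=None, repr=False)

    def mol(self) -> Chem.Mol:
        if not self.valid:
            raise DescriptorError(f"invalid molecule: {self.smiles_raw!r}")
        return Chem.MolFromSmiles(self.smiles_canonical)


def canonicalize(smiles: str, isomeric: bool = True) -> MoleculeRecord:
    """Parse a SMILES and return a record with its canonical isomeric form.

    An unparseable string yields ``valid=False`` with the raw string kept;
    canonicalization is idempotent on its own output.
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return MoleculeRecord(smiles_raw=smiles, valid=False)
    can = Chem.MolToSmiles(mol, isomericSmiles=isomeric)
    return MoleculeRecord(smiles_raw=smiles, smiles_canonical=can, valid=True)


def compute_descriptors(record: MoleculeRecord) -> MoleculeRecord:
    """Fill in molecular weight (g/mol), Crippen logP and SAS in place."""
    mol = record.mol()
    record.mw = Descriptors.MolWt(mol)
    record.logp = Crippen.MolLogP(mol)
    record.sas = float(np.clip(_sascorer.calculateScore(mol), 1.0, 10.0))
    return record


def sas_score(smiles: str) -> float:
    """Synthetic accessibility score of a single SMILES (1 easy .. 10 hard)."""
    rec = canonicalize(smiles)
    if not rec.valid:
        raise DescriptorError(f"invalid molecule: {smiles!r}")
    return float(np.clip(_sascorer.calculateScore(rec.mol()), 1.0, 10.0))


def filter_training_set(
    records: list[MoleculeRecord],
    mw_range: tuple[float, float] = (200.0, 600.0),
    logp_range: tuple[float, float] = (-2.0, 6.0),
) -> list[MoleculeRecord]:
    """Drug-likeness corpus filter: valid, MW and logP inside closed bands."""
    kept = []
    for rec in records:
        if not rec.valid:
            continue
        if rec.mw is None or rec.logp is None:
            compute_descriptors(rec)
        if mw_range[0] <= rec.mw <= mw_range[1] and logp_range[0] <= rec.logp <= logp_range[1]:
            kept.append(rec)
    return kept


def ecfp(record: MoleculeRecord, radius: int = 2, nbits: int = 2048) -> FingerprintVector:
    """Extended-connectivity fingerprint; radius 2 = ECFP4, 3 = ECFP6."""
    mol = record.mol()
    bv = AllChem.GetMorganFingerprintAsBitVect(mol, radius, nBits=nbits)
    arr = np.zeros(nbits, dtype=np.uint8)
    DataStructs.ConvertToNumpyArray(bv, arr)
    return FingerprintVector(bits=arr, radius=radius, nbits=nbits)


def tanimoto(a: FingerprintVector, b: FingerprintVector) -> float:
    """Jaccard similarity of two equal-length bit vectors."""
    if a.nbits != b.nbits:
        raise ValueError("fingerprint lengths differ")
    aa = a.bits.astype(bool)
    bb = b.bits.astype(bool)
    union = np.logical_or(aa, bb).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(aa, bb).sum() / union)


# ---------------------------------------------------------------------- I/O
def read_smiles_file(path: str) -> list[MoleculeRecord]:
    """Read a .smi file (one SMILES per line, optional name column)."""
    records = []
    with open(path, newline=None) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            records.append(canonicalize(line.split()[0]))
    return records


def write_smiles_file(records: list[MoleculeRecord], path: str) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write((rec.smiles_canonical or rec.smiles_raw) + "\n")


def records_to_frame(records: list[MoleculeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "smiles": [r.smiles_canonical or r.smiles_raw for r in records],
            "valid": [r.valid for r in records],
            "mw": [r.mw for r in records],
            "logp": [r.logp for r in records],
            "sas": [r.sas for r in records],
        }
    )


def write_table(records: list[MoleculeRecord], path: str) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_affinity_csv(path: str) -> pd.DataFrame:
    """Read a labelled affinity table with columns ``smiles,pic50``."""
    df = pd.read_csv(path)
    missing = {"smiles", "pic50"} - set(df.columns)
    if missing:
        raise ValueError(f"affinity CSV missing columns: {sorted(missing)}")
    return df
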