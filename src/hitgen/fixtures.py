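"""Self-contained synthetic corpora and affinity tables.

Molecules are built by combinatorial decoration of drug-like scaffold
templates (aryl amides, anilides, sulfonamides, ureas) with substituent
fragments, so every emitted SMILES parses, canonicalizes and sits inside
the MW 200-600 / logP -2..6 drug-likeness bands used to filter the
training corpus.  A share of the fragments carries an unassigned
stereocenter so stereochemistry-aware code paths are exercised.

The affinity oracle assigns a pseudo-pIC50 that is linear in simple
substructure counts (nitrogen atoms, aromatic rings, halogens, amide
groups) plus Gaussian noise.  Because the signal is known in closed
form, recovery by the regressor — and the location of attention mass —
has a ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .chem import canonicalize

# Scaffold cores with three substitution slots.  Fragments open/close their
# own ring digit (2), the core uses 1, so digits never collide.
_TEMPLATES: tuple[str, ...] = (
    "O=C(NC{L}{R1})c1ccc({R2})cc1",          # benzamide
    "{R2}c1ccc(NC(=O)C{L}{R1})cc1",          # anilide
    "{R2}c1ccc(S(=O)(=O)NC{L}{R1})cc1",      # aryl sulfonamide
    "O=C(NC{L}{R1})Nc1ccc({R2})cc1",         # aryl urea
    "{R2}c1ccc(OCC(=O)NC{L}{R1})cc1",        # aryloxy-acetamide
)

# N-side substituent chains; several carry an unassigned stereocenter.
_R1: tuple[str, ...] = (
    "Cc2ccccc2",
    "CCc2ccccc2",
    "Cc2ccc(F)cc2",
    "Cc2ccco2",
    "Cc2cccs2",
    "CCN(C)Cc2ccccc2",
    "C(O)c2ccccc2",          # benzylic alcohol -> stereocenter at the carbinol C
    "C(O)c2ccc(Cl)cc2",
    "C(C)c2ccccc2",          # alpha-methylbenzyl -> stereocenter
    "C(C)c2ccc(OC)cc2",
    "CN2CCN(C)CC2",
    "CC2CCCCC2",             # 2-methylcyclohexyl region
)

# Aryl substituents on the core ring.
_R2: tuple[str, ...] = (
    "F", "Cl", "Br", "I", "C", "OC", "N(C)C", "C(F)(F)F", "CC", "OCC",
    "C#N", "OC(C)C",
)

# Optional chain inserts between the amide and R1.
_L: tuple[str, ...] = ("", "C", "(C)", "C(C)", "CC")


@dataclass
class FixtureSpec:
    """Deterministic recipe for a synthetic corpus or affinity table."""

    n: int = 2000
    seed: int = 0
    noise_sd: float = 0.3
    coefficients: tuple[float, float, float, float] = (0.5, 0.4, 0.3, 0.6)
    mw_range: tuple[float, float] = (200.0, 600.0)
    logp_range: tuple[float, float] = (-2.0, 6.0)
    templates: tuple[str, ...] = field(default=_TEMPLATES)


def _enumerate_library(spec: FixtureSpec) -> list[str]:
    """All decorated scaffolds passing validity and drug-likeness bands."""
    out: list[str] = []
    seen: set[str] = set()
    for tpl, r1, r2, link in product(spec.templates, _R1, _R2, _L):
        smi = tpl.format(R1=r1, R2=r2, L=link)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        mw = Descriptors.MolWt(mol)
        logp = Crippen.MolLogP(mol)
        if not (spec.mw_range[0] <= mw <= spec.mw_range[1]):
            continue
        if not (spec.logp_range[0] <= logp <= spec.logp_range[1]):
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        seen.add(can)
        out.append(can)
    return out


def make_corpus(spec: FixtureSpec) -> list[str]:
    """Sample ``spec.n`` distinct canonical SMILES from the scaffold library."""
    if spec.n < 1:
        raise ValueError("n must be >= 1")
    library = _enumerate_library(spec)
    if spec.n > len(library):
        raise ValueError(
            f"requested {spec.n} molecules but the scaffold library holds "
            f"{len(library)}; reduce n or extend the template/fragment sets"
        )
    rng = np.random.default_rng(spec.seed)
    idx = rng.permutation(len(library))[: spec.n]
    return [library[i] for i in idx]


_AMIDE = Chem.MolFromSmarts("C(=O)N")
_HALOGENS = {9, 17, 35, 53}


def substructure_counts(smiles: str) -> tuple[int, int, int, int]:
    """(nitrogen atoms, aromatic rings, halogen atoms, amide groups)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    n_nitrogen = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 7)
    n_aromatic = rdMolDescriptors.CalcNumAromaticRings(mol)
    n_halogen = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() in _HALOGENS)
    n_amide = len(mol.GetSubstructMatches(_AMIDE))
    return n_nitrogen, n_aromatic, n_halogen, n_amide


def affinity_oracle(
    smiles: str,
    coefficients: tuple[float, float, float, float] = (0.5, 0.4, 0.3, 0.6),
    noise_sd: float = 0.0,
    seed: int = 0,
    intercept: float = 0.0,
) -> float:
    """Pseudo-pIC50: linear substructure score plus Gaussian noise."""
    a, b, c, d = coefficients
    n_n, n_ar, n_hal, n_am = substructure_counts(smiles)
    value = intercept + a * n_n + b * n_ar - c * n_hal + d * n_am
    if noise_sd > 0:
        value += np.random.default_rng(seed).normal(0.0, noise_sd)
    return float(value)


def make_affinity_table(spec: FixtureSpec | None = None) -> pd.DataFrame:
    """Synthetic (smiles, pic50) table; labels affinely mapped to span [4, 10].

    The deterministic substructure score is rescaled to the pIC50 range
    first, then per-molecule Gaussian noise of ``spec.noise_sd`` (pIC50
    units) is added, truncated to stay inside [4, 10].
    """
    spec = spec or FixtureSpec(n=1453)
    smiles = make_corpus(spec)
    det = np.array([affinity_oracle(s, spec.coefficients) for s in smiles])
    lo, hi = det.min(), det.max()
    if hi - lo < 1e-12:
        raise ValueError("degenerate affinity signal: all scores identical")
    labels = 4.0 + 6.0 * (det - lo) / (hi - lo)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 1)
        labels = labels + rng.normal(0.0, spec.noise_sd, size=len(labels))
        labels = np.clip(labels, 4.0, 10.0)
    df = pd.DataFrame({"smiles": smiles, "pic50": labels})
    assert df["smiles"].is_unique
    return df


def stereo_fraction(smiles_list: list[str]) -> float:
    """Share of molecules with at least one unassigned stereocenter."""
    n_with = 0
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s)
        centers = Chem.FindMolChiralCenters(
            mol, includeUnassigned=True, useLegacyImplementation=False
        )
        if any(code == "?" for _, code in centers):
            n_with += 1
    return n_with / max(1, len(smiles_list))


def validate_corpus(smiles_list: list[str], spec: FixtureSpec | None = None) -> bool:
    """True iff every molecule parses and passes the drug-likeness bands."""
    spec = spec or FixtureSpec()
    for s in smiles_list:
        rec = canonicalize(s)
        if not rec.valid:
            return False
        mol = rec.mol()
        mw = Descriptors.MolWt(mol)
        logp = Crippen.MolLogP(mol)
        if not (spec.mw_range[0] <= mw <= spec.mw_range[1]):
            return False
        if not (spec.logp_range[0] <= logp <= spec.logp_range[1]):
            return False
    return True
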