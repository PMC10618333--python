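"""Hit selection: Pareto front, stereoisomer enumeration and ranking,
similarity to reference actives, and attention-based atom importance.

Objectives follow the optimization convention throughout: pIC50 is
maximized, synthetic accessibility (SAS) minimized.  Domination is weak
with at least one strict inequality; solutions tied on both axes are
all retained in the front.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFMCS
from rdkit.Chem.EnumerateStereoisomers import (
    EnumerateStereoisomers,
    StereoEnumerationOptions,
)

from .chem import canonicalize, ecfp, tanimoto
from .predictor import Pic50Predictor


@dataclass
class Solution:
    smiles: str
    pic50: float
    sas: float

    def __post_init__(self):
        if not (np.isfinite(self.pic50) and np.isfinite(self.sas)):
            raise ValueError("solution objectives must be finite")


def _dominates(a: Solution, b: Solution) -> bool:
    """a dominates b: >= on pIC50, <= on SAS, strict on at least one."""
    return (a.pic50 >= b.pic50 and a.sas <= b.sas
            and (a.pic50 > b.pic50 or a.sas < b.sas))


def pareto_front(solutions: list[Solution]) -> tuple[list[Solution], list[Solution]]:
    """Partition into (non_dominated, dominated) by a sort-and-sweep.

    Sorted by decreasing pIC50 (ties by increasing SAS), a solution is
    dominated iff some earlier solution has strictly smaller SAS, or
    equal SAS with strictly larger pIC50.
    """
    if not solutions:
        raise ValueError("empty solution set")
    order = sorted(range(len(solutions)),
                   key=lambda i: (-solutions[i].pic50, solutions[i].sas))
    non_dom_flags = [False] * len(solutions)
    best_sas = np.inf
    best_sas_pic50 = -np.inf
    for i in order:
        s = solutions[i]
        if s.sas < best_sas:
            non_dom_flags[i] = True
            best_sas = s.sas
            best_sas_pic50 = s.pic50
        elif s.sas == best_sas and s.pic50 == best_sas_pic50:
            non_dom_flags[i] = True  # exact tie on both axes: keep both
    front = [s for s, f in zip(solutions, non_dom_flags) if f]
    dominated = [s for s, f in zip(solutions, non_dom_flags) if not f]
    return front, dominated


def pareto_front_bruteforce(solutions: list[Solution]
                            ) -> tuple[list[Solution], list[Solution]]:
    """O(n^2) pairwise-domination reference partition."""
    if not solutions:
        raise ValueError("empty solution set")
    front, dominated = [], []
    for s in solutions:
        if any(_dominates(o, s) for o in solutions):
            dominated.append(s)
        else:
            front.append(s)
    return front, dominated


# ------------------------------------------------------------- stereoisomers
@dataclass
class StereoisomerSet:
    parent: str
    c: int
    isomers: list[str]
    pic50: list[float] = field(default_factory=list)
    sas: list[float] = field(default_factory=list)
    best: int | None = None


def count_unassigned_stereocenters(smiles: str) -> int:
    """Unassigned tetrahedral centers plus unassigned double-bond geometry."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    info = Chem.FindPotentialStereo(mol)
    return sum(1 for e in info
               if str(e.specified) == "Unspecified")


def enumerate_stereoisomers(smiles: str, max_isomers: int = 512) -> StereoisomerSet:
    """Assign all unassigned stereocenters; at most 2^c distinct isomers."""
    rec = canonicalize(smiles)
    if not rec.valid:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    mol = rec.mol()
    c = count_unassigned_stereocenters(rec.smiles_canonical)
    opts = StereoEnumerationOptions(onlyUnassigned=True, unique=True,
                                    maxIsomers=max_isomers)
    isomers = sorted({Chem.MolToSmiles(m, isomericSmiles=True)
                      for m in EnumerateStereoisomers(mol, options=opts)})
    if not isomers:
        isomers = [rec.smiles_canonical]
    return StereoisomerSet(parent=rec.smiles_canonical, c=c, isomers=isomers)


def rank_stereoisomers(stereo_set: StereoisomerSet,
                       predictor: Pic50Predictor) -> StereoisomerSet:
    """Score each isomer by predicted pIC50; best = argmax.

    SAS is reported alongside so the affinity/synthesizability trade-off
    stays visible; the ranking itself is by predicted affinity only.
    """
    from .chem import sas_score

    preds, flags = predictor.predict(stereo_set.isomers)
    if not np.all(flags):
        raise ValueError("unparseable stereoisomer in set")
    order = np.argsort(-preds, kind="stable")
    stereo_set.isomers = [stereo_set.isomers[i] for i in order]
    stereo_set.pic50 = [float(preds[i]) for i in order]
    stereo_set.sas = [sas_score(s) for s in stereo_set.isomers]
    stereo_set.best = 0
    return stereo_set


# ------------------------------------------------------------- similarity
@dataclass
class SimilarityReport:
    t_s: float
    t_mcs: float | None
    mcs_timed_out: bool = False


def similarity_report(smiles_a: str, smiles_b: str, radius: int = 2,
                      nbits: int = 2048, mcs_timeout: int = 10) -> SimilarityReport:
    """Fingerprint Tanimoto plus maximum-common-substructure Tanimoto.

    t_mcs = |MCS atoms| / (|atoms A| + |atoms B| - |MCS atoms|), matching
    atoms by element and bonds by order (aromatic compatible with single).
    """
    ra, rb = canonicalize(smiles_a), canonicalize(smiles_b)
    if not (ra.valid and rb.valid):
        raise ValueError("both molecules must be valid")
    t_s = tanimoto(ecfp(ra, radius, nbits), ecfp(rb, radius, nbits))
    ma, mb = ra.mol(), rb.mol()
    res = rdFMCS.FindMCS(
        [ma, mb],
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrder,
        timeout=mcs_timeout,
    )
    if res.canceled:
        return SimilarityReport(t_s=t_s, t_mcs=None, mcs_timed_out=True)
    n_mcs = res.numAtoms
    na, nb = ma.GetNumAtoms(), mb.GetNumAtoms()
    t_mcs = n_mcs / (na + nb - n_mcs)
    return SimilarityReport(t_s=t_s, t_mcs=float(t_mcs))


# ------------------------------------------------------------- attention map
#: tokens that correspond to one heavy atom in the molecular graph
def _is_atom_token(token: str) -> bool:
    if token.startswith("["):
        return True
    return token in ("B", "C", "N", "O", "P", "S", "F", "I", "Cl", "Br",
                     "b", "c", "n", "o", "p", "s")


def attention_atom_map(predictor: Pic50Predictor, smiles: str,
                       top_k: int = 3) -> dict:
    """Project token-level attention onto atoms.

    Atom tokens keep their weight; each non-atom token's mass is split
    equally between the nearest preceding and following atom tokens
    (boundary tokens assign to their single neighbor).  Returned atom
    weights sum to 1; atom indices follow the order of appearance in the
    canonical SMILES, which matches RDKit's atom numbering for a
    freshly parsed molecule.
    """
    ctx = predictor.attention_weights(smiles)
    tokens, alphas = ctx.tokens, np.asarray(ctx.alphas, dtype=float)
    atom_positions = [i for i, t in enumerate(tokens) if _is_atom_token(t)]
    if not atom_positions:
        raise ValueError("no atom tokens in SMILES")
    atom_w = {i: 0.0 for i in atom_positions}
    for i, (tok, a) in enumerate(zip(tokens, alphas)):
        if i in atom_w:
            atom_w[i] += a
            continue
        prev_atoms = [p for p in atom_positions if p < i]
        next_atoms = [p for p in atom_positions if p > i]
        if prev_atoms and next_atoms:
            atom_w[prev_atoms[-1]] += a / 2
            atom_w[next_atoms[0]] += a / 2
        elif prev_atoms:
            atom_w[prev_atoms[-1]] += a
        else:
            atom_w[next_atoms[0]] += a
    weights = np.array([atom_w[i] for i in atom_positions])
    total = weights.sum()
    if total > 0:
        weights = weights / total
    atom_tokens = [tokens[i] for i in atom_positions]
    order = np.argsort(-weights)
    return {
        "smiles": smiles,
        "atom_tokens": atom_tokens,
        "atom_weights": weights.tolist(),
        "top_atoms": [{"atom_index": int(i), "token": atom_tokens[i],
                       "weight": float(weights[i])} for i in order[:top_k]],
    }


def solutions_from_frame(df: pd.DataFrame) -> list[Solution]:
    return [Solution(smiles=r.smiles, pic50=float(r.pic50), sas=float(r.sas))
            for r in df.itertuples()]


def front_to_frame(front: list[Solution]) -> pd.DataFrame:
    return pd.DataFrame({"smiles": [s.smiles for s in front],
                         "pic50": [s.pic50 for s in front],
                         "sas": [s.sas for s in front]})
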