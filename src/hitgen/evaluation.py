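"""Distribution-learning metrics for generated molecule sets.

Validity, uniqueness and novelty are computed on canonical SMILES.
Diversity is Tanimoto-based: internal diversity is one minus the mean
pairwise fingerprint similarity inside the sample; external diversity
is one minus the mean nearest-neighbor similarity to a reference set.
The KLD score compares physicochemical descriptor distributions of a
sample against a reference via per-descriptor Kullback-Leibler
divergence aggregated as mean(exp(-KL)); 1 means matching
distributions.  The Frechet ChemNet Distance requires an externally
trained reference network and is reported as null.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, GraphDescriptors, Lipinski, rdMolDescriptors

from .chem import canonicalize, ecfp, tanimoto
from .fixtures import FixtureSpec  # noqa: F401  (re-exported convenience)
from .predictor import Pic50Predictor


def validity(sample: list[str]) -> float:
    """Fraction of strings that parse and canonicalize."""
    if not sample:
        raise ValueError("empty sample")
    return float(np.mean([canonicalize(s).valid if s else False for s in sample]))


def _canonical_valid(sample: list[str]) -> list[str]:
    out = []
    for s in sample:
        if not s:
            continue
        rec = canonicalize(s)
        if rec.valid:
            out.append(rec.smiles_canonical)
    return out


def uniqueness_novelty(sample: list[str], corpus: list[str]
                       ) -> tuple[float, float]:
    """uniqueness = distinct/valid; novelty = distinct-not-in-corpus/distinct."""
    valid = _canonical_valid(sample)
    if not valid:
        raise ValueError("no valid molecules in sample")
    distinct = set(valid)
    corpus_set = {canonicalize(s).smiles_canonical for s in corpus
                  if canonicalize(s).valid}
    uniq = len(distinct) / len(valid)
    novel = len(distinct - corpus_set) / len(distinct)
    return float(uniq), float(novel)


def _fingerprints(smiles: list[str], radius: int, nbits: int) -> np.ndarray:
    return np.stack([ecfp(canonicalize(s), radius, nbits).bits
                     for s in smiles]).astype(bool)


def _pairwise_tanimoto(fps_a: np.ndarray, fps_b: np.ndarray) -> np.ndarray:
    """Dense Tanimoto matrix between two stacks of boolean fingerprints."""
    inter = fps_a.astype(np.int32) @ fps_b.T.astype(np.int32)
    pop_a = fps_a.sum(axis=1, keepdims=True)
    pop_b = fps_b.sum(axis=1, keepdims=True)
    union = pop_a + pop_b.T - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return sim


def internal_diversity(sample: list[str], radius: int = 2,
                       nbits: int = 2048) -> float:
    """1 - mean pairwise Tanimoto similarity within the sample."""
    valid = _canonical_valid(sample)
    if len(valid) < 2:
        raise ValueError("need at least 2 valid molecules")
    fps = _fingerprints(valid, radius, nbits)
    sim = _pairwise_tanimoto(fps, fps)
    n = len(valid)
    off_diag = (sim.sum() - np.trace(sim)) / (n * (n - 1))
    return float(1.0 - off_diag)


def external_diversity(sample: list[str], reference: list[str],
                       radius: int = 2, nbits: int = 2048) -> float:
    """1 - mean nearest-reference-neighbor Tanimoto of each sample molecule."""
    valid = _canonical_valid(sample)
    ref = _canonical_valid(reference)
    if len(valid) < 1 or len(ref) < 1:
        raise ValueError("need non-empty valid sample and reference")
    sim = _pairwise_tanimoto(_fingerprints(valid, radius, nbits),
                             _fingerprints(ref, radius, nbits))
    return float(1.0 - sim.max(axis=1).mean())


def diversity(sample: list[str], reference: list[str] | None = None,
              radius: int = 2, nbits: int = 2048) -> float:
    if reference is None:
        return internal_diversity(sample, radius, nbits)
    return external_diversity(sample, reference, radius, nbits)


# ------------------------------------------------------------------- KLD
_CONTINUOUS = {
    "mw": Descriptors.MolWt,
    "logp": Crippen.MolLogP,
    "bertz": GraphDescriptors.BertzCT,
    "fraction_csp3": Lipinski.FractionCSP3,
}
_DISCRETE = {
    "ring_count": rdMolDescriptors.CalcNumRings,
    "aromatic_rings": rdMolDescriptors.CalcNumAromaticRings,
    "heavy_atoms": lambda m: m.GetNumHeavyAtoms(),
    "hbd": rdMolDescriptors.CalcNumHBD,
}


def _descriptor_values(smiles: list[str], fn) -> np.ndarray:
    return np.array([fn(Chem.MolFromSmiles(s)) for s in smiles], dtype=float)


def _kl_continuous(sample: np.ndarray, reference: np.ndarray,
                   bins: int = 50, eps: float = 1e-10) -> float:
    lo, hi = np.percentile(reference, [0.1, 99.9])
    if hi <= lo:
        raise ValueError("degenerate reference distribution")
    edges = np.linspace(lo, hi, bins + 1)
    p, _ = np.histogram(np.clip(sample, lo, hi), bins=edges)
    q, _ = np.histogram(np.clip(reference, lo, hi), bins=edges)
    p = p / p.sum() + eps
    q = q / q.sum() + eps
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


def _kl_discrete(sample: np.ndarray, reference: np.ndarray,
                 eps: float = 1e-10) -> float:
    cats = np.union1d(sample, reference)
    p = np.array([(sample == c).mean() for c in cats]) + eps
    q = np.array([(reference == c).mean() for c in cats]) + eps
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


def kld_score(sample: list[str], reference: list[str],
              aggregate: str = "exp") -> float:
    """Descriptor-distribution match score in [0, 1].

    KL divergence is directed sample -> reference per descriptor;
    ``aggregate='exp'`` returns mean(exp(-KL)) (1 = identical),
    ``'mean'`` returns the raw mean KL.  Descriptors degenerate in the
    reference are skipped.
    """
    s_valid = _canonical_valid(sample)
    r_valid = _canonical_valid(reference)
    if len(s_valid) < 100 or len(r_valid) < 100:
        raise ValueError("need at least 100 valid molecules in each set")
    kls = []
    for name, fn in _CONTINUOUS.items():
        try:
            kls.append(_kl_continuous(_descriptor_values(s_valid, fn),
                                      _descriptor_values(r_valid, fn)))
        except ValueError:
            continue
    for name, fn in _DISCRETE.items():
        ref_vals = _descriptor_values(r_valid, fn)
        if np.unique(ref_vals).size < 2:
            continue
        kls.append(_kl_discrete(_descriptor_values(s_valid, fn), ref_vals))
    if not kls:
        raise ValueError("all descriptors degenerate")
    if aggregate == "exp":
        return float(np.mean(np.exp(-np.asarray(kls))))
    if aggregate == "mean":
        return float(np.mean(kls))
    raise ValueError(f"unknown aggregate {aggregate!r}")


# ---------------------------------------------------------------- reports
@dataclass
class GenerationReport:
    n: int
    validity: float
    uniqueness: float
    novelty: float
    internal_diversity: float
    external_diversity: float | None
    kld_score: float | None
    fcd: None  # requires an externally trained reference network
    pic50_mean: float | None = None
    pic50_sd: float | None = None
    sas_mean: float | None = None
    sas_sd: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def generation_report(sample: list[str], corpus: list[str],
                      predictor: Pic50Predictor | None = None,
                      kld_reference: list[str] | None = None) -> GenerationReport:
    """Full distribution-learning report for a generated sample."""
    from .chem import sas_score

    val = validity(sample)
    uniq, novel = uniqueness_novelty(sample, corpus)
    int_div = internal_diversity(sample)
    ext_div = external_diversity(sample, corpus) if corpus else None
    kld = None
    ref = kld_reference if kld_reference is not None else corpus
    try:
        kld = kld_score(sample, ref)
    except ValueError:
        pass
    rep = GenerationReport(n=len(sample), validity=val, uniqueness=uniq,
                           novelty=novel, internal_diversity=int_div,
                           external_diversity=ext_div, kld_score=kld, fcd=None)
    valid = _canonical_valid(sample)
    if valid:
        sas_vals = np.array([sas_score(s) for s in valid])
        rep.sas_mean, rep.sas_sd = float(sas_vals.mean()), float(sas_vals.std())
        if predictor is not None:
            preds, flags = predictor.predict(valid)
            rep.pic50_mean = float(np.nanmean(preds))
            rep.pic50_sd = float(np.nanstd(preds))
    return rep


def property_shift_report(unbiased: list[str], biased: list[str],
                          predictor: Pic50Predictor) -> dict:
    """Paired mean +/- sd of pIC50 and SAS before/after optimization."""
    from .chem import sas_score

    out: dict = {}
    for name, sample in (("unbiased", unbiased), ("biased", biased)):
        valid = _canonical_valid(sample)
        if not valid:
            raise ValueError(f"no valid molecules in {name} sample")
        preds, _ = predictor.predict(valid)
        sas_vals = np.array([sas_score(s) for s in valid])
        out[name] = {
            "n": len(sample),
            "n_valid": len(valid),
            "pic50_mean": float(np.nanmean(preds)),
            "pic50_sd": float(np.nanstd(preds)),
            "sas_mean": float(sas_vals.mean()),
            "sas_sd": float(sas_vals.std()),
            "pic50_values": [float(p) for p in preds],
            "sas_values": sas_vals.tolist(),
        }
    out["pic50_shift"] = out["biased"]["pic50_mean"] - out["unbiased"]["pic50_mean"]
    out["sas_shift"] = out["biased"]["sas_mean"] - out["unbiased"]["sas_mean"]
    return out
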