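"""SMILES tokenization with a fixed chemistry-aware vocabulary.

Multi-character chemical units — two-letter elements (Cl, Br), bracket
atoms like ``[nH]``, the ``@@`` chirality mark, ``%nn`` ring closures —
are single tokens, so a downstream sequence model never has to learn to
reassemble them.  Segmentation is greedy longest-match; spans the
vocabulary cannot cover map to UNK.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

PAD, GO, EOS, UNK = "<pad>", "<go>", "<eos>", "<unk>"

# Organic-subset atoms, aromatic atoms, common bracket atoms, bonds, ring
# digits (incl. %nn two-digit closures), branches and stereo markers.
DEFAULT_TOKENS: tuple[str, ...] = (
    "Cl", "Br", "B", "C", "N", "O", "P", "S", "F", "I",
    "b", "c", "n", "o", "p", "s",
    "[nH]", "[n+]", "[N+]", "[N-]", "[O-]", "[NH+]", "[NH2+]", "[NH3+]",
    "[C@H]", "[C@@H]", "[C@]", "[C@@]", "[S+]", "[s+]", "[o+]", "[OH+]",
    "@@", "@",
    "-", "=", "#", "/", "\\",
    "(", ")",
    "%10", "%11", "%12",
    "1", "2", "3", "4", "5", "6", "7", "8", "9", "0",
    ".", "+",
)


@dataclass
class TokenVocabulary:
    """Bijective token <-> index map; PAD is pinned to index 0."""

    tokens: list[str] = field(default_factory=lambda: list(DEFAULT_TOKENS))
    index_of: dict[str, int] = field(init=False)

    def __post_init__(self):
        self.specials = [PAD, GO, EOS, UNK]
        ordered = self.specials + [t for t in self.tokens if t not in self.specials]
        self.tokens = ordered
        self.index_of = {t: i for i, t in enumerate(ordered)}
        if len(self.index_of) != len(ordered):
            raise ValueError("duplicate tokens in vocabulary")
        # longest-first pattern so multi-character tokens win
        chem = sorted((t for t in ordered if t not in self.specials),
                      key=len, reverse=True)
        self._pattern = re.compile("|".join(re.escape(t) for t in chem))

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_idx(self) -> int:
        return self.index_of[PAD]

    @property
    def go_idx(self) -> int:
        return self.index_of[GO]

    @property
    def eos_idx(self) -> int:
        return self.index_of[EOS]

    @property
    def unk_idx(self) -> int:
        return self.index_of[UNK]


def tokenize(smiles: str, vocab: TokenVocabulary) -> list[str]:
    """Greedy longest-match segmentation; uncovered characters become UNK."""
    if not smiles:
        raise ValueError("empty SMILES string")
    out: list[str] = []
    pos = 0
    while pos < len(smiles):
        m = vocab._pattern.match(smiles, pos)
        if m:
            out.append(m.group(0))
            pos = m.end()
        else:
            out.append(UNK)
            pos += 1
    return out


def detokenize(tokens: list[str]) -> str:
    return "".join(t for t in tokens if t not in (PAD, GO, EOS))


def pad_encode(tokens: list[str], vocab: TokenVocabulary, max_len: int) -> np.ndarray:
    """Encode as [GO, t1..tn, EOS, PAD...] of total length max_len + 2."""
    if len(tokens) > max_len:
        raise ValueError(f"sequence length {len(tokens)} exceeds max_len {max_len}")
    idx = [vocab.go_idx]
    idx.extend(vocab.index_of.get(t, vocab.unk_idx) for t in tokens)
    idx.append(vocab.eos_idx)
    idx.extend([vocab.pad_idx] * (max_len + 2 - len(idx)))
    return np.asarray(idx, dtype=np.int64)


def decode(indices: np.ndarray, vocab: TokenVocabulary) -> list[str]:
    """Invert :func:`pad_encode`: strip GO/EOS/PAD, map indices to tokens."""
    out = []
    for i in indices:
        t = vocab.tokens[int(i)]
        if t == EOS:
            break
        if t in (GO, PAD):
            continue
        out.append(t)
    return out


def encode_batch(smiles_list: list[str], vocab: TokenVocabulary,
                 max_len: int) -> np.ndarray:
    """Tokenize and pad a list of SMILES into an (n, max_len+2) int array."""
    return np.stack([pad_encode(tokenize(s, vocab), vocab, max_len)
                     for s in smiles_list])
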