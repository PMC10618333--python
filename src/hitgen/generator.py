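"""Recurrent SMILES language model.

Architecture: embedding -> two stacked LSTM layers -> softmax-activated
dense layer over the token vocabulary.  Pretraining is teacher-forced
next-token prediction under categorical cross-entropy averaged per token
and per batch; generation is autoregressive sampling with a softmax
temperature (logits divided by T before normalization), stopping at EOS
or the length cap.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .nn.layers import lstm_sequence
from .tokenizer import (
    TokenVocabulary,
    decode,
    detokenize,
    encode_batch,
    pad_encode,
    tokenize,
)


@dataclass
class GeneratorConfig:
    embedding_dim: int = 64
    units_per_layer: int = 128
    recurrent_layers: int = 2
    max_len: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 128
    temperature: float = 0.8

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


class SmilesGenerator(nn.Module):
    """LSTM language model over a fixed SMILES token vocabulary."""

    def __init__(self, vocab: TokenVocabulary, config: GeneratorConfig | None = None,
                 seed: int = 0):
        self.vocab = vocab
        self.config = config or GeneratorConfig()
        rng = np.random.default_rng(seed)
        cfg = self.config
        self.embedding = nn.Embedding(len(vocab), cfg.embedding_dim, rng)
        self.cells = []
        n_in = cfg.embedding_dim
        for _ in range(cfg.recurrent_layers):
            self.cells.append(nn.LSTMCell(n_in, cfg.units_per_layer, rng))
            n_in = cfg.units_per_layer
        self.out = nn.Dense(cfg.units_per_layer, len(vocab), rng)

    # ------------------------------------------------------------------
    def _step(self, token_idx: np.ndarray, states: list) -> tuple[Tensor, list]:
        """One decoding step for a batch of token indices -> logits."""
        x = nn.embedding(self.embedding.W, token_idx)
        new_states = []
        for cell, st in zip(self.cells, states):
            x, st2 = cell.step(x, st)
            new_states.append(st2)
        return self.out(x), new_states

    def _init_states(self, batch: int) -> list:
        return [c.init_state(batch) for c in self.cells]

    def step_log_probs(self, encoded: np.ndarray) -> Tensor:
        """Teacher-forced per-step log-probabilities of the realized tokens.

        ``encoded`` is an (B, L) int array beginning with GO.  Returns a
        (B, L-1) tensor of log pi(token_{t+1} | prefix).  PAD positions
        carry the log-probability of PAD and must be masked by callers.
        """
        enc = np.atleast_2d(encoded)
        B, L = enc.shape
        x = nn.embedding(self.embedding.W, enc[:, :-1])  # (B, T, D)
        for cell in self.cells:
            x = lstm_sequence(cell, x)
        H = self.config.units_per_layer
        logits = x.reshape(B * (L - 1), H) @ self.out.W + self.out.b
        lp = nn.log_softmax(logits)
        sel = nn.select_rows(lp, enc[:, 1:].reshape(-1))
        return sel.reshape(B, L - 1)

    def sequence_log_probs(self, encoded: np.ndarray) -> np.ndarray:
        """Per-step log pi(A_t|S_t) for one encoded sequence (inference).

        The vector covers tokens after GO up to and including EOS.
        """
        enc = np.asarray(encoded)
        if enc.max() >= len(self.vocab) or enc.min() < 0:
            raise ValueError("token index outside vocabulary")
        with nn.no_grad():
            lps = self.step_log_probs(enc[None, :]).data[0]
        # trim at EOS (inclusive); drop trailing PAD transitions
        out = []
        for t in range(len(enc) - 1):
            out.append(lps[t])
            if enc[t + 1] == self.vocab.eos_idx:
                break
        return np.asarray(out)

    # ------------------------------------------------------------------
    def pretrain(self, corpus: list[str], epochs: int = 10, seed: int = 0,
                 batch_size: int | None = None, lr_decay: float = 1.0,
                 verbose: bool = False) -> list[float]:
        """Teacher-forced training; returns the per-epoch mean loss trace."""
        if not corpus:
            raise ValueError("empty training corpus")
        cfg = self.config
        batch_size = batch_size or cfg.batch_size
        enc = encode_batch(corpus, self.vocab, cfg.max_len)
        # trim shared trailing padding to the longest sequence
        used = int((enc != self.vocab.pad_idx).sum(axis=1).max())
        enc = enc[:, : used + 1]
        rng = np.random.default_rng(seed)
        opt = nn.Adam(self.parameters(), lr=cfg.learning_rate, clip_norm=5.0)
        trace = []
        for epoch in range(epochs):
            order = rng.permutation(len(enc))
            losses = []
            for lo in range(0, len(enc), batch_size):
                batch = enc[order[lo:lo + batch_size]]
                loss = self._batch_loss(batch)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            trace.append(float(np.mean(losses)))
            opt.lr *= lr_decay
            if verbose:
                print(f"epoch {epoch + 1}: loss {trace[-1]:.4f}")
        return trace

    def _batch_loss(self, enc: np.ndarray) -> Tensor:
        """Categorical cross-entropy averaged per token, then per sequence."""
        targets = enc[:, 1:]
        mask = (targets != self.vocab.pad_idx).astype(float)
        lengths = mask.sum(axis=1, keepdims=True)
        weights = mask / np.maximum(lengths, 1.0) / enc.shape[0]
        lps = self.step_log_probs(enc)
        return -(lps * Tensor(weights)).sum()

    # ------------------------------------------------------------------
    def sample(self, n: int, temperature: float | None = None, seed: int = 0,
               batch_size: int = 500) -> list[str]:
        """Draw ``n`` raw SMILES strings by autoregressive sampling."""
        if n <= 0:
            raise ValueError("n must be positive")
        temperature = self.config.temperature if temperature is None else temperature
        if temperature < 0:
            raise ValueError("temperature must be non-negative")
        rng = np.random.default_rng(seed)
        out: list[str] = []
        while len(out) < n:
            b = min(batch_size, n - len(out))
            out.extend(self._sample_batch(b, temperature, rng))
        return out

    def _sample_batch(self, b: int, temperature: float,
                      rng: np.random.Generator) -> list[str]:
        v = self.vocab
        with nn.no_grad():
            states = self._init_states(b)
            current = np.full(b, v.go_idx, dtype=np.int64)
            alive = np.ones(b, dtype=bool)
            seqs: list[list[int]] = [[] for _ in range(b)]
            for _ in range(self.config.max_len + 1):
                logits, states = self._step(current, states)
                if temperature < 1e-8:
                    nxt = logits.data.argmax(axis=1)
                else:
                    scaled = logits.data / temperature
                    scaled -= scaled.max(axis=1, keepdims=True)
                    probs = np.exp(scaled)
                    probs /= probs.sum(axis=1, keepdims=True)
                    u = rng.random((b, 1))
                    nxt = (probs.cumsum(axis=1) < u).sum(axis=1)
                    nxt = np.minimum(nxt, len(v) - 1)
                for i in range(b):
                    if alive[i]:
                        if nxt[i] == v.eos_idx:
                            alive[i] = False
                        else:
                            seqs[i].append(int(nxt[i]))
                if not alive.any():
                    break
                nxt = np.where(alive, nxt, v.pad_idx)
                current = nxt
        return [detokenize([v.tokens[i] for i in s]) for s in seqs]

    def greedy_decode(self) -> str:
        """Deterministic argmax decoding from GO (temperature -> 0 limit)."""
        return self.sample(1, temperature=0.0, seed=0)[0]

    def encode(self, smiles: str) -> np.ndarray:
        return pad_encode(tokenize(smiles, self.vocab), self.vocab,
                          self.config.max_len)

    # ------------------------------------------------------------------
    def save(self, path: str) -> None:
        arrays = self.state_arrays()
        meta = json.dumps({"config": asdict(self.config),
                           "tokens": self.vocab.tokens})
        np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **{f"p{i}": a for i, a in enumerate(arrays)})

    @classmethod
    def load(cls, path: str) -> "SmilesGenerator":
        data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
        meta = json.loads(bytes(data["meta"]).decode())
        vocab = TokenVocabulary(tokens=[t for t in meta["tokens"]])
        gen = cls(vocab, GeneratorConfig(**meta["config"]))
        gen.load_arrays([data[f"p{i}"] for i in range(len(data.files) - 1)])
        return gen

    def clone(self) -> "SmilesGenerator":
        g = SmilesGenerator(self.vocab, self.config)
        g.load_arrays([a.copy() for a in self.state_arrays()])
        return g
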