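"""pIC50 regression from SMILES or fingerprints.

Ten configurations (A-J) pair a molecular descriptor with a network:
fingerprint inputs (ECFP4/ECFP6/RDKit path fingerprint) feed a
feed-forward network; tokenized SMILES feed recurrent stacks —
unidirectional GRU, bidirectional GRU, bidirectional + stacked GRU, or
two separated directional streams — optionally pooled by an additive
attention layer.  The default configuration (I) is
embedding -> bidirectional GRU -> GRU -> attention pool -> dropout ->
linear output.

Attention follows the additive scheme: a dense alignment network scores
each hidden state against a learned output query, a tanh squashes the
score, and a softmax over positions yields weights ``alpha`` with
``context = sum_i alpha_i h_i``.

Labels are standardized robustly as ``z = (y - median) / IQR`` with
linearly interpolated quartiles.  Training uses Adam, early stopping on
a validation split with best-checkpoint restoration, and shuffled
85/15 cross-validation splits plus a hold-out set carved off first.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from . import nn
from .chem import canonicalize, ecfp
from .nn import Tensor
from .nn.layers import gru_sequence
from .tokenizer import TokenVocabulary, encode_batch, pad_encode, tokenize

#: configuration -> (descriptor, architecture, attention)
CONFIGURATIONS: dict[str, tuple[str, str, bool]] = {
    "A": ("ecfp4", "mlp", False),
    "B": ("ecfp6", "mlp", False),
    "C": ("rdkit_fp", "mlp", False),
    "D": ("smiles", "rnn", False),
    "E": ("smiles", "rnn", True),
    "F": ("smiles", "birnn", False),
    "G": ("smiles", "birnn", True),
    "H": ("smiles", "birnn_rnn", False),
    "I": ("smiles", "birnn_rnn", True),
    "J": ("smiles", "sep_birnn", True),
}


@dataclass
class PredictorConfig:
    configuration: str = "I"
    embedding_dim: int = 256
    recurrent_units: int = 128
    dropout: float = 0.3
    nbits: int = 2048
    max_len: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    patience: int = 15

    def __post_init__(self):
        if self.configuration not in CONFIGURATIONS:
            raise ValueError(f"unknown configuration {self.configuration!r}")

    @property
    def descriptor(self) -> str:
        return CONFIGURATIONS[self.configuration][0]

    @property
    def architecture(self) -> str:
        return CONFIGURATIONS[self.configuration][1]

    @property
    def attention(self) -> bool:
        return CONFIGURATIONS[self.configuration][2]


# ---------------------------------------------------------------- scaling
@dataclass
class LabelScaler:
    """Robust standardization: z = (y - median) / IQR."""

    median: float
    iqr: float

    @classmethod
    def fit(cls, y: np.ndarray) -> "LabelScaler":
        y = np.asarray(y, dtype=float)
        if len(y) < 4:
            raise ValueError("need at least 4 labels to fit the scaler")
        q1, med, q3 = np.percentile(y, [25, 50, 75])
        iqr = q3 - q1
        if iqr <= 0:
            raise ValueError("degenerate labels: interquartile range is zero")
        return cls(median=float(med), iqr=float(iqr))

    def transform(self, y) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.median) / self.iqr

    def invert(self, z) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.iqr + self.median


def standardize_labels(y) -> tuple[LabelScaler, np.ndarray]:
    scaler = LabelScaler.fit(np.asarray(y))
    return scaler, scaler.transform(y)


# ---------------------------------------------------------------- metrics
@dataclass
class RegressionMetrics:
    mse: float
    rmse: float
    q2: float
    ccc: float

    def as_dict(self) -> dict:
        return asdict(self)


def regression_metrics(y, yhat) -> RegressionMetrics:
    """MSE, RMSE, coefficient of determination Q2, and Lin's CCC."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch between labels and predictions")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    resid = y - yhat
    mse = float(np.mean(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    sy = y.std()
    syh = yhat.std()
    cov = float(np.mean((y - y.mean()) * (yhat - yhat.mean())))
    denom = sy ** 2 + syh ** 2 + (y.mean() - yhat.mean()) ** 2
    ccc = 2.0 * cov / denom if denom > 0 else float("nan")
    return RegressionMetrics(mse=mse, rmse=float(np.sqrt(mse)), q2=q2, ccc=ccc)


# ---------------------------------------------------------------- attention
@dataclass
class AttentionContext:
    """Per-token attention weights and the pooled context vector."""

    alphas: np.ndarray      # (T,)
    context: np.ndarray     # (H,)
    tokens: list[str] | None = None


def attention_pool(hidden: Tensor, score_net: "nn.Dense",
                   mask: np.ndarray | None = None) -> tuple[Tensor, Tensor]:
    """Additive attention over a (B, T, H) slab.

    scores_i = score_net(h_i); alpha = softmax(tanh(scores)) over valid
    positions; context = sum_i alpha_i h_i.  Returns (context (B, H),
    alphas (B, T)).
    """
    B, T, H = hidden.shape
    if T < 1:
        raise ValueError("attention over an empty sequence")
    flat = hidden.reshape(B * T, H)
    scores = (flat @ score_net.W + score_net.b).reshape(B, T)
    squashed = scores.tanh()
    if mask is not None:
        squashed = squashed + Tensor((mask.astype(float) - 1.0) * 1e9)
    alphas = nn.softmax(squashed, axis=1)
    weighted = hidden * alphas.reshape(B, T, 1)
    context = weighted.sum(axis=1)
    return context, alphas


# ---------------------------------------------------------------- model
class Pic50Predictor(nn.Module):
    """Bioactivity regressor over one of the A-J configurations."""

    def __init__(self, vocab: TokenVocabulary | None = None,
                 config: PredictorConfig | None = None, seed: int = 0):
        self.config = config or PredictorConfig()
        self.vocab = vocab or TokenVocabulary()
        self.scaler: LabelScaler | None = None
        cfg = self.config
        rng = np.random.default_rng(seed)
        self._rng = np.random.default_rng(seed + 1)  # dropout masks
        H = cfg.recurrent_units
        if cfg.descriptor == "smiles":
            self.embedding = nn.Embedding(len(self.vocab), cfg.embedding_dim, rng)
            arch = cfg.architecture
            if arch == "rnn":
                self.cells = [nn.GRUCell(cfg.embedding_dim, H, rng)]
                pooled = H
            elif arch == "birnn":
                self.cells = [nn.GRUCell(cfg.embedding_dim, H, rng),
                              nn.GRUCell(cfg.embedding_dim, H, rng)]
                pooled = 2 * H
            elif arch == "birnn_rnn":
                self.cells = [nn.GRUCell(cfg.embedding_dim, H, rng),
                              nn.GRUCell(cfg.embedding_dim, H, rng),
                              nn.GRUCell(2 * H, H, rng)]
                pooled = H
            elif arch == "sep_birnn":
                self.cells = [nn.GRUCell(cfg.embedding_dim, H, rng),
                              nn.GRUCell(cfg.embedding_dim, H, rng)]
                pooled = 2 * H
            else:  # pragma: no cover
                raise ValueError(arch)
            if cfg.attention:
                if arch == "sep_birnn":
                    self.score_net = nn.Dense(H, 1, rng)
                    self.score_net_bwd = nn.Dense(H, 1, rng)
                else:
                    self.score_net = nn.Dense(pooled, 1, rng)
            self.out = nn.Dense(pooled, 1, rng)
        else:
            if cfg.attention:
                raise ValueError("attention requires a sequence descriptor")
            self.fc1 = nn.Dense(cfg.nbits, 256, rng)
            self.fc2 = nn.Dense(256, 64, rng)
            self.out = nn.Dense(64, 1, rng)

    # ------------------------------------------------------------------
    def _featurize(self, smiles_list: list[str]) -> np.ndarray:
        cfg = self.config
        if cfg.descriptor == "smiles":
            return encode_batch(smiles_list, self.vocab, cfg.max_len)
        rows = []
        for s in smiles_list:
            rec = canonicalize(s)
            if cfg.descriptor == "ecfp4":
                rows.append(ecfp(rec, radius=2, nbits=cfg.nbits).bits)
            elif cfg.descriptor == "ecfp6":
                rows.append(ecfp(rec, radius=3, nbits=cfg.nbits).bits)
            else:
                fp = Chem.RDKFingerprint(rec.mol(), fpSize=cfg.nbits)
                rows.append(np.asarray(fp, dtype=np.uint8))
        return np.asarray(rows, dtype=float)

    def _forward(self, features: np.ndarray, train: bool = False
                 ) -> tuple[Tensor, Tensor | None]:
        """Returns (standardized predictions (B,), alphas (B,T) or None)."""
        cfg = self.config
        if cfg.descriptor != "smiles":
            x = Tensor(features)
            h = (self.fc1(x)).relu()
            h = (self.fc2(h)).relu()
            h = nn.dropout(h, cfg.dropout, self._rng, train)
            return self.out(h).reshape(-1), None

        enc = features
        # trim to the longest sequence in the batch (padding is shared)
        used = int((enc != self.vocab.pad_idx).sum(axis=1).max())
        enc = enc[:, :used]
        mask = (enc != self.vocab.pad_idx).astype(float)
        lengths = mask.sum(axis=1).astype(int)
        B, T = enc.shape
        x = nn.embedding(self.embedding.W, enc)
        arch = cfg.architecture
        alphas = None
        if arch == "rnn":
            hs = gru_sequence(self.cells[0], x, mask=mask)
            if cfg.attention:
                pooled, alphas = attention_pool(hs, self.score_net, mask)
            else:
                pooled = hs[(np.arange(B), lengths - 1)]
        elif arch == "birnn":
            fwd = gru_sequence(self.cells[0], x, mask=mask)
            bwd = gru_sequence(self.cells[1], x, reverse=True, mask=mask)
            hs = nn.concatenate([fwd, bwd], axis=2)
            if cfg.attention:
                pooled, alphas = attention_pool(hs, self.score_net, mask)
            else:
                last_f = fwd[(np.arange(B), lengths - 1)]
                first_b = bwd[(np.arange(B), np.zeros(B, dtype=int))]
                pooled = nn.concatenate([last_f, first_b], axis=1)
        elif arch == "birnn_rnn":
            fwd = gru_sequence(self.cells[0], x, mask=mask)
            bwd = gru_sequence(self.cells[1], x, reverse=True, mask=mask)
            h1 = nn.concatenate([fwd, bwd], axis=2)
            hs = gru_sequence(self.cells[2], h1, mask=mask)
            if cfg.attention:
                pooled, alphas = attention_pool(hs, self.score_net, mask)
            else:
                pooled = hs[(np.arange(B), lengths - 1)]
        else:  # sep_birnn: separated directional streams, pooled independently
            fwd = gru_sequence(self.cells[0], x, mask=mask)
            bwd = gru_sequence(self.cells[1], x, reverse=True, mask=mask)
            ctx_f, alpha_f = attention_pool(fwd, self.score_net, mask)
            ctx_b, _ = attention_pool(bwd, self.score_net_bwd, mask)
            pooled = nn.concatenate([ctx_f, ctx_b], axis=1)
            alphas = alpha_f
        pooled = nn.dropout(pooled, cfg.dropout, self._rng, train)
        return self.out(pooled).reshape(-1), alphas

    # ------------------------------------------------------------------
    def fit(self, smiles: list[str], pic50: np.ndarray, seed: int = 0,
            epochs: int | None = None, val_fraction: float = 0.15,
            learning_rate: float | None = None, refit_scaler: bool = True,
            verbose: bool = False) -> dict:
        """Train with early stopping on an internal validation split.

        Returns a history dict with per-epoch train/validation MSE (in
        standardized units) and the restored best epoch.
        """
        cfg = self.config
        epochs = cfg.epochs if epochs is None else epochs
        lr = cfg.learning_rate if learning_rate is None else learning_rate
        pic50 = np.asarray(pic50, dtype=float)
        if len(smiles) == 0:
            raise ValueError("empty training set")
        if refit_scaler or self.scaler is None:
            self.scaler = LabelScaler.fit(pic50)
        z = self.scaler.transform(pic50)
        feats = self._featurize(smiles)
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(smiles))
        n_val = max(1, int(round(val_fraction * len(smiles)))) if val_fraction > 0 else 0
        val_idx, tr_idx = order[:n_val], order[n_val:]
        if len(tr_idx) == 0:
            tr_idx = order
        opt = nn.Adam(self.parameters(), lr=lr, clip_norm=5.0)
        best_val = np.inf
        best_state = [a.copy() for a in self.state_arrays()]
        best_epoch = 0
        wait = 0
        history = {"train_mse": [], "val_mse": []}
        for epoch in range(epochs):
            ep_order = rng.permutation(tr_idx)
            losses = []
            for lo in range(0, len(ep_order), cfg.batch_size):
                idx = ep_order[lo:lo + cfg.batch_size]
                pred, _ = self._forward(feats[idx], train=True)
                err = pred - Tensor(z[idx])
                loss = (err * err).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            history["train_mse"].append(float(np.mean(losses)))
            if n_val:
                with nn.no_grad():
                    pv, _ = self._forward(feats[val_idx], train=False)
                val_mse = float(np.mean((pv.data - z[val_idx]) ** 2))
            else:
                val_mse = history["train_mse"][-1]
            history["val_mse"].append(val_mse)
            if verbose:
                print(f"epoch {epoch + 1}: train {history['train_mse'][-1]:.4f} "
                      f"val {val_mse:.4f}")
            if val_mse < best_val - 1e-6:
                best_val = val_mse
                best_state = [a.copy() for a in self.state_arrays()]
                best_epoch = epoch + 1
                wait = 0
            else:
                wait += 1
                if wait >= cfg.patience:
                    break
        self.load_arrays(best_state)
        history["best_epoch"] = best_epoch
        history["best_val_mse"] = float(best_val)
        return history

    # ------------------------------------------------------------------
    def predict(self, smiles_list: list[str], return_attention: bool = False,
                batch_size: int = 256):
        """Predict pIC50 for each valid SMILES (canonicalize-before-predict).

        Returns (values, valid_flags) or (values, valid_flags, contexts)
        when attention is requested; invalid inputs get NaN and a False
        flag.  Batch and per-item predictions agree because inference
        uses no dropout.
        """
        if self.scaler is None:
            raise RuntimeError("predictor is untrained")
        flags = np.zeros(len(smiles_list), dtype=bool)
        canon: list[str | None] = []
        for s in smiles_list:
            rec = canonicalize(s) if s else None
            if rec is not None and rec.valid:
                canon.append(rec.smiles_canonical)
                flags[len(canon) - 1] = True
            else:
                canon.append(None)
        values = np.full(len(smiles_list), np.nan)
        contexts: list[AttentionContext | None] = [None] * len(smiles_list)
        valid_pos = [i for i, c in enumerate(canon) if c is not None]
        for lo in range(0, len(valid_pos), batch_size):
            pos = valid_pos[lo:lo + batch_size]
            feats = self._featurize([canon[i] for i in pos])
            with nn.no_grad():
                pred, alphas = self._forward(feats, train=False)
            values[pos] = self.scaler.invert(pred.data)
            if return_attention and alphas is not None:
                for row, i in enumerate(pos):
                    toks = tokenize(canon[i], self.vocab)
                    # positions 1..len(toks) carry the SMILES tokens (0 is GO)
                    a = alphas.data[row][1:len(toks) + 1]
                    a = a / max(a.sum(), 1e-12)
                    contexts[i] = AttentionContext(alphas=a, context=np.zeros(0),
                                                   tokens=toks)
        if return_attention:
            if not self.config.attention:
                raise ValueError("model has no attention mechanism")
            return values, flags, contexts
        return values, flags

    def attention_weights(self, smiles: str) -> AttentionContext:
        """Per-token attention weights for one molecule."""
        if not self.config.attention:
            raise ValueError("model has no attention mechanism")
        values, flags, ctx = self.predict([smiles], return_attention=True)
        if not flags[0]:
            raise ValueError(f"invalid SMILES: {smiles!r}")
        return ctx[0]

    # ------------------------------------------------------------------
    def save(self, path: str) -> None:
        meta = json.dumps({"config": asdict(self.config),
                           "tokens": self.vocab.tokens,
                           "scaler": asdict(self.scaler) if self.scaler else None})
        np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **{f"p{i}": a for i, a in enumerate(self.state_arrays())})

    @classmethod
    def load(cls, path: str) -> "Pic50Predictor":
        data = np.load(path if str(path).endswith(".npz") else str(path) + ".npz")
        meta = json.loads(bytes(data["meta"]).decode())
        vocab = TokenVocabulary(tokens=list(meta["tokens"]))
        model = cls(vocab, PredictorConfig(**meta["config"]))
        model.load_arrays([data[f"p{i}"] for i in range(len(data.files) - 1)])
        if meta["scaler"]:
            model.scaler = LabelScaler(**meta["scaler"])
        return model


# ---------------------------------------------------------------- training
def _prepare_dataset(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Canonicalize, drop unparseable rows, collapse duplicate molecules."""
    canon = []
    keep = []
    for i, s in enumerate(df["smiles"]):
        rec = canonicalize(str(s))
        if rec.valid:
            canon.append(rec.smiles_canonical)
            keep.append(i)
    dropped = len(df) - len(keep)
    out = df.iloc[keep].copy()
    out["smiles"] = canon
    out = out.groupby("smiles", as_index=False, sort=False)["pic50"].mean()
    return out, dropped


def train_predictor(dataset: pd.DataFrame, config: PredictorConfig | None = None,
                    seed: int = 0, n_folds: int = 5, holdout_fraction: float = 0.1,
                    epochs: int | None = None, run_cv: bool = True,
                    verbose: bool = False) -> tuple[Pic50Predictor, dict]:
    """Cross-validated training of a pIC50 predictor.

    The dataset is deduplicated on canonical SMILES, a hold-out set is
    carved off first, and ``n_folds`` shuffled 85/15 train/validation
    splits are trained with early stopping.  The returned model is
    refit on the full CV pool; the report carries per-fold and hold-out
    metrics plus the dropped-row count.
    """
    config = config or PredictorConfig()
    data, dropped = _prepare_dataset(dataset)
    if len(data) == 0:
        raise ValueError("no parseable molecules in dataset")
    if len(data) < 50:
        raise ValueError("need at least 50 unique molecules")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(data))
    n_hold = int(round(holdout_fraction * len(data)))
    hold_idx, pool_idx = order[:n_hold], order[n_hold:]
    pool = data.iloc[pool_idx]
    report: dict = {"dropped_rows": int(dropped), "folds": [],
                    "n_train": int(len(pool)), "n_holdout": int(len(hold_idx))}
    if run_cv:
        for k in range(n_folds):
            fold_model = Pic50Predictor(config=config, seed=seed + 100 + k)
            hist = fold_model.fit(list(pool["smiles"]), pool["pic50"].to_numpy(),
                                  seed=seed + 100 + k, epochs=epochs,
                                  verbose=verbose)
            z_val = hist["best_val_mse"]
            report["folds"].append({"val_mse_std": float(z_val),
                                    "best_epoch": hist["best_epoch"]})
    model = Pic50Predictor(config=config, seed=seed)
    model.fit(list(pool["smiles"]), pool["pic50"].to_numpy(), seed=seed,
              epochs=epochs, verbose=verbose)
    if n_hold:
        hold = data.iloc[hold_idx]
        pred, _ = model.predict(list(hold["smiles"]))
        report["holdout"] = regression_metrics(hold["pic50"].to_numpy(),
                                               pred).as_dict()
    return model, report


def fine_tune(model: Pic50Predictor, subset: pd.DataFrame, epochs: int = 10,
              lr_factor: float = 0.1, seed: int = 0) -> Pic50Predictor:
    """Continue training on a focused subset at a reduced learning rate.

    The label scaler is kept frozen so predictions stay on the original
    pIC50 scale; zero epochs returns the model unchanged.
    """
    if len(subset) == 0:
        raise ValueError("empty fine-tuning subset")
    if epochs == 0:
        return model
    model.fit(list(subset["smiles"]), subset["pic50"].to_numpy(), seed=seed,
              epochs=epochs, learning_rate=model.config.learning_rate * lr_factor,
              refit_scaler=False, val_fraction=0.15)
    return model
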