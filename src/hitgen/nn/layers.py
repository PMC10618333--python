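"""Neural-network building blocks on the autodiff core.

Layers hold :class:`~hitgen.nn.tensor.Tensor` parameters and expose a
functional ``__call__``.  Recurrent cells process one timestep of a
``(batch, features)`` slab; sequence drivers live with the models that
use them.  Weight layout follows the usual fused-gate convention
(input and recurrent weights concatenated, gates side by side).
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concatenate


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _recurrent_init(rng: np.random.Generator, n_in: int, n_hidden: int,
                    n_gates: int) -> np.ndarray:
    """Glorot input block stacked on orthogonal per-gate recurrent blocks."""
    W = np.empty((n_in + n_hidden, n_gates * n_hidden))
    W[:n_in] = _glorot(rng, n_in, n_gates * n_hidden)
    for g in range(n_gates):
        q, _ = np.linalg.qr(rng.normal(size=(n_hidden, n_hidden)))
        W[n_in:, g * n_hidden:(g + 1) * n_hidden] = q
    return W


class Module:
    """Parameter container with recursive collection."""

    def parameters(self) -> list[Tensor]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = a.astype(p.data.dtype).copy()


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Tensor(_glorot(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Embedding(Module):
    def __init__(self, n_vocab: int, dim: int, rng: np.random.Generator):
        self.W = Tensor(rng.normal(0, 0.1, size=(n_vocab, dim)), requires_grad=True)


class LSTMCell(Module):
    """Fused-gate LSTM cell; gate order [i, f, g, o]; forget bias 1."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.W = Tensor(_recurrent_init(rng, n_in, n_hidden, 4), requires_grad=True)
        b = np.zeros(4 * n_hidden)
        b[n_hidden:2 * n_hidden] = 1.0
        self.b = Tensor(b, requires_grad=True)

    def init_state(self, batch: int) -> tuple[Tensor, Tensor]:
        z = np.zeros((batch, self.n_hidden))
        return Tensor(z), Tensor(z.copy())

    def step(self, x: Tensor, state: tuple[Tensor, Tensor]) -> tuple[Tensor, tuple[Tensor, Tensor]]:
        h_prev, c_prev = state
        z = concatenate([x, h_prev], axis=-1) @ self.W + self.b
        H = self.n_hidden
        i = z[:, 0 * H:1 * H].sigmoid()
        f = z[:, 1 * H:2 * H].sigmoid()
        g = z[:, 2 * H:3 * H].tanh()
        o = z[:, 3 * H:4 * H].sigmoid()
        c = f * c_prev + i * g
        h = o * c.tanh()
        return h, (h, c)


class GRUCell(Module):
    """Fused-gate GRU cell; gate order [z, r] plus candidate."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.Wg = Tensor(_recurrent_init(rng, n_in, n_hidden, 2), requires_grad=True)
        self.bg = Tensor(np.zeros(2 * n_hidden), requires_grad=True)
        self.Wc = Tensor(_recurrent_init(rng, n_in, n_hidden, 1), requires_grad=True)
        self.bc = Tensor(np.zeros(n_hidden), requires_grad=True)

    def init_state(self, batch: int) -> Tensor:
        return Tensor(np.zeros((batch, self.n_hidden)))

    def step(self, x: Tensor, h_prev: Tensor) -> tuple[Tensor, Tensor]:
        H = self.n_hidden
        gates = concatenate([x, h_prev], axis=-1) @ self.Wg + self.bg
        zg = gates[:, 0 * H:1 * H].sigmoid()
        rg = gates[:, 1 * H:2 * H].sigmoid()
        cand = (concatenate([x, rg * h_prev], axis=-1) @ self.Wc + self.bc).tanh()
        h = zg * h_prev + (1.0 - zg) * cand
        return h, h


def lstm_sequence(cell: "LSTMCell", x: Tensor, h0: np.ndarray | None = None,
                  c0: np.ndarray | None = None,
                  mask: np.ndarray | None = None) -> Tensor:
    """Run an LSTM over a full (B, T, D) slab; returns hidden states (B, T, H).

    Fused op with hand-written backpropagation-through-time: the input
    projection is one large matmul and each timestep only does the
    recurrent update, which makes it several times faster than stepping
    the cell through the autodiff graph.  ``mask`` (B, T) holds the
    state constant on padded steps so batch padding cannot leak into
    the representation.
    """
    B, T, D = x.data.shape
    H = cell.n_hidden
    W, b = cell.W, cell.b
    Wx = W.data[:D]
    Wh = W.data[D:]
    xp = x.data.reshape(B * T, D) @ Wx + b.data  # (B*T, 4H)
    xp = xp.reshape(B, T, 4 * H)
    dt = x.data.dtype
    m_all = None if mask is None else mask.astype(dt)[:, :, None]
    h = np.zeros((B, H), dtype=dt) if h0 is None else h0
    c = np.zeros((B, H), dtype=dt) if c0 is None else c0
    hs = np.empty((B, T, H), dtype=dt)
    cache = []
    for t in range(T):
        z = xp[:, t] + h @ Wh
        i = 1 / (1 + np.exp(-z[:, :H]))
        f = 1 / (1 + np.exp(-z[:, H:2 * H]))
        g = np.tanh(z[:, 2 * H:3 * H])
        o = 1 / (1 + np.exp(-z[:, 3 * H:]))
        c_raw = f * c + i * g
        tc = np.tanh(c_raw)
        h_raw = o * tc
        if m_all is None:
            h_new, c_new = h_raw, c_raw
        else:
            m = m_all[:, t]
            h_new = m * h_raw + (1 - m) * h
            c_new = m * c_raw + (1 - m) * c
        cache.append((h, c, i, f, g, o, tc))
        h, c = h_new, c_new
        hs[:, t] = h

    def backward(grad_hs):
        dW = np.zeros_like(W.data)
        dz_all = np.empty((B, T, 4 * H), dtype=dt)
        dh = np.zeros((B, H), dtype=dt)
        dc = np.zeros((B, H), dtype=dt)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh = dh + grad_hs[:, t]
            if m_all is None:
                dh_raw, dc_raw_in = dh, dc
                dh_skip = dc_skip = 0.0
            else:
                m = m_all[:, t]
                dh_raw = dh * m
                dc_raw_in = dc * m
                dh_skip = dh * (1 - m)
                dc_skip = dc * (1 - m)
            do = dh_raw * tc
            dc_raw = dc_raw_in + dh_raw * o * (1 - tc * tc)
            di = dc_raw * g
            df = dc_raw * c_prev
            dg = dc_raw * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g * g), do * o * (1 - o)], axis=1)
            dz_all[:, t] = dz
            dW[D:] += h_prev.T @ dz
            dh = dz @ Wh.T + dh_skip
            dc = dc_raw * f + dc_skip
        dz_flat = dz_all.reshape(B * T, 4 * H)
        if W.requires_grad:
            dW[:D] = x.data.reshape(B * T, D).T @ dz_flat
            W._accum(dW)
        if b.requires_grad:
            b._accum(dz_flat.sum(axis=0))
        if x.requires_grad:
            x._accum((dz_flat @ Wx.T).reshape(B, T, D))

    return Tensor._make(hs, (x, W, b), backward)


def gru_sequence(cell: "GRUCell", x: Tensor, h0: np.ndarray | None = None,
                 reverse: bool = False,
                 mask: np.ndarray | None = None) -> Tensor:
    """Run a GRU over a (B, T, D) slab; returns hidden states (B, T, H).

    ``reverse=True`` processes the sequence right-to-left (the returned
    slab is in original time order), for bidirectional stacks.  ``mask``
    (B, T) holds the state constant on padded steps so batch padding
    cannot leak into the representation.
    """
    B, T, D = x.data.shape
    H = cell.n_hidden
    Wg, bg, Wc, bc = cell.Wg, cell.bg, cell.Wc, cell.bc
    Wgx, Wgh = Wg.data[:D], Wg.data[D:]
    Wcx, Wch = Wc.data[:D], Wc.data[D:]
    order = range(T - 1, -1, -1) if reverse else range(T)
    xg = (x.data.reshape(B * T, D) @ Wgx + bg.data).reshape(B, T, 2 * H)
    xc = (x.data.reshape(B * T, D) @ Wcx + bc.data).reshape(B, T, H)
    dt = x.data.dtype
    m_all = None if mask is None else mask.astype(dt)[:, :, None]
    h = np.zeros((B, H), dtype=dt) if h0 is None else h0
    hs = np.empty((B, T, H), dtype=dt)
    cache = {}
    for t in order:
        gates = xg[:, t] + h @ Wgh
        zg = 1 / (1 + np.exp(-gates[:, :H]))
        rg = 1 / (1 + np.exp(-gates[:, H:]))
        cand = np.tanh(xc[:, t] + (rg * h) @ Wch)
        h_raw = zg * h + (1 - zg) * cand
        if m_all is None:
            h_new = h_raw
        else:
            m = m_all[:, t]
            h_new = m * h_raw + (1 - m) * h
        cache[t] = (h, zg, rg, cand)
        h = h_new
        hs[:, t] = h

    def backward(grad_hs):
        dWg = np.zeros_like(Wg.data)
        dWc = np.zeros_like(Wc.data)
        dzg_all = np.zeros((B, T, 2 * H), dtype=dt)
        dzc_all = np.zeros((B, T, H), dtype=dt)
        dh = np.zeros((B, H), dtype=dt)
        for t in (range(T) if reverse else range(T - 1, -1, -1)):
            h_prev, zg, rg, cand = cache[t]
            dh = dh + grad_hs[:, t]
            if m_all is None:
                dh_raw = dh
                dh_skip = 0.0
            else:
                m = m_all[:, t]
                dh_raw = dh * m
                dh_skip = dh * (1 - m)
            dzg = dh_raw * (h_prev - cand) * zg * (1 - zg)
            dcand = dh_raw * (1 - zg) * (1 - cand * cand)
            drh = dcand @ Wch.T
            drg = drh * h_prev * rg * (1 - rg)
            dgates = np.concatenate([dzg, drg], axis=1)
            dzg_all[:, t] = dgates
            dzc_all[:, t] = dcand
            dWg[D:] += h_prev.T @ dgates
            dWc[D:] += (rg * h_prev).T @ dcand
            dh = dh_raw * zg + dgates @ Wgh.T + drh * rg + dh_skip
        dzg_flat = dzg_all.reshape(B * T, 2 * H)
        dzc_flat = dzc_all.reshape(B * T, H)
        if Wg.requires_grad:
            dWg[:D] = x.data.reshape(B * T, D).T @ dzg_flat
            Wg._accum(dWg)
        if bg.requires_grad:
            bg._accum(dzg_flat.sum(axis=0))
        if Wc.requires_grad:
            dWc[:D] = x.data.reshape(B * T, D).T @ dzc_flat
            Wc._accum(dWc)
        if bc.requires_grad:
            bc._accum(dzc_flat.sum(axis=0))
        if x.requires_grad:
            x._accum((dzg_flat @ Wgx.T).reshape(B, T, D)
                     + (dzc_flat @ Wcx.T).reshape(B, T, D))

    return Tensor._make(hs, (x, Wg, bg, Wc, bc), backward)


class Adam:
    """Adam with optional global-norm gradient clipping."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip_norm and total > 0:
                scale = self.clip_norm / total
                grads = [g * scale for g in grads]
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
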