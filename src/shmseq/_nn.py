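"""Minimal numpy neural-network layers with explicit backpropagation.

Only what the genus classifier needs: 1-D same-padding convolution (via
im2col), a masked bidirectional LSTM, dense layers, inverted dropout,
softmax cross-entropy and Adam.  Forward passes cache what the backward pass
needs; parameters and gradients live in flat name->array dicts so the
optimizer stays trivial.
"""

from __future__ import annotations

import numpy as np


DTYPE = np.float32


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# 1-D convolution (same padding) via im2col
# ---------------------------------------------------------------------------

class Conv1D:
    """y[b,t,f] = relu( sum_{d,c} x[b, t+d-k//2, c] W[d,c,f] + b[f] )."""

    def __init__(self, name: str, kernel: int, in_ch: int, filters: int,
                 params: dict, rng: np.random.Generator) -> None:
        self.name = name
        self.kernel = kernel
        self.in_ch = in_ch
        self.filters = filters
        params[f"{name}/W"] = glorot(rng, kernel * in_ch, filters,
                                     (kernel * in_ch, filters))
        params[f"{name}/b"] = np.zeros(filters, dtype=DTYPE)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        B, T, C = x.shape
        k = self.kernel
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, k - 1 - pad), (0, 0)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        # cols: (B, T, C, k) -> (B, T, k*C) with d-major ordering
        return np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(B, T, k * C)

    def forward(self, params: dict, x: np.ndarray) -> tuple[np.ndarray, dict]:
        cols = self._im2col(x)
        z = cols @ params[f"{self.name}/W"] + params[f"{self.name}/b"]
        y = np.maximum(z, 0.0)
        return y, {"cols": cols, "z": z, "x_shape": x.shape}

    def backward(self, params: dict, grads: dict, dy: np.ndarray,
                 cache: dict) -> np.ndarray:
        dz = dy * (cache["z"] > 0)
        B, T, KC = cache["cols"].shape
        grads[f"{self.name}/W"] += cache["cols"].reshape(-1, KC).T @ dz.reshape(-1, self.filters)
        grads[f"{self.name}/b"] += dz.sum(axis=(0, 1))
        dcols = dz @ params[f"{self.name}/W"].T
        # col2im: scatter-add back into the padded input
        k, C = self.kernel, self.in_ch
        pad = k // 2
        _, T_in, _ = cache["x_shape"]
        dxp = np.zeros((B, T_in + k - 1, C), dtype=dz.dtype)
        dcols = dcols.reshape(B, T, k, C)
        for d in range(k):
            dxp[:, d : d + T, :] += dcols[:, :, d, :]
        return dxp[:, pad : pad + T_in, :]


# ---------------------------------------------------------------------------
# Masked LSTM (one direction)
# ---------------------------------------------------------------------------

class LSTM:
    """A unidirectional LSTM scan with carry-through masking.

    At masked time steps the cell and hidden state are carried through
    unchanged, so right-padded positions never influence valid steps and the
    final state equals the state at the last valid step.
    """

    def __init__(self, name: str, in_ch: int, hidden: int,
                 params: dict, rng: np.random.Generator) -> None:
        self.name = name
        self.in_ch = in_ch
        self.hidden = hidden
        H = hidden
        params[f"{name}/Wx"] = glorot(rng, in_ch, 4 * H, (in_ch, 4 * H))
        params[f"{name}/Wh"] = glorot(rng, H, 4 * H, (H, 4 * H))
        b = np.zeros(4 * H, dtype=DTYPE)
        b[H : 2 * H] = 1.0  # forget-gate bias init
        params[f"{name}/b"] = b

    def forward(self, params: dict, x: np.ndarray, mask: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, dict]:
        """x: (B,T,C); mask: (B,T) float.  Returns (seq (B,T,H), last (B,H), cache)."""
        B, T, _ = x.shape
        H = self.hidden
        Wx, Wh, b = (params[f"{self.name}/Wx"], params[f"{self.name}/Wh"],
                     params[f"{self.name}/b"])
        xz = x @ Wx  # (B,T,4H) hoisted out of the scan
        dt = x.dtype
        h = np.zeros((B, H), dtype=dt)
        c = np.zeros((B, H), dtype=dt)
        seq = np.zeros((B, T, H), dtype=dt)
        gates = np.zeros((B, T, 4 * H), dtype=dt)
        cs = np.zeros((B, T, H), dtype=dt)       # post-step cell state
        h_prevs = np.zeros((B, T, H), dtype=dt)
        c_prevs = np.zeros((B, T, H), dtype=dt)
        for t in range(T):
            m = mask[:, t][:, None]
            h_prevs[:, t] = h
            c_prevs[:, t] = c
            z = xz[:, t] + h @ Wh + b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            c = m * c_new + (1 - m) * c
            h = m * h_new + (1 - m) * h
            gates[:, t, :H] = i
            gates[:, t, H : 2 * H] = f
            gates[:, t, 2 * H : 3 * H] = g
            gates[:, t, 3 * H :] = o
            cs[:, t] = c_new
            seq[:, t] = h
        cache = {"x": x, "mask": mask, "gates": gates, "cs": cs,
                 "h_prevs": h_prevs, "c_prevs": c_prevs}
        return seq, h, cache

    def backward(self, params: dict, grads: dict, dseq: np.ndarray,
                 dlast: np.ndarray, cache: dict) -> np.ndarray:
        x, mask = cache["x"], cache["mask"]
        B, T, _ = x.shape
        H = self.hidden
        Wx, Wh = params[f"{self.name}/Wx"], params[f"{self.name}/Wh"]
        gates, cs = cache["gates"], cache["cs"]
        h_prevs, c_prevs = cache["h_prevs"], cache["c_prevs"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H, dtype=x.dtype)
        dx = np.zeros_like(x)
        dh = (dlast.astype(x.dtype) if dlast is not None
              else np.zeros((B, H), dtype=x.dtype))
        dc = np.zeros((B, H), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            m = mask[:, t][:, None]
            dh_t = dh + dseq[:, t]
            # carry-through split: masked part flows to h_new, rest to h_prev
            dh_new = m * dh_t
            dh_prev_carry = (1 - m) * dh_t
            dc_new = m * dc
            dc_prev_carry = (1 - m) * dc
            i = gates[:, t, :H]
            f = gates[:, t, H : 2 * H]
            g = gates[:, t, 2 * H : 3 * H]
            o = gates[:, t, 3 * H :]
            tc = np.tanh(cs[:, t])
            do = dh_new * tc
            dc_new = dc_new + dh_new * o * (1 - tc * tc)
            di = dc_new * g
            df = dc_new * c_prevs[:, t]
            dg = dc_new * i
            dc_prev = dc_new * f + dc_prev_carry
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g * g), do * o * (1 - o)], axis=1)
            dWx += x[:, t].T @ dz
            dWh += h_prevs[:, t].T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ Wx.T
            dh = dz @ Wh.T + dh_prev_carry
            dc = dc_prev
        grads[f"{self.name}/Wx"] += dWx
        grads[f"{self.name}/Wh"] += dWh
        grads[f"{self.name}/b"] += db
        return dx


class BiLSTM:
    """Forward and time-reversed LSTM; outputs concatenated per position."""

    def __init__(self, name: str, in_ch: int, hidden: int,
                 params: dict, rng: np.random.Generator) -> None:
        self.fwd = LSTM(f"{name}/fwd", in_ch, hidden, params, rng)
        self.bwd = LSTM(f"{name}/bwd", in_ch, hidden, params, rng)
        self.hidden = hidden

    def forward(self, params: dict, x: np.ndarray, mask: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, dict]:
        seq_f, last_f, cache_f = self.fwd.forward(params, x, mask)
        xr = x[:, ::-1]
        mr = mask[:, ::-1]
        seq_b, last_b, cache_b = self.bwd.forward(params, xr, mr)
        seq = np.concatenate([seq_f, seq_b[:, ::-1]], axis=2)
        last = np.concatenate([last_f, last_b], axis=1)
        return seq, last, {"f": cache_f, "b": cache_b}

    def backward(self, params: dict, grads: dict, dseq, dlast, cache) -> np.ndarray:
        H = self.hidden
        B, T, _ = cache["f"]["x"].shape
        dt = cache["f"]["x"].dtype
        if dseq is None:
            dseq = np.zeros((B, T, 2 * H), dtype=dt)
        if dlast is None:
            dlast = np.zeros((B, 2 * H), dtype=dt)
        dx_f = self.fwd.backward(params, grads, dseq[:, :, :H], dlast[:, :H],
                                 cache["f"])
        dseq_b = dseq[:, ::-1, H:]
        dx_b = self.bwd.backward(params, grads, dseq_b, dlast[:, H:],
                                 cache["b"])
        return dx_f + dx_b[:, ::-1]


# ---------------------------------------------------------------------------
# Dense / dropout / loss
# ---------------------------------------------------------------------------

class Dense:
    def __init__(self, name: str, in_ch: int, out_ch: int, activation: str,
                 params: dict, rng: np.random.Generator) -> None:
        self.name = name
        self.activation = activation
        params[f"{name}/W"] = glorot(rng, in_ch, out_ch, (in_ch, out_ch))
        params[f"{name}/b"] = np.zeros(out_ch, dtype=DTYPE)

    def forward(self, params: dict, x: np.ndarray) -> tuple[np.ndarray, dict]:
        z = x @ params[f"{self.name}/W"] + params[f"{self.name}/b"]
        y = np.maximum(z, 0.0) if self.activation == "relu" else z
        return y, {"x": x, "z": z}

    def backward(self, params: dict, grads: dict, dy: np.ndarray,
                 cache: dict) -> np.ndarray:
        dz = dy * (cache["z"] > 0) if self.activation == "relu" else dy
        grads[f"{self.name}/W"] += cache["x"].T @ dz
        grads[f"{self.name}/b"] += dz.sum(axis=0)
        return dz @ params[f"{self.name}/W"].T


def dropout_forward(x: np.ndarray, rate: float, rng: np.random.Generator,
                    training: bool) -> tuple[np.ndarray, np.ndarray | None]:
    if not training or rate == 0.0:
        return x, None
    keep = ((rng.random(x.shape) >= rate) / (1.0 - rate)).astype(x.dtype)
    return x * keep, keep


def dropout_backward(dy: np.ndarray, keep: np.ndarray | None) -> np.ndarray:
    return dy if keep is None else dy * keep


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray
                 ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. logits.  labels: int (B,)."""
    p = softmax(logits)
    B = logits.shape[0]
    loss = -float(np.mean(np.log(p[np.arange(B), labels] + 1e-300)))
    dlogits = p.copy()
    dlogits[np.arange(B), labels] -= 1.0
    return loss, dlogits / B


class Adam:
    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
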