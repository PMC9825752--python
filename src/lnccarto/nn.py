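"""Minimal numpy neural-network layers with explicit backward passes.

This module provides exactly the operations the three sequence-classifier
architectures need: dense layers, valid-mode 1-D convolution (im2col +
GEMM), non-overlapping max pooling, masked global max/average pooling, an
LSTM (with bidirectional wrapper), single-head scaled dot-product
self-attention, layer normalization, inverted dropout, sinusoidal positional
encodings, a class-weighted softmax cross-entropy and an Adam optimizer.

All sequence operations take a ``lengths`` vector and guarantee that padded
positions neither influence valid outputs nor receive gradient.  Every
``*_fwd`` returns ``(output, cache)`` and the matching ``*_bwd`` consumes
the upstream gradient plus that cache.  float32 is the working precision;
the layers follow the dtype of their inputs, which the finite-difference
gradient checks exploit by running in float64.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

_NEG = -1e30  # effectively -inf, safe in float32 arithmetic


def glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out, dtype=DTYPE):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def length_mask(lengths: np.ndarray, L: int) -> np.ndarray:
    """Boolean (B, L) mask, True at valid positions."""
    return np.arange(L)[None, :] < np.asarray(lengths)[:, None]


# ---------------------------------------------------------------------------
# dense / relu / dropout

def dense_fwd(x, W, b):
    return x @ W + b, (x, W)


def dense_bwd(dout, cache):
    x, W = cache
    dx = dout @ W.T
    shp = (-1, x.shape[-1])
    dW = x.reshape(shp).T @ dout.reshape(-1, W.shape[1])
    db = dout.reshape(-1, W.shape[1]).sum(axis=0)
    return dx, dW, db


def relu_fwd(x, inplace: bool = False):
    out = np.maximum(x, 0, out=x) if inplace else np.maximum(x, 0)
    return out, out


def relu_bwd(dout, out):
    return dout * (out > 0)


def dropout_fwd(x, rate: float, rng: np.random.Generator, train: bool):
    if not train or rate <= 0.0:
        return x, None
    keep = (rng.random(x.shape) >= rate).astype(x.dtype) / (1.0 - rate)
    return x * keep, keep


def dropout_bwd(dout, keep):
    if keep is None:
        return dout
    return dout * keep


# ---------------------------------------------------------------------------
# 1-D convolution (valid mode) via im2col + GEMM

def conv1d_fwd(x, W, b):
    """x: (B, L, C); W: (K, C, F); returns (B, L-K+1, F).

    Implemented as K shifted full-length GEMMs (one per kernel offset),
    which avoids materializing an im2col matrix; the few positions computed
    past each sample's valid range are masked by the next pooling op.
    Padded input positions must be zero.
    """
    B, L, C = x.shape
    K, _, F = W.shape
    Lout = L - K + 1
    x2 = x.reshape(B * L, C)
    tmp = np.empty((B * L, F), dtype=x.dtype)
    np.matmul(x2, W[0], out=tmp)
    out = tmp.reshape(B, L, F)[:, :Lout].copy()
    for j in range(1, K):
        np.matmul(x2, W[j], out=tmp)
        out += tmp.reshape(B, L, F)[:, j : j + Lout]
    out += b
    return out, (x, W)


def conv1d_bwd(dout, cache):
    x, W = cache
    B, L, C = x.shape
    K, _, F = W.shape
    Lout = L - K + 1
    x2 = x.reshape(B * L, C)
    dW = np.empty_like(W)
    db = dout.sum(axis=(0, 1))
    dfull = np.zeros((B, L, F), dtype=dout.dtype)
    d2 = dfull.reshape(B * L, F)
    dx = np.zeros((B * L, C), dtype=dout.dtype)
    tmp = np.empty((B * L, C), dtype=dout.dtype)
    for j in range(K):
        dfull[:] = 0.0
        dfull[:, j : j + Lout] = dout
        np.matmul(x2.T, d2, out=dW[j])
        np.matmul(d2, W[j].T, out=tmp)
        dx += tmp
    return dx.reshape(B, L, C), dW, db


def conv_out_lengths(lengths, K):
    return np.maximum(np.asarray(lengths) - (K - 1), 0)


# ---------------------------------------------------------------------------
# pooling

def maxpool_fwd(x, lengths, size: int, want_grad: bool = True):
    """Non-overlapping max pooling over time with per-sample lengths.

    Output length per sample is ``lengths // size``; invalid output
    positions are zeroed.  Because windows never straddle a sample's valid
    boundary (``(lengths // size) * size <= lengths``), valid outputs only
    ever see valid inputs and no masking of the input is needed.  Returns
    (out, new_lengths, cache); with ``want_grad=False`` (inference) the
    argmax bookkeeping for the backward pass is skipped.
    """
    from ._kernels import maxpool_pass

    B, L, F = x.shape
    Lp = L // size
    new_lengths = np.asarray(lengths) // size
    out, am = maxpool_pass(x, size, want_grad)
    out_invalid = ~length_mask(new_lengths, Lp)
    out[out_invalid] = 0.0
    if not want_grad:
        return out, new_lengths, None
    return out, new_lengths, (am, x.shape, size, out_invalid)


def maxpool_bwd(dout, cache):
    am, xshape, size, out_invalid = cache
    B, L, F = xshape
    Lp = L // size
    from ._kernels import maxpool_scatter

    d = dout.copy()
    d[out_invalid] = 0.0
    dx = maxpool_scatter(am, d, size, L)
    if dx.shape != xshape:  # L was trimmed to a multiple of size
        full = np.zeros(xshape, dtype=dout.dtype)
        full[:, : dx.shape[1]] = dx
        dx = full
    return dx


def global_maxpool_fwd(x, lengths):
    """Masked global max over time: (B, L, F) -> (B, F)."""
    B, L, F = x.shape
    xm = x.copy()
    xm[~length_mask(lengths, L)] = _NEG
    am = xm.argmax(axis=1)
    out = np.take_along_axis(xm, am[:, None, :], axis=1)[:, 0, :]
    return out, (am, x.shape)


def global_maxpool_bwd(dout, cache):
    am, xshape = cache
    dx = np.zeros(xshape, dtype=dout.dtype)
    np.put_along_axis(dx, am[:, None, :], dout[:, None, :], axis=1)
    return dx


def global_avgpool_fwd(x, lengths):
    """Masked global mean over time: (B, L, F) -> (B, F)."""
    B, L, F = x.shape
    mask = length_mask(lengths, L).astype(x.dtype)
    denom = np.maximum(np.asarray(lengths), 1).astype(x.dtype)
    out = (x * mask[:, :, None]).sum(axis=1) / denom[:, None]
    return out, (mask, denom, x.shape)


def global_avgpool_bwd(dout, cache):
    mask, denom, xshape = cache
    dx = (dout / denom[:, None])[:, None, :] * mask[:, :, None]
    return dx.astype(dout.dtype)


# ---------------------------------------------------------------------------
# LSTM

def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def lstm_fwd(x, lengths, Wx, Wh, b):
    """Unidirectional LSTM returning the final valid hidden state.

    x: (B, T, C); Wx: (C, 4H); Wh: (H, 4H); b: (4H,).  Gate layout along the
    last axis is [input, forget, candidate, output].  Returns
    (h_last (B, H), cache).
    """
    B, T, C = x.shape
    H = Wh.shape[0]
    dt = x.dtype
    h = np.zeros((B, H), dtype=dt)
    c = np.zeros((B, H), dtype=dt)
    states = []
    hs = np.zeros((T, B, H), dtype=dt)
    cs = np.zeros((T, B, H), dtype=dt)
    for t in range(T):
        z = x[:, t] @ Wx + h @ Wh + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_prev = c
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        states.append((i, f, g, o, c_prev, tc))
        hs[t] = h
        cs[t] = c
    last = np.maximum(np.asarray(lengths), 1) - 1
    h_last = hs[last, np.arange(B)]
    return h_last, (x, lengths, Wx, Wh, states, hs, last)


def lstm_bwd(dh_last, cache):
    x, lengths, Wx, Wh, states, hs, last = cache
    B, T, C = x.shape
    H = Wh.shape[0]
    dt = x.dtype
    dx = np.zeros_like(x)
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H, dtype=dt)
    dh = np.zeros((B, H), dtype=dt)
    dc = np.zeros((B, H), dtype=dt)
    for t in range(T - 1, -1, -1):
        inject = (last == t)[:, None]
        dh = dh + np.where(inject, dh_last, 0.0)
        i, f, g, o, c_prev, tc = states[t]
        do = dh * tc
        dct = dc + dh * o * (1.0 - tc * tc)
        di = dct * g
        df = dct * c_prev
        dg = dct * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        h_prev = hs[t - 1] if t > 0 else np.zeros((B, H), dtype=dt)
        dWx += x[:, t].T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx[:, t] = dz @ Wx.T
        dh = dz @ Wh.T
        dc = dct * f
    return dx, dWx, dWh, db


def reverse_padded(x, lengths):
    """Reverse each sample's valid prefix in time, leaving padding in place."""
    out = x.copy()
    for b, n in enumerate(np.asarray(lengths)):
        n = int(n)
        out[b, :n] = x[b, :n][::-1]
    return out


# ---------------------------------------------------------------------------
# single-head self-attention, layer norm, positional encoding

def softmax(z, axis=-1, inplace=False):
    """Numerically safe softmax.

    Shifted scores are clamped at -80 before exponentiation: exp of very
    negative values (e.g. masked attention scores) would underflow into
    subnormals, which is both pointless and extremely slow on most FPUs.
    """
    out = z if inplace else np.array(z)
    out -= out.max(axis=axis, keepdims=True)
    np.clip(out, -80.0, None, out=out)
    np.exp(out, out=out)
    out /= out.sum(axis=axis, keepdims=True)
    return out


def attention_fwd(x, lengths, Wq, bq, Wk, bk, Wv, bv, Wo, bo):
    """Single-head scaled dot-product self-attention over valid positions.

    x: (B, L, D).  Attention is computed per sample over its valid prefix
    only (padded positions are neither queries nor keys; their context rows
    are zero), which both masks padding exactly and keeps every temporary
    at O(n^2) for one sample -- large batched (B, L, L) score tensors are
    deliberately avoided, and the attention probabilities are recomputed in
    the backward pass rather than cached.
    """
    B, L, D = x.shape
    q = x @ Wq + bq
    k = x @ Wk + bk
    v = x @ Wv + bv
    scale = 1.0 / np.sqrt(D)
    ctx = np.zeros_like(q)
    for b in range(B):
        n = int(lengths[b])
        s = (q[b, :n] @ k[b, :n].T) * scale
        p = softmax(s, axis=1, inplace=True)
        ctx[b, :n] = p @ v[b, :n]
    out = ctx @ Wo + bo
    return out, (x, q, k, v, ctx, lengths, Wq, Wk, Wv, Wo, scale)


def attention_bwd(dout, cache):
    x, q, k, v, ctx, lengths, Wq, Wk, Wv, Wo, scale = cache
    B, L, D = x.shape
    dctx = dout @ Wo.T
    dWo = ctx.reshape(-1, D).T @ dout.reshape(-1, D)
    dbo = dout.reshape(-1, D).sum(axis=0)
    dq = np.zeros_like(q)
    dk = np.zeros_like(k)
    dv = np.zeros_like(v)
    for b in range(B):
        n = int(lengths[b])
        qb, kb, vb = q[b, :n], k[b, :n], v[b, :n]
        s = (qb @ kb.T) * scale
        p = softmax(s, axis=1, inplace=True)
        dcb = dctx[b, :n]
        dp = dcb @ vb.T
        dv[b, :n] = p.T @ dcb
        rowsum = (dp * p).sum(axis=1)
        dp -= rowsum[:, None]
        dp *= p  # now the score gradient
        dq[b, :n] = (dp @ kb) * scale
        dk[b, :n] = (dp.T @ qb) * scale
    dx = dq @ Wq.T + dk @ Wk.T + dv @ Wv.T
    x2 = x.reshape(-1, D)
    dWq = x2.T @ dq.reshape(-1, D)
    dWk = x2.T @ dk.reshape(-1, D)
    dWv = x2.T @ dv.reshape(-1, D)
    dbq = dq.reshape(-1, D).sum(axis=0)
    dbk = dk.reshape(-1, D).sum(axis=0)
    dbv = dv.reshape(-1, D).sum(axis=0)
    return dx, dWq, dbq, dWk, dbk, dWv, dbv, dWo, dbo


def layernorm_fwd(x, gamma, beta, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    return xhat * gamma + beta, (xhat, inv, gamma)


def layernorm_bwd(dout, cache):
    xhat, inv, gamma = cache
    D = xhat.shape[-1]
    dgamma = (dout * xhat).reshape(-1, D).sum(axis=0)
    dbeta = dout.reshape(-1, D).sum(axis=0)
    dxhat = dout * gamma
    dx = inv * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    return dx.astype(dout.dtype), dgamma, dbeta


def positional_encoding(L: int, D: int, dtype=DTYPE) -> np.ndarray:
    """Fixed sinusoidal positional encodings, (L, D)."""
    pos = np.arange(L)[:, None].astype(np.float64)
    i = np.arange(D)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / D)
    pe = np.empty((L, D))
    pe[:, 0::2] = np.sin(angle[:, 0::2])
    pe[:, 1::2] = np.cos(angle[:, 1::2])
    return pe.astype(dtype)


# ---------------------------------------------------------------------------
# loss and optimizer

def softmax_xent_fwd(logits, y, sample_w):
    """Class-weighted 2-class cross-entropy (weighted mean over the batch).

    Returns (loss, probs, dlogits).  With all weights equal to 1 this is the
    plain mean cross-entropy.
    """
    p = softmax(logits.astype(np.float64), axis=1)
    B = logits.shape[0]
    w = np.asarray(sample_w, dtype=np.float64)
    wsum = w.sum()
    py = p[np.arange(B), y]
    loss = float((w * -np.log(np.maximum(py, 1e-300))).sum() / wsum)
    dlog = p.copy()
    dlog[np.arange(B), y] -= 1.0
    dlog *= (w / wsum)[:, None]
    return loss, p, dlog.astype(logits.dtype)


class Adam:
    """Adam optimizer over a flat dict of named parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            if g is None:
                continue
            p = self.params[k]
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * (g * g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
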