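"""Vectorised float32 forward/backward passes for adversarial training.

This module is the numerical workhorse behind :mod:`molcycle.training`.
Parameters live in flat dicts with GEMM-friendly layouts (weights stored
as (input, output); the four LSTM gates fused into one matrix in f/i/C/o
order).  The input half of every LSTM gate pre-activation is computed for
all time steps in a single large GEMM; only the recurrent half runs inside
the time loop.  Weight gradients are likewise accumulated with one large
GEMM over all (batch x time) rows.

Correctness is established by tests comparing these passes against the
plain reference implementations in :mod:`molcycle.networks` and against
finite-difference gradients.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from . import LATENT_DIM
from . import _kernels
from .networks import (
    BN_EPS,
    BN_MOMENTUM,
    DiscriminatorParams,
    GeneratorParams,
)

F32 = np.float32


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Buffer pool
#
# The training loop churns through ~40 MB of sequence caches per batch;
# recycling them avoids repeated page-fault costs.  Buffers are acquired in
# a forward pass, carried inside its cache, and released exactly once by
# the matching backward pass.  Contents are never assumed zeroed.

_POOL: Dict[tuple, list] = {}


def _acquire(shape: tuple) -> np.ndarray:
    free = _POOL.get((shape, np.dtype(F32).str))
    if free:
        return free.pop()
    return np.empty(shape, F32)


def _release(*arrays: np.ndarray) -> None:
    for a in arrays:
        _POOL.setdefault((a.shape, a.dtype.str), []).append(a)


def clear_pool() -> None:
    _POOL.clear()


# ---------------------------------------------------------------------------
# Layout conversion


def gen_to_engine(p: GeneratorParams) -> Dict[str, np.ndarray]:
    d: Dict[str, np.ndarray] = {
        "headW": p.head_W.T,
        "headb": p.head_b,
        "gamma": p.bn.gamma,
        "beta": p.bn.beta,
        "rmean": p.bn.running_mean,
        "rvar": p.bn.running_var,
        "fusW": p.fusion_W.T,
        "fusb": p.fusion_b,
        "attQ": p.attention.query_proj,
        "attK": p.attention.key_proj,
        "attV": p.attention.value_proj,
    }
    for name, lp in (("l1", p.lstm1), ("l2", p.lstm2), ("l3", p.lstm3)):
        H = lp.hidden
        Wh = np.concatenate(
            [lp.W_f[:, :H].T, lp.W_i[:, :H].T, lp.W_C[:, :H].T, lp.W_o[:, :H].T], axis=1
        )
        Wx = np.concatenate(
            [lp.W_f[:, H:].T, lp.W_i[:, H:].T, lp.W_C[:, H:].T, lp.W_o[:, H:].T], axis=1
        )
        b = np.concatenate([lp.b_f, lp.b_i, lp.b_C, lp.b_o])
        d[f"{name}_Wh"] = Wh
        d[f"{name}_Wx"] = Wx
        d[f"{name}_b"] = b
    return {k: np.ascontiguousarray(v, dtype=F32) for k, v in d.items()}


def engine_to_gen(d: Dict[str, np.ndarray], p: GeneratorParams) -> None:
    p.head_W = d["headW"].T.astype(np.float64)
    p.head_b = d["headb"].astype(np.float64)
    p.bn.gamma = d["gamma"].astype(np.float64)
    p.bn.beta = d["beta"].astype(np.float64)
    p.bn.running_mean = d["rmean"].astype(np.float64)
    p.bn.running_var = d["rvar"].astype(np.float64)
    p.fusion_W = d["fusW"].T.astype(np.float64)
    p.fusion_b = d["fusb"].astype(np.float64)
    p.attention.query_proj = d["attQ"].astype(np.float64)
    p.attention.key_proj = d["attK"].astype(np.float64)
    p.attention.value_proj = d["attV"].astype(np.float64)
    for name, lp in (("l1", p.lstm1), ("l2", p.lstm2), ("l3", p.lstm3)):
        H = lp.hidden
        Wh = d[f"{name}_Wh"].astype(np.float64)
        Wx = d[f"{name}_Wx"].astype(np.float64)
        b = d[f"{name}_b"].astype(np.float64)
        for g, (wname, bname) in enumerate(
            (("W_f", "b_f"), ("W_i", "b_i"), ("W_C", "b_C"), ("W_o", "b_o"))
        ):
            W = np.concatenate(
                [Wh[:, g * H : (g + 1) * H].T, Wx[:, g * H : (g + 1) * H].T], axis=1
            )
            setattr(lp, wname, W)
            setattr(lp, bname, b[g * H : (g + 1) * H].copy())


def disc_to_engine(p: DiscriminatorParams) -> Dict[str, np.ndarray]:
    d = {
        "d1W": p.dense1_W.T,
        "d1b": p.dense1_b,
        "d2W": p.dense2_W.T,
        "d2b": p.dense2_b,
        "d3W": p.dense3_W.T,
        "d3b": p.dense3_b,
        "attQ": p.attention.query_proj,
        "attK": p.attention.key_proj,
        "attV": p.attention.value_proj,
        "outW": p.out_W.T,
        "outb": p.out_b,
    }
    out = {k: np.ascontiguousarray(v, dtype=F32) for k, v in d.items()}
    out["final_sigmoid"] = p.final_sigmoid  # type: ignore[assignment]
    return out


def engine_to_disc(d: Dict[str, np.ndarray], p: DiscriminatorParams) -> None:
    p.dense1_W = d["d1W"].T.astype(np.float64)
    p.dense1_b = d["d1b"].astype(np.float64)
    p.dense2_W = d["d2W"].T.astype(np.float64)
    p.dense2_b = d["d2b"].astype(np.float64)
    p.dense3_W = d["d3W"].T.astype(np.float64)
    p.dense3_b = d["d3b"].astype(np.float64)
    p.attention.query_proj = d["attQ"].astype(np.float64)
    p.attention.key_proj = d["attK"].astype(np.float64)
    p.attention.value_proj = d["attV"].astype(np.float64)
    p.out_W = d["outW"].T.astype(np.float64)
    p.out_b = d["outb"].astype(np.float64)


# ---------------------------------------------------------------------------
# LSTM layer


def lstm_forward(X: np.ndarray, Wx, Wh, b) -> Tuple[np.ndarray, tuple]:
    # In-place ufuncs and a single fused sigmoid over all four gate blocks
    # keep the sequential time loop close to GEMM-bound.
    B, T, In = X.shape
    H = Wh.shape[0]
    preX = _acquire((B, T, 4 * H))
    np.dot(X.reshape(B * T, In), Wx, out=preX.reshape(B * T, 4 * H))
    preX += b
    Fg = _acquire((B, T, H))
    Ig = _acquire((B, T, H))
    Cb = _acquire((B, T, H))
    Og = _acquire((B, T, H))
    Cs = _acquire((B, T, H))
    TC = _acquire((B, T, H))
    Hs = _acquire((B, T, H))
    g = np.empty((B, 4 * H), F32)
    zc = np.empty((B, H), F32)
    tmp = np.empty((B, H), F32)
    h = np.zeros((B, H), F32)
    c = np.zeros((B, H), F32)
    for t in range(T):
        np.dot(h, Wh, out=g)
        g += preX[:, t]
        zc[...] = g[:, 2 * H : 3 * H]  # pre-activation of the cell candidate
        np.negative(g, out=g)
        np.exp(g, out=g)
        g += F32(1.0)
        np.reciprocal(g, out=g)  # sigmoid of every gate block
        f = g[:, :H]
        i = g[:, H : 2 * H]
        o = g[:, 3 * H :]
        cb = np.tanh(zc, out=zc)
        np.multiply(f, c, out=c)
        np.multiply(i, cb, out=tmp)
        c += tmp
        tc = np.tanh(c, out=tmp)
        np.multiply(o, tc, out=h)
        Fg[:, t] = f
        Ig[:, t] = i
        Cb[:, t] = cb
        Og[:, t] = o
        Cs[:, t] = c
        TC[:, t] = tc
        Hs[:, t] = h
    _release(preX)
    return Hs, (X, Fg, Ig, Cb, Og, Cs, TC, Hs)


def lstm_backward(dH: np.ndarray, cache: tuple, Wx, Wh):
    X, Fg, Ig, Cb, Og, Cs, TC, Hs = cache
    B, T, In = X.shape
    H = Wh.shape[0]
    dG = _acquire((B, T, 4 * H))
    if _kernels.HAVE_NUMBA and F32 is np.float32:
        dHc = np.ascontiguousarray(dH, dtype=F32)
        WhT = np.ascontiguousarray(Wh.T)
        _kernels.lstm_loop_bwd(dHc, Fg, Ig, Cb, Og, Cs, TC, WhT, dG)
    else:
        dh = np.zeros((B, H), F32)
        dc = np.zeros((B, H), F32)
        for t in range(T - 1, -1, -1):
            dht = dH[:, t] + dh
            f, i, cb, o = Fg[:, t], Ig[:, t], Cb[:, t], Og[:, t]
            tc = TC[:, t]
            c_prev = Cs[:, t - 1] if t > 0 else 0.0
            do = dht * tc
            dc = dc + dht * o * (1.0 - tc * tc)
            dG[:, t, :H] = (dc * c_prev) * f * (1.0 - f) if t > 0 else 0.0
            dG[:, t, H : 2 * H] = (dc * cb) * i * (1.0 - i)
            dG[:, t, 2 * H : 3 * H] = (dc * i) * (1.0 - cb * cb)
            dG[:, t, 3 * H :] = do * o * (1.0 - o)
            dh = dG[:, t] @ Wh.T
            dc = dc * f
    dG2 = dG.reshape(B * T, 4 * H)
    dWx = X.reshape(B * T, In).T @ dG2
    Hprev = _acquire((B, T, H))
    Hprev[:, 0] = 0.0
    Hprev[:, 1:] = Hs[:, :-1]
    dWh = Hprev.reshape(B * T, H).T @ dG2
    db = dG2.sum(axis=0)
    dX = _acquire((B, T, In))
    np.dot(dG2, Wx.T, out=dX.reshape(B * T, In))
    _release(dG, Hprev, Fg, Ig, Cb, Og, Cs, TC, Hs)
    return dX, dWx, dWh, db


# ---------------------------------------------------------------------------
# Attention (batched, width-1 context)


def attention_forward(seq: np.ndarray, Q, K, V) -> Tuple[np.ndarray, tuple]:
    # seq: (B, T, iw)
    B, T, iw = seq.shape
    d = Q.shape[1]
    q = seq[:, -1, :] @ Q  # (B, d)
    Ks = _acquire((B, T, d))
    np.dot(seq.reshape(B * T, iw), K, out=Ks.reshape(B * T, d))
    s = np.einsum("btk,bk->bt", Ks, q) / np.sqrt(F32(d))
    s -= s.max(axis=1, keepdims=True)
    w = np.exp(s)
    w /= w.sum(axis=1, keepdims=True)
    v = (seq @ V)[..., 0]  # (B, T)
    ctx = np.sum(w * v, axis=1, keepdims=True)  # (B, 1)
    return ctx, (seq, q, Ks, w, v)


def attention_backward(dctx: np.ndarray, cache: tuple, Q, K, V):
    seq, q, Ks, w, v = cache
    B, T, iw = seq.shape
    d = Q.shape[1]
    scale = F32(1.0 / np.sqrt(d))
    dw = dctx * v  # (B, T)
    dv = dctx * w  # (B, T)
    seq2 = seq.reshape(B * T, iw)
    dV = seq2.T @ dv.reshape(B * T, 1)
    dseq = _acquire((B, T, iw))
    np.multiply(dv[:, :, None], V[:, 0][None, None, :], out=dseq)
    # softmax backward
    ds = w * (dw - np.sum(dw * w, axis=1, keepdims=True))  # (B, T)
    dq = np.einsum("bt,btk->bk", ds, Ks) * scale  # (B, d)
    dKs = ds[:, :, None] * (q[:, None, :] * scale)  # (B, T, d)
    dQ = seq[:, -1, :].T @ dq
    dK = seq2.T @ dKs.reshape(B * T, d)
    dseq += dKs @ K.T
    dlast = dq @ Q.T  # (B, iw)
    dseq[:, -1, :] += dlast
    _release(Ks)
    return dseq, dQ, dK, dV


# ---------------------------------------------------------------------------
# Generator


def gen_forward(
    p: Dict[str, np.ndarray],
    Z: np.ndarray,
    training: bool = True,
    split: int | None = None,
):
    """Generator forward with cache.

    ``split`` marks a boundary between two independently batch-normalised
    sub-batches, so two logical forward passes can share one physical pass
    (all layers after the head treat samples independently).
    """
    Z = np.ascontiguousarray(Z, dtype=F32)
    a = Z @ p["headW"] + p["headb"]
    segments = [(0, a.shape[0])] if split is None else [(0, split), (split, a.shape[0])]
    if training:
        xhat = np.empty_like(a)
        istd = np.empty((len(segments), a.shape[1]), dtype=a.dtype)
        for si, (lo, hi) in enumerate(segments):
            mu = a[lo:hi].mean(axis=0)
            var = a[lo:hi].var(axis=0)
            p["rmean"] = (BN_MOMENTUM * p["rmean"] + (1 - BN_MOMENTUM) * mu).astype(F32)
            p["rvar"] = (BN_MOMENTUM * p["rvar"] + (1 - BN_MOMENTUM) * var).astype(F32)
            istd[si] = 1.0 / np.sqrt(var + F32(BN_EPS))
            xhat[lo:hi] = (a[lo:hi] - mu) * istd[si]
    else:
        istd = (1.0 / np.sqrt(p["rvar"] + F32(BN_EPS)))[None, :]
        xhat = (a - p["rmean"]) * istd[0]
    bnout = p["gamma"] * xhat + p["beta"]
    head = np.maximum(bnout, 0.0)

    seq1 = head[:, :, None]
    o1, c1 = lstm_forward(seq1, p["l1_Wx"], p["l1_Wh"], p["l1_b"])
    o2, c2 = lstm_forward(o1, p["l2_Wx"], p["l2_Wh"], p["l2_b"])
    o3, c3 = lstm_forward(o2, p["l3_Wx"], p["l3_Wh"], p["l3_b"])
    ctx, catt = attention_forward(o3, p["attQ"], p["attK"], p["attV"])
    fused = np.concatenate([head, ctx], axis=1)  # (B, 57)
    out = fused @ p["fusW"] + p["fusb"]
    cache = (Z, xhat, istd, bnout, head, c1, c2, c3, catt, fused, segments)
    return out, cache


def gen_backward(p: Dict[str, np.ndarray], cache, dOut: np.ndarray):
    Z, xhat, istd, bnout, head, c1, c2, c3, catt, fused, segments = cache
    B = Z.shape[0]
    g: Dict[str, np.ndarray] = {}
    g["fusW"] = fused.T @ dOut
    g["fusb"] = dOut.sum(axis=0)
    dfused = dOut @ p["fusW"].T
    dhead = dfused[:, :LATENT_DIM].copy()
    dctx = dfused[:, LATENT_DIM:]

    do3, g["attQ"], g["attK"], g["attV"] = attention_backward(
        dctx, catt, p["attQ"], p["attK"], p["attV"]
    )
    do2, g["l3_Wx"], g["l3_Wh"], g["l3_b"] = lstm_backward(
        do3, c3, p["l3_Wx"], p["l3_Wh"]
    )
    _release(do3)
    do1, g["l2_Wx"], g["l2_Wh"], g["l2_b"] = lstm_backward(
        do2, c2, p["l2_Wx"], p["l2_Wh"]
    )
    _release(do2)
    dseq1, g["l1_Wx"], g["l1_Wh"], g["l1_b"] = lstm_backward(
        do1, c1, p["l1_Wx"], p["l1_Wh"]
    )
    _release(do1)
    dhead += dseq1[:, :, 0]
    _release(dseq1)

    dbn = dhead * (bnout > 0)
    g["gamma"] = (dbn * xhat).sum(axis=0)
    g["beta"] = dbn.sum(axis=0)
    dxhat = dbn * p["gamma"]
    dx = np.empty_like(dxhat)
    for si, (lo, hi) in enumerate(segments):
        dxh = dxhat[lo:hi]
        xh = xhat[lo:hi]
        dx[lo:hi] = istd[si] * (
            dxh - dxh.mean(axis=0) - xh * (dxh * xh).mean(axis=0)
        )
    g["headW"] = Z.T @ dx
    g["headb"] = dx.sum(axis=0)
    dZ = dx @ p["headW"].T
    return g, dZ


# ---------------------------------------------------------------------------
# Discriminator


def disc_forward(p: Dict[str, np.ndarray], Z: np.ndarray):
    Z = np.ascontiguousarray(Z, dtype=F32)
    a1 = Z @ p["d1W"] + p["d1b"]
    h1 = np.maximum(a1, 0.0)
    a2 = h1 @ p["d2W"] + p["d2b"]
    h2 = np.maximum(a2, 0.0)
    a3 = h2 @ p["d3W"] + p["d3b"]
    h3 = np.maximum(a3, 0.0)
    seq = h3[:, :, None]
    ctx, catt = attention_forward(seq, p["attQ"], p["attK"], p["attV"])
    if p["final_sigmoid"]:
        sg = _sigmoid(ctx)
    else:
        sg = ctx
    score = (sg @ p["outW"] + p["outb"])[:, 0]
    cache = (Z, a1, h1, a2, h2, a3, h3, catt, ctx, sg)
    return score, cache


def disc_backward(p: Dict[str, np.ndarray], cache, dscore: np.ndarray):
    Z, a1, h1, a2, h2, a3, h3, catt, ctx, sg = cache
    ds = dscore[:, None].astype(F32)
    g: Dict[str, np.ndarray] = {}
    g["outW"] = sg.T @ ds
    g["outb"] = ds.sum(axis=0)
    dsg = ds @ p["outW"].T
    if p["final_sigmoid"]:
        dctx = dsg * sg * (1.0 - sg)
    else:
        dctx = dsg
    dseq, g["attQ"], g["attK"], g["attV"] = attention_backward(
        dctx, catt, p["attQ"], p["attK"], p["attV"]
    )
    dh3 = dseq[:, :, 0] * (a3 > 0)
    _release(dseq)
    g["d3W"] = h2.T @ dh3
    g["d3b"] = dh3.sum(axis=0)
    dh2 = (dh3 @ p["d3W"].T) * (a2 > 0)
    g["d2W"] = h1.T @ dh2
    g["d2b"] = dh2.sum(axis=0)
    dh1 = (dh2 @ p["d2W"].T) * (a1 > 0)
    g["d1W"] = Z.T @ dh1
    g["d1b"] = dh1.sum(axis=0)
    dZ = dh1 @ p["d1W"].T
    return g, dZ


# ---------------------------------------------------------------------------
# Adam


class Adam:
    def __init__(self, lr: float, beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = F32(lr)
        self.beta1 = F32(beta1)
        self.beta2 = F32(beta2)
        self.eps = F32(eps)
        self.t = 0
        self.m: Dict[str, np.ndarray] = {}
        self.v: Dict[str, np.ndarray] = {}

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = F32(1.0 - float(self.beta1) ** self.t)
        b2t = F32(1.0 - float(self.beta2) ** self.t)
        for k, gk in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1 - self.beta1) * gk
            v *= self.beta2
            v += (1 - self.beta2) * gk * gk
            params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
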