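"""Generator and discriminator forward computations.

Layer widths (generator / discriminator)::

    generator:      Input 56 -> Dense 56 (+BN, ReLU) -> LSTM 56 -> LSTM 28
                    -> LSTM 56 -> Attention (56 steps, key width 64, value
                    width 1) -> concatenate head+tail (57) -> Dense 56
    discriminator:  Input 56 -> Dense 56 -> Dense 28 -> Dense 56
                    -> Attention (56 scalar steps) -> Sigmoid -> Dense 1

A width-56 vector entering an LSTM stack is unrolled as a 56-step sequence
of one scalar per step; every LSTM returns its full output sequence so the
attention layer sees 56 positions.  The "head" of the fusion is the output
of the first dense layer; the "tail" is the width-1 attention summary.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from . import LATENT_DIM

KEY_WIDTH = 64
BN_EPS = 1e-5
BN_MOMENTUM = 0.9  # running <- momentum*running + (1-momentum)*batch


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass
class LSTMParams:
    """Gate weights, each of shape (hidden, hidden + input)."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_C: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_C: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.W_f.shape, self.W_i.shape, self.W_C.shape, self.W_o.shape}
        if len(shapes) != 1:
            raise ValueError("all four gate weight matrices must share a shape")
        h = self.W_f.shape[0]
        for b in (self.b_f, self.b_i, self.b_C, self.b_o):
            if b.shape != (h,):
                raise ValueError("bias length must equal hidden width")

    @property
    def hidden(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_width(self) -> int:
        return self.W_f.shape[1] - self.W_f.shape[0]


@dataclass
class AttentionParams:
    query_proj: np.ndarray  # (input_width, 64)
    key_proj: np.ndarray  # (input_width, 64)
    value_proj: np.ndarray  # (input_width, 1)
    key_width: int = KEY_WIDTH

    def __post_init__(self) -> None:
        iw = self.query_proj.shape[0]
        if self.query_proj.shape != (iw, self.key_width):
            raise ValueError("query projection must be (input_width, key_width)")
        if self.key_proj.shape != (iw, self.key_width):
            raise ValueError("key projection must be (input_width, key_width)")
        if self.value_proj.shape != (iw, 1):
            raise ValueError("value projection must be (input_width, 1)")

    @property
    def input_width(self) -> int:
        return self.query_proj.shape[0]


@dataclass
class BatchNormParams:
    gamma: np.ndarray
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray


@dataclass
class GeneratorParams:
    head_W: np.ndarray  # (56, 56)
    head_b: np.ndarray
    bn: BatchNormParams
    lstm1: LSTMParams  # input 1,  hidden 56
    lstm2: LSTMParams  # input 56, hidden 28
    lstm3: LSTMParams  # input 28, hidden 56
    attention: AttentionParams  # input width 56
    fusion_W: np.ndarray  # (56, 57)
    fusion_b: np.ndarray


@dataclass
class DiscriminatorParams:
    dense1_W: np.ndarray  # (56, 56)
    dense1_b: np.ndarray
    dense2_W: np.ndarray  # (28, 56)
    dense2_b: np.ndarray
    dense3_W: np.ndarray  # (56, 28)
    dense3_b: np.ndarray
    attention: AttentionParams  # input width 1
    out_W: np.ndarray  # (1, 1)
    out_b: np.ndarray
    final_sigmoid: bool = True  # printed design: sigmoid before the last dense


# ---------------------------------------------------------------------------
# Initialisation (seeded Gaussian sd 0.02, zero biases)


def _gauss(rng: np.random.Generator, shape: Tuple[int, ...]) -> np.ndarray:
    return 0.02 * rng.standard_normal(shape)


def init_lstm(rng: np.random.Generator, hidden: int, input_width: int) -> LSTMParams:
    cols = hidden + input_width
    return LSTMParams(
        W_f=_gauss(rng, (hidden, cols)),
        W_i=_gauss(rng, (hidden, cols)),
        W_C=_gauss(rng, (hidden, cols)),
        W_o=_gauss(rng, (hidden, cols)),
        b_f=np.zeros(hidden),
        b_i=np.zeros(hidden),
        b_C=np.zeros(hidden),
        b_o=np.zeros(hidden),
    )


def init_attention(rng: np.random.Generator, input_width: int) -> AttentionParams:
    return AttentionParams(
        query_proj=_gauss(rng, (input_width, KEY_WIDTH)),
        key_proj=_gauss(rng, (input_width, KEY_WIDTH)),
        value_proj=_gauss(rng, (input_width, 1)),
    )


def init_generator(rng: np.random.Generator) -> GeneratorParams:
    d = LATENT_DIM
    return GeneratorParams(
        head_W=_gauss(rng, (d, d)),
        head_b=np.zeros(d),
        bn=BatchNormParams(
            gamma=np.ones(d),
            beta=np.zeros(d),
            running_mean=np.zeros(d),
            running_var=np.ones(d),
        ),
        lstm1=init_lstm(rng, 56, 1),
        lstm2=init_lstm(rng, 28, 56),
        lstm3=init_lstm(rng, 56, 28),
        attention=init_attention(rng, 56),
        fusion_W=_gauss(rng, (d, d + 1)),
        fusion_b=np.zeros(d),
    )


def init_discriminator(rng: np.random.Generator, final_sigmoid: bool = True) -> DiscriminatorParams:
    return DiscriminatorParams(
        dense1_W=_gauss(rng, (56, 56)),
        dense1_b=np.zeros(56),
        dense2_W=_gauss(rng, (28, 56)),
        dense2_b=np.zeros(28),
        dense3_W=_gauss(rng, (56, 28)),
        dense3_b=np.zeros(56),
        attention=init_attention(rng, 1),
        out_W=_gauss(rng, (1, 1)),
        out_b=np.zeros(1),
        final_sigmoid=final_sigmoid,
    )


# ---------------------------------------------------------------------------
# Forward computations


def lstm_step(
    x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, p: LSTMParams
) -> Tuple[np.ndarray, np.ndarray]:
    """One LSTM cell step.

    f = sigma(W_f.[h,x] + b_f); i = sigma(W_i.[h,x] + b_i);
    C' = tanh(W_C.[h,x] + b_C); c_t = f*c_prev + i*C';
    o = sigma(W_o.[h,x] + b_o); h_t = o*tanh(c_t).
    """
    x_t = np.atleast_1d(np.asarray(x_t, dtype=np.float64))
    h_prev = np.asarray(h_prev, dtype=np.float64)
    c_prev = np.asarray(c_prev, dtype=np.float64)
    if h_prev.shape != (p.hidden,) or c_prev.shape != (p.hidden,):
        raise ValueError("state widths must equal the hidden width")
    if x_t.shape != (p.input_width,):
        raise ValueError(
            f"input width {x_t.shape} does not match parameters ({p.input_width},)"
        )
    hx = np.concatenate([h_prev, x_t])
    f = sigmoid(p.W_f @ hx + p.b_f)
    i = sigmoid(p.W_i @ hx + p.b_i)
    C_bar = np.tanh(p.W_C @ hx + p.b_C)
    c_t = f * c_prev + i * C_bar
    o = sigmoid(p.W_o @ hx + p.b_o)
    h_t = o * np.tanh(c_t)
    return h_t, c_t


def _lstm_sequence(X: np.ndarray, p: LSTMParams) -> np.ndarray:
    """Run a batched input sequence (B, T, input) -> outputs (B, T, hidden).

    Zero initial states; returns the full output sequence.
    """
    B, T, _ = X.shape
    H = p.hidden
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    out = np.empty((B, T, H))
    # concat convention [h_prev, x]: split the weights accordingly
    Wf_h, Wf_x = p.W_f[:, :H], p.W_f[:, H:]
    Wi_h, Wi_x = p.W_i[:, :H], p.W_i[:, H:]
    WC_h, WC_x = p.W_C[:, :H], p.W_C[:, H:]
    Wo_h, Wo_x = p.W_o[:, :H], p.W_o[:, H:]
    for t in range(T):
        x_t = X[:, t, :]
        f = sigmoid(h @ Wf_h.T + x_t @ Wf_x.T + p.b_f)
        i = sigmoid(h @ Wi_h.T + x_t @ Wi_x.T + p.b_i)
        C_bar = np.tanh(h @ WC_h.T + x_t @ WC_x.T + p.b_C)
        c = f * c + i * C_bar
        o = sigmoid(h @ Wo_h.T + x_t @ Wo_x.T + p.b_o)
        h = o * np.tanh(c)
        out[:, t, :] = h
    return out


def attention_pool(
    sequence: Sequence[np.ndarray], p: AttentionParams
) -> Tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product attention pooled to a width-1 context.

    The query is the projected final element; scores are query.key/sqrt(d);
    the context is the weight-averaged width-1 value projection.
    """
    seq = np.asarray(sequence, dtype=np.float64)
    if seq.ndim == 1:
        seq = seq[:, None]
    if seq.ndim != 2 or seq.shape[0] == 0:
        raise ValueError("sequence must be a non-empty list of equal-width vectors")
    if seq.shape[1] != p.input_width:
        raise ValueError(
            f"element width {seq.shape[1]} does not match attention input width {p.input_width}"
        )
    q = seq[-1] @ p.query_proj  # (64,)
    keys = seq @ p.key_proj  # (T, 64)
    scores = keys @ q / np.sqrt(p.key_width)  # (T,)
    scores = scores - scores.max()
    w = np.exp(scores)
    w /= w.sum()
    values = seq @ p.value_proj  # (T, 1)
    context = w @ values  # (1,)
    return context, w


def _attention_batch(seq: np.ndarray, p: AttentionParams) -> np.ndarray:
    """Batched attention: (B, T, input_width) -> context (B, 1)."""
    q = seq[:, -1, :] @ p.query_proj  # (B, 64)
    keys = seq @ p.key_proj  # (B, T, 64)
    scores = np.einsum("btk,bk->bt", keys, q) / np.sqrt(p.key_width)
    scores -= scores.max(axis=1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=1, keepdims=True)
    values = (seq @ p.value_proj)[..., 0]  # (B, T)
    return np.sum(w * values, axis=1, keepdims=True)  # (B, 1)


def _batchnorm(
    x: np.ndarray, bn: BatchNormParams, training: bool, update_running: bool = False
) -> np.ndarray:
    if training:
        mean = x.mean(axis=0)
        var = x.var(axis=0)
        if update_running:
            bn.running_mean = BN_MOMENTUM * bn.running_mean + (1 - BN_MOMENTUM) * mean
            bn.running_var = BN_MOMENTUM * bn.running_var + (1 - BN_MOMENTUM) * var
    else:
        mean, var = bn.running_mean, bn.running_var
    return bn.gamma * (x - mean) / np.sqrt(var + BN_EPS) + bn.beta


def generator_forward(
    z: np.ndarray,
    p: GeneratorParams,
    training: bool = False,
    return_internals: bool = False,
):
    """Map latent vectors through the generator.

    Accepts a single (56,) vector or a batch (B, 56); returns the same
    leading shape.  Deterministic when ``training`` is false (running batch
    statistics are used for normalisation).
    """
    z = np.asarray(z, dtype=np.float64)
    single = z.ndim == 1
    zb = z[None, :] if single else z
    if zb.ndim != 2 or zb.shape[1] != LATENT_DIM:
        raise ValueError(f"generator input must have width {LATENT_DIM}")

    head = relu(_batchnorm(zb @ p.head_W.T + p.head_b, p.bn, training))  # (B, 56)
    seq1 = head[:, :, None]  # 56 steps of one scalar each
    o1 = _lstm_sequence(seq1, p.lstm1)  # (B, 56, 56)
    o2 = _lstm_sequence(o1, p.lstm2)  # (B, 56, 28)
    o3 = _lstm_sequence(o2, p.lstm3)  # (B, 56, 56)
    tail = _attention_batch(o3, p.attention)  # (B, 1)
    fused = np.concatenate([head, tail], axis=1)  # (B, 57)
    out = fused @ p.fusion_W.T + p.fusion_b  # (B, 56)

    result = out[0] if single else out
    if return_internals:
        internals = {
            "head_width": head.shape[1],
            "tail_width": tail.shape[1],
            "fusion_width": fused.shape[1],
            "output_width": out.shape[1],
        }
        return result, internals
    return result


def discriminator_forward(z: np.ndarray, p: DiscriminatorParams) -> np.ndarray:
    """Score latent vectors; accepts (56,) -> scalar or (B, 56) -> (B,)."""
    z = np.asarray(z, dtype=np.float64)
    single = z.ndim == 1
    zb = z[None, :] if single else z
    if zb.ndim != 2 or zb.shape[1] != LATENT_DIM:
        raise ValueError(f"discriminator input must have width {LATENT_DIM}")

    h = relu(zb @ p.dense1_W.T + p.dense1_b)
    h = relu(h @ p.dense2_W.T + p.dense2_b)
    h = relu(h @ p.dense3_W.T + p.dense3_b)  # (B, 56)
    seq = h[:, :, None]  # 56 scalar positions
    ctx = _attention_batch(seq, p.attention)  # (B, 1)
    if p.final_sigmoid:
        ctx = sigmoid(ctx)
    score = ctx @ p.out_W.T + p.out_b  # (B, 1)
    out = score[:, 0]
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# Parameter archive (JSON manifest + npz arrays)


def _flatten_params(obj, prefix: str) -> Dict[str, np.ndarray]:
    out: Dict[str, np.ndarray] = {}
    if isinstance(obj, np.ndarray):
        out[prefix] = obj
    elif isinstance(obj, (LSTMParams, AttentionParams, BatchNormParams,
                          GeneratorParams, DiscriminatorParams)):
        for name, val in vars(obj).items():
            if isinstance(val, (np.ndarray, LSTMParams, AttentionParams, BatchNormParams)):
                out.update(_flatten_params(val, f"{prefix}.{name}"))
    return out


def save_params(directory: str, named: Dict[str, object], seed: Optional[int] = None) -> None:
    """Write a parameter archive: manifest.json + params.npz."""
    os.makedirs(directory, exist_ok=True)
    flat: Dict[str, np.ndarray] = {}
    extras: Dict[str, object] = {}
    for top, obj in named.items():
        flat.update(_flatten_params(obj, top))
        if isinstance(obj, DiscriminatorParams):
            extras[f"{top}.final_sigmoid"] = bool(obj.final_sigmoid)
    manifest = {
        "seed": seed,
        "arrays": {k: list(v.shape) for k, v in flat.items()},
        "extras": extras,
    }
    with open(os.path.join(directory, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    np.savez(os.path.join(directory, "params.npz"), **flat)


def _assign_params(obj, prefix: str, arrays: Dict[str, np.ndarray]) -> None:
    for name, val in list(vars(obj).items()):
        key = f"{prefix}.{name}"
        if isinstance(val, np.ndarray):
            if key not in arrays:
                raise ValueError(f"archive missing array {key}")
            if arrays[key].shape != val.shape:
                raise ValueError(
                    f"shape mismatch for {key}: archive {arrays[key].shape}, "
                    f"expected {val.shape}"
                )
            setattr(obj, name, arrays[key].astype(np.float64))
        elif isinstance(val, (LSTMParams, AttentionParams, BatchNormParams)):
            _assign_params(val, key, arrays)


def load_params(directory: str, named: Dict[str, object]) -> None:
    """Load arrays into existing parameter objects; loud on any mismatch."""
    with open(os.path.join(directory, "manifest.json"), "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    with np.load(os.path.join(directory, "params.npz")) as npz:
        arrays = {k: npz[k] for k in npz.files}
    declared = set(manifest["arrays"])
    if declared != set(arrays):
        raise ValueError("manifest and archive disagree on stored arrays")
    for top, obj in named.items():
        _assign_params(obj, top, arrays)
        if isinstance(obj, DiscriminatorParams):
            flag = manifest.get("extras", {}).get(f"{top}.final_sigmoid")
            if flag is not None:
                obj.final_sigmoid = bool(flag)
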