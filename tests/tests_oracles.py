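"""Independent straight-from-the-equations oracle implementations.

Deliberately written without reference to the package internals: plain
per-element formula evaluation, used by the acceptance tests.
"""

import numpy as np


def oracle_lstm_step(x_t, h_prev, c_prev, p):
    hx = np.concatenate([h_prev, np.atleast_1d(x_t)])
    f = 1 / (1 + np.exp(-(p.W_f @ hx + p.b_f)))
    i = 1 / (1 + np.exp(-(p.W_i @ hx + p.b_i)))
    C_bar = np.tanh(p.W_C @ hx + p.b_C)
    c = f * c_prev + i * C_bar
    o = 1 / (1 + np.exp(-(p.W_o @ hx + p.b_o)))
    return o * np.tanh(c), c


def oracle_attention(seq, p):
    seq = np.asarray(seq, dtype=float)
    q = seq[-1] @ p.query_proj
    scores = np.array([(seq[t] @ p.key_proj) @ q for t in range(len(seq))])
    scores = scores / np.sqrt(p.key_width)
    e = np.exp(scores - scores.max())
    w = e / e.sum()
    vals = np.array([(seq[t] @ p.value_proj)[0] for t in range(len(seq))])
    return float(w @ vals), w
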