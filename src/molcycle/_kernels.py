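"""Optional numba-accelerated inner loop for the LSTM backward pass.

The backward-through-time recurrence is pure polynomial elementwise work
plus one small GEMM per step, which numba fuses well.  (The forward pass
stays in NumPy: its transcendentals run far faster through NumPy's SIMD
``exp``/``tanh`` than through scalar libm calls in a jitted loop.)  When
numba is unavailable the engine falls back to the equivalent pure NumPy
loop in :mod:`molcycle._engine`; tests assert both paths agree.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is pre-installed in CI
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore[misc]
        def wrap(fn):
            return fn

        if a and callable(a[0]):
            return a[0]
        return wrap


@njit(fastmath=True, cache=False)
def lstm_loop_bwd(dH, Fg, Ig, Cb, Og, Cs, TC, WhT, dG):  # pragma: no cover
    B, T, H = dH.shape
    dh = np.zeros((B, H), np.float32)
    dc = np.zeros((B, H), np.float32)
    tmp = np.empty((B, 4 * H), np.float32)
    for t in range(T - 1, -1, -1):
        for bi in range(B):
            for j in range(H):
                dht = dH[bi, t, j] + dh[bi, j]
                f = Fg[bi, t, j]
                i = Ig[bi, t, j]
                cb = Cb[bi, t, j]
                o = Og[bi, t, j]
                tc = TC[bi, t, j]
                cprev = Cs[bi, t - 1, j] if t > 0 else 0.0
                do = dht * tc
                dcc = dc[bi, j] + dht * o * (1.0 - tc * tc)
                tmp[bi, j] = dcc * cprev * f * (1.0 - f)
                tmp[bi, H + j] = dcc * cb * i * (1.0 - i)
                tmp[bi, 2 * H + j] = dcc * i * (1.0 - cb * cb)
                tmp[bi, 3 * H + j] = do * o * (1.0 - o)
                dc[bi, j] = dcc * f
        dhn = np.dot(tmp, WhT)
        for bi in range(B):
            for j in range(H):
                dh[bi, j] = dhn[bi, j]
            for j in range(4 * H):
                dG[bi, t, j] = tmp[bi, j]
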