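"""Numba-compiled LSTM backward kernel.

The per-timestep gate gradients are fused into tight loops; the recurrent
matmuls stay BLAS calls.  Arrays are time-major (T, B, .) so each step
touches contiguous memory.  Gate layout within the 4H axis is
[i | f | o | g], stored post-activation by the forward pass.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def lstm_backward_kernel(gates, tanh_c, c_prev, h_prev, U, mask_t, dh_out_t, reverse):
    """Reverse-mode pass; returns (dxp time-major, dU)."""
    T, B, H4 = gates.shape
    H = H4 // 4
    dt = gates.dtype
    dxp = np.zeros((T, B, H4), dtype=dt)
    dU = np.zeros_like(U)
    dh = np.zeros((B, H), dtype=dt)
    dc = np.zeros((B, H), dtype=dt)
    for s in range(T):
        t = s if reverse else T - 1 - s
        z = gates[t]
        dz = dxp[t]
        for b in range(B):
            m = mask_t[t, b]
            keep = 1.0 - m
            for j in range(H):
                i_g = z[b, j]
                f_g = z[b, H + j]
                o_g = z[b, 2 * H + j]
                g_g = z[b, 3 * H + j]
                tc = tanh_c[t, b, j]
                dh_total = dh_out_t[t, b, j] + dh[b, j]
                dh_new = dh_total * m
                dc_new = dh_new * o_g * (1.0 - tc * tc) + dc[b, j] * m
                do = dh_new * tc
                di = dc_new * g_g
                df = dc_new * c_prev[t, b, j]
                dg = dc_new * i_g
                dz[b, j] = di * i_g * (1.0 - i_g)
                dz[b, H + j] = df * f_g * (1.0 - f_g)
                dz[b, 2 * H + j] = do * o_g * (1.0 - o_g)
                dz[b, 3 * H + j] = dg * (1.0 - g_g * g_g)
                dh[b, j] = dh_total * keep
                dc[b, j] = dc[b, j] * keep + dc_new * f_g
        dU += np.dot(h_prev[t].T, dz)
        dhr = np.dot(dz, U.T)
        dh += dhr
    return dxp, dU
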