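"""Numba-compiled direct convolution kernels.

Channel counts in this network are small (4-128), which starves BLAS-based
im2col formulations; a direct convolution whose innermost loop runs along
the contiguous output row vectorizes well and is compute-bound instead.
The three kernels are the forward correlation, the input-gradient scatter
and the weight-gradient reduction; all work in the array dtype they are
given (float32 in production, float64 in gradient tests) and specialize on
stride 1 so the inner loop carries a unit-stride access pattern.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(fastmath=True, cache=True)
def conv_forward(xp: np.ndarray, w: np.ndarray, out: np.ndarray, s: int) -> None:
    """out[n,co,i,j] += sum_{ci,di,dj} w[co,ci,di,dj] * xp[n,ci,i*s+di,j*s+dj].

    ``xp`` is the zero-padded input; ``out`` must be zero-initialized.
    """
    n_batch, c_in = xp.shape[0], xp.shape[1]
    c_out, k = w.shape[0], w.shape[2]
    h_out, w_out = out.shape[2], out.shape[3]
    for n in range(n_batch):
        for co in range(c_out):
            for i in range(h_out):
                orow = out[n, co, i]
                for ci in range(c_in):
                    for di in range(k):
                        xrow = xp[n, ci, i * s + di]
                        if s == 1:
                            for dj in range(k):
                                wv = w[co, ci, di, dj]
                                for j in range(w_out):
                                    orow[j] += wv * xrow[dj + j]
                        else:
                            for dj in range(k):
                                wv = w[co, ci, di, dj]
                                for j in range(w_out):
                                    orow[j] += wv * xrow[dj + j * s]


@njit(fastmath=True, cache=True)
def conv_backward_input(dxp: np.ndarray, w: np.ndarray, dout: np.ndarray,
                        s: int) -> None:
    """dxp[n,ci,i*s+di,j*s+dj] += w[co,ci,di,dj] * dout[n,co,i,j] (dxp zeroed)."""
    n_batch, c_in = dxp.shape[0], dxp.shape[1]
    c_out, k = w.shape[0], w.shape[2]
    h_out, w_out = dout.shape[2], dout.shape[3]
    for n in range(n_batch):
        for ci in range(c_in):
            for i in range(h_out):
                for co in range(c_out):
                    drow = dout[n, co, i]
                    for di in range(k):
                        xrow = dxp[n, ci, i * s + di]
                        if s == 1:
                            for dj in range(k):
                                wv = w[co, ci, di, dj]
                                for j in range(w_out):
                                    xrow[dj + j] += wv * drow[j]
                        else:
                            for dj in range(k):
                                wv = w[co, ci, di, dj]
                                for j in range(w_out):
                                    xrow[dj + j * s] += wv * drow[j]


@njit(fastmath=True, cache=True)
def conv_backward_weight(xp: np.ndarray, dw: np.ndarray, dout: np.ndarray,
                         s: int) -> None:
    """dw[co,ci,di,dj] += sum_{n,i,j} xp[n,ci,i*s+di,j*s+dj] * dout[n,co,i,j]."""
    n_batch, c_in = xp.shape[0], xp.shape[1]
    c_out, k = dw.shape[0], dw.shape[2]
    h_out, w_out = dout.shape[2], dout.shape[3]
    for n in range(n_batch):
        for i in range(h_out):
            for co in range(c_out):
                drow = dout[n, co, i]
                for ci in range(c_in):
                    for di in range(k):
                        xrow = xp[n, ci, i * s + di]
                        for dj in range(k):
                            acc = xrow[dj] * 0.0
                            if s == 1:
                                for j in range(w_out):
                                    acc += xrow[dj + j] * drow[j]
                            else:
                                for j in range(w_out):
                                    acc += xrow[dj + j * s] * drow[j]
                            dw[co, ci, di, dj] += acc
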