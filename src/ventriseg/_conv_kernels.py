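"""Numba kernels for 3x3 stride-1 'same' convolution in NCHW layout.

The forward pass accumulates one output-channel row block at a time so
the inner loop is a contiguous fused multiply-add over the row; the
backward kernels follow the same structure for the input gradient
(full correlation) and the weight gradient (row-wise reductions).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(fastmath=True, cache=True)
def conv3_fwd(xp, w, b, out):
    # xp: (N, Ci, H+2, W+2); w: (3, 3, Ci, Co); b: (Co,); out: (N, Co, H, W)
    n_im, ci, hp, wp = xp.shape
    co = w.shape[3]
    h, wd = hp - 2, wp - 2
    acc = np.empty((co, wd), dtype=np.float32)
    for n in range(n_im):
        for i in range(h):
            for o in range(co):
                bv = b[o]
                for j in range(wd):
                    acc[o, j] = bv
            for c in range(ci):
                for di in range(3):
                    xrow = xp[n, c, i + di]
                    for dj in range(3):
                        for o in range(co):
                            wv = w[di, dj, c, o]
                            for j in range(wd):
                                acc[o, j] += wv * xrow[j + dj]
            out[n, :, i, :] = acc


@njit(fastmath=True, cache=True)
def conv3_dx(dxp, w, dy):
    # dxp: (N, Ci, H+2, W+2) zero-initialized; dy: (N, Co, H, W)
    n_im, ci, hp, wp = dxp.shape
    co = w.shape[3]
    h, wd = hp - 2, wp - 2
    acc = np.empty(wp, dtype=np.float32)
    for n in range(n_im):
        for c in range(ci):
            for i in range(h):
                for di in range(3):
                    # accumulate all (o, dj) contributions for this target
                    # row in an L1-resident buffer, then add once
                    for j in range(wp):
                        acc[j] = 0.0
                    for o in range(co):
                        dyrow = dy[n, o, i]
                        for dj in range(3):
                            wv = w[di, dj, c, o]
                            for j in range(wd):
                                acc[j + dj] += wv * dyrow[j]
                    drow = dxp[n, c, i + di]
                    for j in range(wp):
                        drow[j] += acc[j]


@njit(fastmath=True, cache=True)
def conv3_dw(xp, dy, dw, db):
    # dw: (3, 3, Ci, Co) accumulated in place; db: (Co,)
    n_im, ci, hp, wp = xp.shape
    co = dy.shape[1]
    h, wd = hp - 2, wp - 2
    for n in range(n_im):
        for o in range(co):
            sb = np.float32(0.0)
            for i in range(h):
                dyrow = dy[n, o, i]
                for j in range(wd):
                    sb += dyrow[j]
            db[o] += sb
        for c in range(ci):
            for o in range(co):
                for i in range(h):
                    dyrow = dy[n, o, i]
                    for di in range(3):
                        xrow = xp[n, c, i + di]
                        s0 = np.float32(0.0)
                        s1 = np.float32(0.0)
                        s2 = np.float32(0.0)
                        for j in range(wd):
                            d = dyrow[j]
                            s0 += d * xrow[j]
                            s1 += d * xrow[j + 1]
                            s2 += d * xrow[j + 2]
                        dw[di, 0, c, o] += s0
                        dw[di, 1, c, o] += s1
                        dw[di, 2, c, o] += s2
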