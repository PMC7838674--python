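"""Brute-force reference implementations used to verify the fast paths.

These are deliberately written as explicit nested loops with no vectorisation
so that they share no code with the production operations they check.  They
are O(everything) and only meant for tiny inputs inside tests and the
acceptance checks.
"""

from __future__ import annotations

import numpy as np


def conv2d_direct(x: np.ndarray, w: np.ndarray, b: np.ndarray,
                  stride: int = 1) -> np.ndarray:
    """Direct 2-D cross-correlation with SAME padding, single feature map.

    Parameters
    ----------
    x : (H, W, Cin) input map.
    w : (kh, kw, Cin, Cout) kernel.
    b : (Cout,) bias.
    stride : spatial stride (same both axes).
    """
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    h, wd, cin = x.shape
    kh, kw, _, cout = w.shape
    ho = -(-h // stride)
    wo = -(-wd // stride)
    pad_h = max((ho - 1) * stride + kh - h, 0)
    pad_w = max((wo - 1) * stride + kw - wd, 0)
    pt, pl = pad_h // 2, pad_w // 2
    y = np.zeros((ho, wo, cout))
    for i in range(ho):
        for j in range(wo):
            for co in range(cout):
                acc = b[co]
                for di in range(kh):
                    for dj in range(kw):
                        ii = i * stride + di - pt
                        jj = j * stride + dj - pl
                        if 0 <= ii < h and 0 <= jj < wd:
                            for ci in range(cin):
                                acc += x[ii, jj, ci] * w[di, dj, ci, co]
                y[i, j, co] = acc
    return y


def relu_direct(x: np.ndarray) -> np.ndarray:
    """Elementwise max(x, 0) by explicit iteration."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    flat_in = x.ravel()
    flat_out = out.ravel()
    for i in range(flat_in.size):
        flat_out[i] = flat_in[i] if flat_in[i] > 0 else 0.0
    return out
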