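"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written directly from the mathematical definitions with
explicit Python loops and symmetric index reflection, deliberately sharing no
code with the package.
"""

import numpy as np


def reflect_index(i: int, n: int) -> int:
    """Symmetric (edge-repeating) reflection of index i into [0, n)."""
    while i < 0 or i >= n:
        if i < 0:
            i = -1 - i
        else:
            i = 2 * n - 1 - i
    return i


def reduce_oracle(x: np.ndarray, taps) -> np.ndarray:
    """Full 2-D separable 5-tap convolution with symmetric borders, then [::2]."""
    taps = np.asarray(taps, dtype=float)
    h, w = x.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            s = 0.0
            for m in range(-2, 3):
                for n in range(-2, 3):
                    s += (taps[m + 2] * taps[n + 2]
                          * x[reflect_index(i + m, h), reflect_index(j + n, w)])
            out[i, j] = s
    return out[::2, ::2]


def expand_oracle(x: np.ndarray, taps, target_shape) -> np.ndarray:
    """Zero-insertion upsampling convolved with the doubled separable kernel.

    Only even source positions contribute; out-of-range source indices are
    reflected symmetrically.  The 4x factor restores unit gain (2x per axis).
    """
    taps = np.asarray(taps, dtype=float)
    h, w = x.shape
    th, tw = target_shape
    out = np.zeros((th, tw))
    for i in range(th):
        for j in range(tw):
            s = 0.0
            for m in range(-2, 3):
                for n in range(-2, 3):
                    if (i - m) % 2 or (j - n) % 2:
                        continue
                    s += (4.0 * taps[m + 2] * taps[n + 2]
                          * x[reflect_index((i - m) // 2, h),
                              reflect_index((j - n) // 2, w)])
            out[i, j] = s
    return out


def sliding_window_oracle(x: np.ndarray, se_shape, op) -> np.ndarray:
    """Naive O(H*W*h*w) sliding min or max with symmetric border reflection."""
    sh, sw = se_shape
    rh, rw = sh // 2, sw // 2
    h, w = x.shape
    out = np.zeros_like(x, dtype=float)
    for i in range(h):
        for j in range(w):
            vals = [
                x[reflect_index(i + di, h), reflect_index(j + dj, w)]
                for di in range(-rh, rh + 1)
                for dj in range(-rw, rw + 1)
            ]
            out[i, j] = op(vals)
    return out


def local_contrast_oracle(x: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel (max-min)/(max+min) with zero where the denominator is zero."""
    mx = sliding_window_oracle(x, (window, window), max)
    mn = sliding_window_oracle(x, (window, window), min)
    out = np.zeros_like(x, dtype=float)
    nz = (mx + mn) != 0
    out[nz] = (mx[nz] - mn[nz]) / (mx[nz] + mn[nz])
    return out


def histogram_oracle(x: np.ndarray, L: int, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Per-pixel tally into L uniform half-open bins (last bin closed)."""
    counts = np.zeros(L)
    width = (hi - lo) / L
    for v in x.ravel():
        k = int((v - lo) / width)
        counts[min(max(k, 0), L - 1)] += 1
    return counts


def variance_oracle(x: np.ndarray) -> float:
    """Two-pass population variance."""
    m = x.mean()
    return float(((x - m) ** 2).mean())
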