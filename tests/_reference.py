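"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's vectorized code paths: plain loops,
explicit least-squares projections and `np.corrcoef`, so that agreement
with the pipeline is a meaningful cross-check rather than a tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import hilbert


def ref_aec_pair(x: np.ndarray, y: np.ndarray, trim_fraction: float = 0.05) -> float:
    """Corrected amplitude envelope correlation of one epoch pair, step by step."""
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    n = x.size
    t = int(round(trim_fraction * n))
    sl = slice(t, n - t if t else n)

    def directed(a: np.ndarray, b: np.ndarray) -> float:
        # envelope of a vs envelope of (b with a regressed out at lag zero)
        beta = np.dot(a, b) / np.dot(a, a)
        resid = b - beta * a
        ea = np.abs(hilbert(a))[sl]
        er = np.abs(hilbert(resid))[sl]
        return float(np.corrcoef(ea, er)[0, 1])

    r = 0.5 * (directed(x, y) + directed(y, x))
    return (r + 1.0) / 2.0


def ref_aec_matrix(
    epochs: np.ndarray, trim_fraction: float = 0.05
) -> np.ndarray:
    """AEC-c matrix by looping over pairs and epochs; NaN diagonal."""
    n_ep, n_reg, _ = epochs.shape
    out = np.full((n_reg, n_reg), np.nan)
    for i in range(n_reg):
        for j in range(i + 1, n_reg):
            vals = [
                ref_aec_pair(epochs[e, i], epochs[e, j], trim_fraction)
                for e in range(n_ep)
            ]
            out[i, j] = out[j, i] = float(np.mean(vals))
    return out
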