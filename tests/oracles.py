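"""Independent brute-force oracles for the core numerics.

Everything here is written as plain double loops / direct linear algebra,
deliberately sharing no code with the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np


def brute_kl(p, q, base=2.0) -> float:
    """Element-by-element Kullback-Leibler summation."""
    total = 0.0
    for pi, qi in zip(p, q):
        if pi > 0.0:
            total += pi * (np.log(pi) - np.log(qi)) / np.log(base)
    return total


def brute_weight(t: float) -> float:
    if t > 1.0:
        return 0.0
    return 1.0 - 0.5 * (7.0 * t**2 - 9.0 * t**4 + 5.0 * t**6 - t**8)


def brute_o(coords, hydro, cutoff=9.0) -> np.ndarray:
    """Pairwise double-loop accumulation of observed hydrophobicity."""
    n = len(coords)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            r = float(np.sqrt(sum((coords[i][k] - coords[j][k]) ** 2 for k in range(3))))
            if r <= cutoff:
                out[i] += (hydro[i] + hydro[j]) * brute_weight(r / cutoff)
    return out


def brute_envelope_sigma(coords) -> np.ndarray:
    """Center, eigen-decompose, and take max |coordinate| / 3 per axis."""
    pts = np.asarray(coords, dtype=float)
    centered = pts - pts.mean(axis=0)
    cov = np.cov(centered.T, bias=True)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axes = eigvecs[:, np.argsort(eigvals)[::-1]]
    local = centered @ axes
    return np.maximum(np.abs(local).max(axis=0) / 3.0, 1.0)


def interaction_matrix(coords, cutoff=9.0) -> np.ndarray:
    """M such that raw O = M @ H (double-loop construction).

    O~_i = H_i * sum_j w_ij + sum_j w_ij H_j is linear in H, giving
    M = W + diag(row sums of W).
    """
    pts = np.asarray(coords, dtype=float)
    n = len(pts)
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                r = float(np.linalg.norm(pts[i] - pts[j]))
                W[i, j] = brute_weight(r / cutoff)
    return W + np.diag(W.sum(axis=1))
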