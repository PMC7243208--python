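"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here recomputes quantities with naive nested loops straight
from the definitions, deliberately sharing no code with the package's
vectorised implementations.
"""

from __future__ import annotations

import numpy as np


def grm_vanraden_loops(dosage: np.ndarray) -> np.ndarray:
    """Centered SNP relationship matrix by explicit per-pair summation."""
    n, m = dosage.shape
    p = np.array([dosage[:, i].sum() / (2 * n) for i in range(m)])
    denom = 2 * sum(p[i] * (1 - p[i]) for i in range(m))
    K = np.zeros((n, n))
    for j in range(n):
        for i in range(n):
            K[j, i] = sum(
                (dosage[j, k] - 2 * p[k]) * (dosage[i, k] - 2 * p[k])
                for k in range(m)
            ) / denom
    return K


def grm_haplotype_loops(mh: np.ndarray, q: int) -> np.ndarray:
    """Uncentered pseudo-marker cross-product by explicit summation."""
    n, P = mh.shape
    K = np.zeros((n, n))
    for j in range(n):
        for i in range(n):
            K[j, i] = sum(float(mh[j, k]) * float(mh[i, k]) for k in range(P)) / q
    return K


def ibs_loops(states: np.ndarray, count: int) -> np.ndarray:
    """Proportion of loci in identical state, counted pairwise."""
    n, m = states.shape
    K = np.zeros((n, n))
    for j in range(n):
        for i in range(n):
            K[j, i] = sum(states[j, k] == states[i, k] for k in range(m)) / count
    return K


def epistasis_loops(states: np.ndarray, count: int) -> np.ndarray:
    """Epistasis entry: unordered locus pairs (self-pairs included) where
    both loci are simultaneously in identical state, over count^2."""
    n, m = states.shape
    K = np.zeros((n, n))
    for j in range(n):
        for i in range(n):
            shared = [k for k in range(m) if states[j, k] == states[i, k]]
            npairs = 0
            for a in range(len(shared)):
                for b in range(a, len(shared)):
                    npairs += 1
            K[j, i] = npairs / count**2
    return K


def distinct_haplotype_count(haps: np.ndarray, lo: int, hi: int) -> int:
    """Number of distinct haplotype strings over marker columns [lo, hi)."""
    seen = set()
    for row in haps:
        seen.add(tuple(row[lo:hi]))
    return len(seen)


def reml_direct(y: np.ndarray, K: np.ndarray, ridge: float = 1e-6,
                grid: int = 2001) -> tuple[float, float, float]:
    """Naive REML: dense-matrix restricted likelihood maximised on a fine
    h2 grid, with explicit inverses and determinants at every point.

    Returns (sigma2_a, sigma2_e, h2) on the mean-diagonal-1 kernel scale.
    """
    n = len(y)
    Kn = K / np.mean(np.diag(K)) + ridge * np.eye(n)
    X = np.ones((n, 1))
    best = (-np.inf, None)
    for h2 in np.linspace(1e-4, 1 - 1e-4, grid):
        lam = h2 / (1 - h2)
        H = lam * Kn + np.eye(n)
        Hi = np.linalg.inv(H)
        XtHiX = (X.T @ Hi @ X).item()
        mu = (X.T @ Hi @ y).item() / XtHiX
        r = y - mu
        q = float(r @ Hi @ r)
        s2e = q / (n - 1)
        ll = -0.5 * ((n - 1) * (np.log(s2e) + 1)
                     + np.linalg.slogdet(H)[1] + np.log(XtHiX))
        if ll > best[0]:
            best = (ll, (lam * s2e, s2e, h2))
    return best[1]


def blup_direct(y: np.ndarray, K: np.ndarray, s2a: float, s2e: float,
                ridge: float = 1e-6) -> np.ndarray:
    """Mixed-model-equation BLUP with explicit matrix inversion.

    Solves [X'X/s2e  X'Z/s2e; Z'X/s2e  Z'Z/s2e + (s2a K)^-1] [mu; a] = rhs
    on the training individuals (Z = I, X = 1).
    """
    n = len(y)
    Kn = K / np.mean(np.diag(K)) + ridge * np.eye(n)
    Ki = np.linalg.inv(s2a * Kn)
    top = np.hstack([np.full((1, 1), n / s2e), np.full((1, n), 1 / s2e)])
    bottom = np.hstack([np.full((n, 1), 1 / s2e), np.eye(n) / s2e + Ki])
    lhs = np.vstack([top, bottom])
    rhs = np.concatenate([[y.sum() / s2e], y / s2e])
    sol = np.linalg.solve(lhs, rhs)
    return sol[1:]
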