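"""Vectorisation operators and the Magnus–Neudecker constant matrices.

``vec`` stacks columns; ``vech`` stacks the lower triangle (including the
diagonal) column by column.  The duplication matrix ``D_n``, elimination
matrix ``L_n`` and commutation matrix ``K_n`` relate the two operators:

    D_n vech(A) = vec(A)        for symmetric A,
    L_n vec(A)  = vech(A),
    K_n vec(A)  = vec(A.T).

These constants appear throughout the closed-form Jacobians of the causal
effect functions and in the expected-information formula for the asymptotic
covariance of the ML estimator.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def vec(a: np.ndarray) -> np.ndarray:
    """Column-major vectorisation of a matrix into a 1-d array."""
    a = np.asarray(a)
    return a.reshape(-1, order="F")


def vech(a: np.ndarray) -> np.ndarray:
    """Half-vectorisation: lower triangle incl. diagonal, column by column."""
    a = np.asarray(a)
    n = a.shape[0]
    rows, cols = np.tril_indices(n)
    # tril_indices is row-major over the triangle; reorder column by column
    order = np.lexsort((rows, cols))
    return a[rows[order], cols[order]]


def vech_index(i: int, j: int, n: int) -> int:
    """Position of entry (i, j), i >= j, 0-based, within vech of an n x n matrix."""
    if i < j:
        i, j = j, i
    return j * n - j * (j - 1) // 2 + (i - j)


@lru_cache(maxsize=32)
def duplication_matrix(n: int) -> np.ndarray:
    """D_n with D_n vech(A) = vec(A) for symmetric A; shape (n^2, n(n+1)/2)."""
    m = n * (n + 1) // 2
    d = np.zeros((n * n, m))
    for j in range(n):
        for i in range(n):
            d[j * n + i, vech_index(i, j, n)] = 1.0
    return d


@lru_cache(maxsize=32)
def elimination_matrix(n: int) -> np.ndarray:
    """L_n with L_n vec(A) = vech(A); shape (n(n+1)/2, n^2)."""
    m = n * (n + 1) // 2
    ell = np.zeros((m, n * n))
    for j in range(n):
        for i in range(j, n):
            ell[vech_index(i, j, n), j * n + i] = 1.0
    return ell


@lru_cache(maxsize=32)
def commutation_matrix(n: int) -> np.ndarray:
    """K_n with K_n vec(A) = vec(A.T); shape (n^2, n^2)."""
    k = np.zeros((n * n, n * n))
    for j in range(n):
        for i in range(n):
            k[i * n + j, j * n + i] = 1.0
    return k


def unvech(v: np.ndarray, n: int) -> np.ndarray:
    """Inverse of vech: rebuild the symmetric n x n matrix."""
    a = np.zeros((n, n))
    idx = 0
    for j in range(n):
        for i in range(j, n):
            a[i, j] = a[j, i] = v[idx]
            idx += 1
    return a
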