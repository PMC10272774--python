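"""Column matching between synergy matrices.

Bilinear factorizations D ~= C S are identifiable only up to column
permutation and positive scaling of C (absorbed into S).  Any comparison
of synergy matrices across runs, days or methods therefore first matches
columns greedily by Pearson correlation on unit-normalized columns.
"""

from __future__ import annotations

import numpy as np

from .errors import ArgumentError, UndefinedMetricError


def pearson_cc(x, y) -> float:
    """Product-moment correlation between two equal-length series.

    Raises
    ------
    ArgumentError
        If lengths differ or are < 2.
    UndefinedMetricError
        If either input is constant (zero variance).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ArgumentError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ArgumentError("need at least 2 samples to correlate")
    xd = x - x.mean()
    yd = y - y.mean()
    sx2 = np.sum(xd * xd)
    sy2 = np.sum(yd * yd)
    if sx2 == 0.0 or sy2 == 0.0:
        raise UndefinedMetricError("correlation undefined for constant input")
    # exact paths: CC is mathematically +/-1 for identical (up to sign)
    # centered series; return it without rounding through the quotient
    if np.array_equal(xd, yd):
        return 1.0
    if np.array_equal(xd, -yd):
        return -1.0
    return float(np.sum(xd * yd) / np.sqrt(sx2 * sy2))


def _safe_cc(x, y) -> float:
    try:
        return pearson_cc(x, y)
    except UndefinedMetricError:
        return 0.0


def column_cc_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Pearson CC between columns of A (m x p) and B (m x q)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ArgumentError("column length mismatch")
    out = np.empty((A.shape[1], B.shape[1]))
    for i in range(A.shape[1]):
        for j in range(B.shape[1]):
            out[i, j] = _safe_cc(A[:, i], B[:, j])
    return out


def match_columns(C_ref: np.ndarray, C: np.ndarray):
    """Greedy maximum-CC matching of ``C``'s columns onto ``C_ref``'s.

    Columns are unit-normalized before comparison (scale is not
    identifiable).  Returns ``(perm, ccs)`` where ``C[:, perm[k]]`` is the
    match for ``C_ref[:, k]`` and ``ccs[k]`` the corresponding CC.
    """
    C_ref = np.asarray(C_ref, dtype=float)
    C = np.asarray(C, dtype=float)
    if C_ref.shape != C.shape:
        raise ArgumentError(f"shape mismatch: {C_ref.shape} vs {C.shape}")
    r = C_ref.shape[1]

    def _unit(M):
        norms = np.linalg.norm(M, axis=0)
        norms[norms == 0] = 1.0
        return M / norms

    cc = column_cc_matrix(_unit(C_ref), _unit(C))
    perm = np.full(r, -1, dtype=int)
    ccs = np.zeros(r)
    work = cc.copy()
    for _ in range(r):
        i, j = np.unravel_index(np.argmax(work), work.shape)
        perm[i] = j
        ccs[i] = cc[i, j]
        work[i, :] = -np.inf
        work[:, j] = -np.inf
    return perm, ccs


def mean_matched_cc(C_ref: np.ndarray, C: np.ndarray) -> float:
    """Mean CC of greedily matched, unit-normalized synergy columns."""
    _, ccs = match_columns(C_ref, C)
    return float(np.mean(ccs))
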