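"""Recovery metrics for scoring estimates against synthetic ground truth."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment


def amari_distance(W: np.ndarray, A: np.ndarray) -> float:
    """Permutation/scale-invariant distance of ``W @ A`` from the identity.

    Zero iff the unmixing ``W`` inverts the mixing ``A`` up to permutation
    and scaling; the usual normalization keeps it in [0, 1].
    """
    P = np.abs(np.asarray(W) @ np.asarray(A))
    m = P.shape[0]
    row = (P.sum(axis=1) / P.max(axis=1) - 1.0).sum()
    col = (P.sum(axis=0) / P.max(axis=0) - 1.0).sum()
    return float((row + col) / (2 * m * (m - 1)))


def match_columns(est: np.ndarray, true: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Match estimated columns to true columns by maximal |correlation|.

    Solves the assignment problem on the |corr| matrix (Hungarian method).
    Returns (indices of est columns matched to each true column, the matched
    |corr| values). ``est`` may have more columns than ``true``.
    """
    est = np.asarray(est, float)
    true = np.asarray(true, float)
    ec = est - est.mean(axis=0)
    tc = true - true.mean(axis=0)
    ec /= np.linalg.norm(ec, axis=0)
    tc /= np.linalg.norm(tc, axis=0)
    C = np.abs(tc.T @ ec)                      # true x est
    rows, cols = linear_sum_assignment(-C)
    order = np.argsort(rows)
    return cols[order], C[rows, cols][order]


def matched_abs_corr(est: np.ndarray, true: np.ndarray) -> float:
    """Mean |correlation| between true columns and their matched estimates."""
    _, corrs = match_columns(est, true)
    return float(np.mean(corrs))


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index of two boolean masks (1.0 when both are empty)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
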