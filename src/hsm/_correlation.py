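"""Vectorised Pearson correlation with the package-wide degenerate-input
convention: correlations involving a constant vector are defined as 0."""

from __future__ import annotations

import numpy as np
from scipy import stats


def pearson_matrix(values: np.ndarray, rowvar: bool = False) -> np.ndarray:
    """Pairwise Pearson correlation of columns (rows if ``rowvar``).

    Constant vectors yield correlation 0 against everything (including
    themselves), never NaN.
    """
    A = np.asarray(values, dtype=float)
    if rowvar:
        A = A.T
    n, p = A.shape
    centered = A - A.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    safe = norms.copy()
    safe[safe == 0] = 1.0
    U = centered / safe
    r = U.T @ U
    r = np.clip(r, -1.0, 1.0)
    const = norms == 0
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.fill_diagonal(r, np.where(const, 0.0, 1.0))
    return r


def pearson_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values of the correlation t-test (df = n-2) applied
    elementwise to a correlation matrix; the diagonal is set to 1."""
    if n < 3:
        raise ValueError("correlation p-values need at least 3 samples")
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 0.0))
    p = 2.0 * stats.t.sf(t, df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    if p.ndim == 2:
        np.fill_diagonal(p, 1.0)
    return p
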