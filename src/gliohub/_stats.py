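"""Small vectorised correlation helpers shared across modules."""

from __future__ import annotations

import numpy as np
from scipy import stats


def standardize_rows(x: np.ndarray) -> np.ndarray:
    """Z-score each row (gene) across columns (samples).

    Raises ValueError naming the first constant row, since a zero-variance
    profile has no defined correlation with anything.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ValueError(f"constant profile at row index {bad[0]}: correlation undefined")
    return (x - mu) / sd


def row_correlations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of ``x`` and every row of ``y``.

    Both arrays share the sample axis (columns). Returns an
    ``x.shape[0] x y.shape[0]`` matrix.
    """
    n = x.shape[1]
    if y.shape[1] != n:
        raise ValueError("sample dimensions differ")
    zx = standardize_rows(x)
    zy = standardize_rows(y)
    r = zx @ zy.T / (n - 1)
    return np.clip(r, -1.0, 1.0)


def correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value for a Pearson correlation via the t transform.

    Uses t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom; |r| = 1
    maps to p = 0.
    """
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return p


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided t-based p for two aligned vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    p = float(correlation_pvalues(np.array(r), n))
    return r, p
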