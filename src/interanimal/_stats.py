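"""Vectorised correlation helpers shared across the package."""

from __future__ import annotations

import numpy as np


def columnwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between matching columns of two (n_obs, n_cols) arrays.

    Columns with zero variance in either input yield NaN (callers decide
    whether that is an exclusion or an error).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    num = (xc * yc).sum(axis=0)
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / denom
    r[~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0)


def cross_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Full (n_cols_x, n_cols_y) Pearson correlation matrix.

    Zero-variance columns produce NaN rows/columns.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must share the observation axis")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / np.outer(sx, sy)
    r[~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Scalar Pearson r between two 1-D vectors (NaN if either is constant)."""
    return float(columnwise_pearson(np.asarray(x).reshape(-1, 1),
                                    np.asarray(y).reshape(-1, 1))[0])
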