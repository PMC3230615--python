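"""Displacement covariance and correlation between alignment positions.

Covariance is pairwise-complete over the proteins that have both positions
present (gap cells are missing data), with per-column means taken over each
column's own present cells and an (N_ij - 1) divisor. The Pearson-style
normalisation r_ij = c_ij / sqrt(c_ii c_jj) gives the position displacement
correlation matrix that is thresholded (r > 0.60) downstream. The same
routines serve unchanged at segment level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: correlation above which a position pair counts as strongly coupled
CORRELATION_THRESHOLD = 0.60
#: minimum number of jointly present proteins for a covariance entry
MIN_PAIR_COUNT = 3


@dataclass
class CorrelationResult:
    """Covariance/correlation matrices over positions (or segments)."""

    covariance: np.ndarray          # (L, L), Angstrom^2, NaN where undefined
    column_means: np.ndarray        # (L,) mean displacement per position
    valid_pairs: np.ndarray         # (L, L) int, proteins behind each entry
    correlation: np.ndarray | None = None  # (L, L) in [-1, 1], NaN where undefined

    @property
    def length(self) -> int:
        return self.covariance.shape[0]


def _displacement_values(d) -> np.ndarray:
    """Accept a DisplacementMatrix or a bare (N, L) array."""
    values = getattr(d, "values", d)
    return np.asarray(values, dtype=float)


def displacement_covariance(d) -> CorrelationResult:
    """Pairwise-complete covariance of displacement columns.

    ``c_ij = sum_over_jointly_present (d_i - dbar_i)(d_j - dbar_j) / (N_ij - 1)``
    with column means dbar over each column's own present cells. Columns with
    fewer than 3 present cells get NaN covariances (logged); entries with
    N_ij < 3 are NaN.
    """
    values = _displacement_values(d)
    n = values.shape[0]
    if n < MIN_PAIR_COUNT:
        raise ValueError(f"need at least {MIN_PAIR_COUNT} proteins, got {n}")
    present = ~np.isnan(values)
    counts = present.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, np.where(present, values, 0.0).sum(axis=0) / np.maximum(counts, 1), np.nan)
    centered = np.where(present, values - means[None, :], 0.0)

    num = centered.T @ centered
    n_ij = present.T.astype(np.int64) @ present.astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = num / (n_ij - 1)
    cov[n_ij < MIN_PAIR_COUNT] = np.nan

    thin = np.flatnonzero(counts < MIN_PAIR_COUNT)
    if thin.size:
        logger.warning(
            "columns with < %d present cells set missing: %s",
            MIN_PAIR_COUNT, (thin + 1).tolist(),
        )
        cov[thin, :] = np.nan
        cov[:, thin] = np.nan
    return CorrelationResult(covariance=cov, column_means=means, valid_pairs=n_ij)


def displacement_correlation(result: CorrelationResult) -> CorrelationResult:
    """Fill the correlation matrix r_ij = c_ij / sqrt(c_ii c_jj).

    The diagonal is exactly 1 wherever the column variance is positive;
    pairs involving zero-variance (or missing) columns are NaN. Values are
    clipped into [-1, 1] against last-bit rounding.
    """
    cov = result.covariance
    var = np.diag(cov).copy()
    ok = np.isfinite(var) & (var > 0)
    denom = np.sqrt(np.where(ok, var, np.nan))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / denom[:, None] / denom[None, :]
    corr = np.clip(corr, -1.0, 1.0)
    corr[~ok, :] = np.nan
    corr[:, ~ok] = np.nan
    idx = np.flatnonzero(ok)
    corr[idx, idx] = 1.0
    result.correlation = corr
    return result


def high_correlation_pairs(
    result: CorrelationResult, threshold: float = CORRELATION_THRESHOLD
) -> list[tuple[int, int, float]]:
    """Off-diagonal pairs with r strictly above the threshold.

    Both orientations (i, j) and (j, i) are reported, matching the symmetric
    way strongly coupled pairs are conventionally listed; sorted by i then j.
    Indices are 0-based.
    """
    if result.correlation is None:
        raise ValueError("correlation not filled; call displacement_correlation first")
    corr = result.correlation
    out: list[tuple[int, int, float]] = []
    length = corr.shape[0]
    for i in range(length):
        for j in range(length):
            if i == j:
                continue
            r = corr[i, j]
            if np.isfinite(r) and r > threshold:
                out.append((i, j, float(r)))
    return out
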