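"""Independent reference implementations used only to cross-check results.

These deliberately take different algorithmic routes from the package:
the quaternion (Horn) closed-form superposition instead of the SVD-based
Kabsch fit, explicit double loops instead of vectorised matrix algebra,
and a fixed-iteration generalized Procrustes loop.
"""

from __future__ import annotations

import numpy as np


def quaternion_fit_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Optimal superposition RMSD via Horn's quaternion method."""
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    p = mobile.shape[0]
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    s = mc.T @ tc
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(k)
    w, x, y, z = eigvecs[:, -1]
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    diff = mc @ rot.T - tc
    return float(np.sqrt((diff ** 2).sum() / p))


def quaternion_generalized_procrustes(coords: np.ndarray, n_iter: int = 200) -> np.ndarray:
    """Fixed-iteration generalized Procrustes mean of (N, P, 3) coordinates.

    No convergence test: just ``n_iter`` rounds of quaternion fits onto the
    running mean. Returns the final per-point mean structure.
    """
    coords = np.asarray(coords, float).copy()
    n = coords.shape[0]
    for _ in range(n_iter):
        mean = coords.mean(axis=0)
        for i in range(n):
            coords[i] = _quaternion_apply(coords[i], mean)
    return coords.mean(axis=0)


def _quaternion_apply(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    mc_mean = mobile.mean(axis=0)
    tc_mean = target.mean(axis=0)
    mc = mobile - mc_mean
    tc = target - tc_mean
    s = mc.T @ tc
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    _, eigvecs = np.linalg.eigh(k)
    w, x, y, z = eigvecs[:, -1]
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return mc @ rot.T + tc_mean


def pairwise_covariance(values: np.ndarray) -> np.ndarray:
    """Double-loop pairwise-complete covariance with (N_ij - 1) divisor."""
    n, length = values.shape
    means = np.array(
        [np.mean([v for v in values[:, l] if not np.isnan(v)]) for l in range(length)]
    )
    cov = np.full((length, length), np.nan)
    for i in range(length):
        for j in range(length):
            acc, cnt = 0.0, 0
            for a in range(n):
                di, dj = values[a, i], values[a, j]
                if np.isnan(di) or np.isnan(dj):
                    continue
                acc += (di - means[i]) * (dj - means[j])
                cnt += 1
            if cnt >= 3:
                cov[i, j] = acc / (cnt - 1)
    return cov


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson correlation of two complete columns."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm ** 2).sum() * (ym ** 2).sum()))
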