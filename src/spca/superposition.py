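"""Rigid-body superposition: pairwise Kabsch fits and the iterative
generalized (multi-body) superposition of an aligned family onto its
evolving mean structure.

The generalized scheme alternates (a) averaging the non-gap coordinates at
the masked columns and (b) least-squares fitting each protein onto that
mean, until the summed RMSD stops improving. A second-stage refinement
restricted to the most conservative positions reuses the same loop with a
column mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .family import AlignedFamily

#: default convergence tolerance: improvement in summed RMSD, Angstrom.
DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 100

_DEGENERACY_RTOL = 1e-8


@dataclass
class RigidTransform:
    """A proper rigid motion x -> R x + t."""

    rotation: np.ndarray   # (3, 3), orthonormal, det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) coordinate array; NaNs pass through."""
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


@dataclass
class SuperpositionReport:
    """Convergence record of a generalized superposition run."""

    iterations: int
    rmsd_trace: list[float] = field(default_factory=list)
    converged: bool = False


def kabsch_fit(
    mobile: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of ``mobile`` onto ``target`` (Kabsch).

    Returns the proper rigid transform minimizing the weighted RMSD and the
    RMSD itself. Requires at least 3 non-collinear points; a reflection in
    the raw SVD solution is corrected to keep the rotation proper.
    """
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    target = np.asarray(target, dtype=float).reshape(-1, 3)
    p = mobile.shape[0]
    if target.shape[0] != p:
        raise ValueError("mobile and target point counts differ")
    if p < 3:
        raise ValueError(f"need at least 3 points, got {p}")
    if weights is None:
        w = np.full(p, 1.0 / p)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (p,) or (w < 0).any():
            raise ValueError("weights must be P non-negative reals")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights sum must be positive")
        w = w / total

    mob_c = mobile - (w @ mobile)
    tar_c = target - (w @ target)

    # collinearity check on the mobile cloud
    sv = np.linalg.svd(mob_c * np.sqrt(w)[:, None], compute_uv=False)
    if sv[0] == 0 or sv[1] < _DEGENERACY_RTOL * sv[0]:
        raise ValueError("degenerate (collinear) point configuration")

    h = (mob_c * w[:, None]).T @ tar_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = (w @ target) - rot @ (w @ mobile)
    tf = RigidTransform(rotation=rot, translation=trans)
    diff = tf.apply(mobile) - target
    rmsd = float(np.sqrt((w * (diff ** 2).sum(axis=1)).sum()))
    return tf, rmsd


def _masked_mean(alpha: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Per-column mean over usable cells; NaN where no cell is usable."""
    sums = np.where(cells[:, :, None], alpha, 0.0).sum(axis=0)
    counts = cells.sum(axis=0)
    mean = np.full(alpha.shape[1:], np.nan)
    ok = counts > 0
    mean[ok] = sums[ok] / counts[ok, None]
    return mean


def _masked_rmsd(alpha: np.ndarray, mean: np.ndarray, cells: np.ndarray) -> float:
    """RMSD over all usable (protein, column) cells against the column mean."""
    diff = alpha - mean[None, :, :]
    sq = (diff ** 2).sum(axis=2)
    vals = sq[cells]
    return float(np.sqrt(vals.mean())) if vals.size else 0.0


def generalized_superpose(
    family: AlignedFamily,
    position_mask: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[AlignedFamily, SuperpositionReport]:
    """Iteratively superpose every family member onto the family mean.

    Parameters
    ----------
    family : AlignedFamily
    position_mask : optional (L,) boolean array
        Columns used for fitting; all columns by default. A column also needs
        at least 2 non-gap proteins to enter the mean. The transforms are
        applied to ALL coordinates (alpha-carbon and mass-center) of each
        protein.
    tol : stop when the summed RMSD improves by less than this (Angstrom).
    max_iter : iteration cap.

    The mean is initialised from the first protein's frame (the family as
    given); convergence is declared when the RMSD improvement drops below
    ``tol``.
    """
    fam = family.copy()
    n, length = fam.n_proteins, fam.length
    if n < 1:
        raise ValueError("empty family")
    if position_mask is None:
        mask = np.ones(length, dtype=bool)
    else:
        mask = np.asarray(position_mask, dtype=bool)
        if mask.shape != (length,):
            raise ValueError("position_mask length mismatch")

    present = ~fam.gap_mask
    usable_cols = mask & (present.sum(axis=0) >= 2)
    if n == 1:
        return fam, SuperpositionReport(iterations=1, rmsd_trace=[0.0], converged=True)
    if usable_cols.sum() < 3:
        raise ValueError(
            f"only {int(usable_cols.sum())} usable columns (need >= 3): "
            "mask must select at least 3 columns with at least 2 non-gap proteins"
        )

    cells = present & usable_cols[None, :]
    prev_rmsd = np.inf
    trace: list[float] = []
    converged = False
    iterations = 0
    for _ in range(max_iter):
        iterations += 1
        mean = _masked_mean(fam.alpha, cells)
        for i in range(n):
            cols = cells[i]
            if cols.sum() < 3:
                continue
            try:
                tf, _ = kabsch_fit(fam.alpha[i, cols], mean[cols])
            except ValueError:
                continue  # degenerate cloud for this protein; leave in place
            fam.alpha[i] = tf.apply(fam.alpha[i])
            fam.mass_center[i] = tf.apply(fam.mass_center[i])
        mean = _masked_mean(fam.alpha, cells)
        rmsd = _masked_rmsd(fam.alpha, mean, cells)
        trace.append(rmsd)
        if prev_rmsd - rmsd < tol:
            converged = True
            break
        prev_rmsd = rmsd
    fam.validate()
    return fam, SuperpositionReport(iterations=iterations, rmsd_trace=trace, converged=converged)


def refine_on_conservative(
    family: AlignedFamily,
    conservative_positions: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[AlignedFamily, SuperpositionReport]:
    """Second-stage superposition restricted to the most conservative columns.

    Delegates to :func:`generalized_superpose` with a mask over the given
    column indices, minimizing the coordinate RMSD at those positions; all
    coordinates are co-transformed.
    """
    cons = np.asarray(list(conservative_positions), dtype=int)
    if cons.size == 0:
        raise ValueError("conservative position set is empty")
    mask = np.zeros(family.length, dtype=bool)
    mask[cons] = True
    if mask.sum() < 3:
        raise ValueError("need at least 3 conservative columns")
    return generalized_superpose(family, position_mask=mask, tol=tol, max_iter=max_iter)
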