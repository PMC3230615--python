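"""The standard protein of a family and the position displacement matrices.

The standard protein is the family's hypothetical representative: the most
frequent amino acid and the unweighted average coordinate at every alignment
column (gap cells contribute nothing). Displacements are the Euclidean
distances from each protein's residue to the standard protein's at the same
column, in the alpha-carbon or residue-mass-center flavor; they are the
foundational variables of the correlation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .family import AlignedFamily, Residue

FLAVORS = ("alpha", "mass_center")


@dataclass
class StandardProtein:
    """Consensus sequence plus average coordinates of a superposed family."""

    consensus: np.ndarray            # (L,) one-letter codes (may contain '-')
    alpha_coords: np.ndarray         # (L, 3) Angstrom
    mass_center_coords: np.ndarray   # (L, 3) Angstrom
    support: np.ndarray              # (L,) number of contributing proteins

    @property
    def length(self) -> int:
        return self.alpha_coords.shape[0]


@dataclass
class DisplacementMatrix:
    """Distances of every protein's positions to the standard protein.

    ``values`` is (N, L) with NaN at gap cells; ``column_means`` averages
    over the non-missing cells of each column.
    """

    values: np.ndarray
    flavor: str
    column_means: np.ndarray


def residue_mass_center(residue: Residue) -> np.ndarray:
    """Mass-weighted mean coordinate of a residue's atoms, sum(m x)/sum(m)."""
    total = residue.masses.sum()
    if total <= 0:
        raise ValueError(f"residue {residue.name}: zero total mass")
    return (residue.masses[:, None] * residue.coords).sum(axis=0) / total


def standard_protein(family: AlignedFamily, table) -> StandardProtein:
    """Build the standard protein from a superposed family.

    Coordinates are the per-column unweighted mean over non-gap proteins, for
    both the alpha-carbon and the mass-center flavor; the sequence is the
    consensus from the frequency table. The family must already be
    superposed (caller responsibility — a raw coordinate average across
    un-superposed frames is meaningless).
    """
    present = ~family.gap_mask
    support = present.sum(axis=0)
    if (support == 0).any():
        bad = np.flatnonzero(support == 0) + 1
        raise ValueError(f"columns with no non-gap protein: {bad.tolist()}")
    if table.length != family.length:
        raise ValueError("frequency table and family lengths differ")

    def col_mean(coords: np.ndarray) -> np.ndarray:
        sums = np.where(present[:, :, None], coords, 0.0).sum(axis=0)
        return sums / support[:, None]

    return StandardProtein(
        consensus=np.asarray(table.consensus, dtype="<U1").copy(),
        alpha_coords=col_mean(family.alpha),
        mass_center_coords=col_mean(family.mass_center),
        support=support,
    )


def displacement_matrix(
    family: AlignedFamily, p0: StandardProtein, flavor: str = "alpha"
) -> DisplacementMatrix:
    """Position displacement matrix D (N x L) for the chosen flavor.

    ``d[i, l]`` is the Euclidean distance between protein i's coordinate and
    the standard protein's at column l; gap cells are NaN.
    """
    if flavor not in FLAVORS:
        raise ValueError(f"unknown flavor {flavor!r}; expected one of {FLAVORS}")
    if p0.length != family.length:
        raise ValueError("standard protein and family lengths differ")
    coords = family.alpha if flavor == "alpha" else family.mass_center
    ref = p0.alpha_coords if flavor == "alpha" else p0.mass_center_coords
    diff = coords - ref[None, :, :]
    values = np.sqrt((diff ** 2).sum(axis=2))  # NaN propagates through gaps
    with np.errstate(invalid="ignore"):
        column_means = np.nanmean(values, axis=0)
    return DisplacementMatrix(values=values, flavor=flavor, column_means=column_means)
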