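"""Core data containers for multiply aligned structural protein families.

An aligned family couples a gapped multiple sequence alignment (N rows x L
columns) with the 3-D coordinates of every residue: for each non-gap cell we
keep the alpha-carbon coordinate and the residue mass-center coordinate.
Gap cells carry NaN coordinates; the gap mask, the sequence and the
coordinate arrays are kept consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GAP = "-"

#: the 21-letter alphabet used throughout: gap first, then the 20 natural
#: amino acids in alphabetical one-letter order.
ALPHABET = "-ACDEFGHIKLMNPQRSTVWY"
AA_LETTERS = ALPHABET[1:]

ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}


@dataclass
class Residue:
    """One residue: name, its alpha carbon, and its full atom table."""

    name: str                 # 3-letter residue name
    alpha: np.ndarray         # (3,) alpha-carbon coordinate, Angstrom
    elements: list[str]       # element symbol per atom
    masses: np.ndarray        # (k,) atomic masses, unified atomic mass units
    coords: np.ndarray        # (k, 3) atom coordinates, Angstrom

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.coords.shape[0] == 0:
            raise ValueError(f"residue {self.name}: empty atom list")
        if not (np.isfinite(self.alpha).all() and np.isfinite(self.coords).all()):
            raise ValueError(f"residue {self.name}: non-finite coordinates")

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class StructureRecord:
    """A single protein chain: an ordered list of residues."""

    id: str
    residues: list[Residue]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def alpha_coords(self) -> np.ndarray:
        """(n_residues, 3) array of alpha-carbon coordinates."""
        return np.array([r.alpha for r in self.residues], dtype=float).reshape(-1, 3)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class AlignedFamily:
    """N structures scattered into the L columns of a gapped alignment.

    Attributes
    ----------
    ids : list of str
        Protein labels, length N.
    sequences : (N, L) array of single characters
        One-letter residue codes, ``'-'`` at gaps.
    alpha : (N, L, 3) float array
        Alpha-carbon coordinates, NaN at gap cells.
    mass_center : (N, L, 3) float array
        Residue mass-center coordinates, NaN at gap cells.
    """

    ids: list[str]
    sequences: np.ndarray
    alpha: np.ndarray
    mass_center: np.ndarray

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype="<U1")
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.mass_center = np.asarray(self.mass_center, dtype=float)
        n, l = self.sequences.shape
        if len(self.ids) != n:
            raise ValueError("ids length does not match sequence rows")
        if self.alpha.shape != (n, l, 3) or self.mass_center.shape != (n, l, 3):
            raise ValueError("coordinate array shape mismatch")

    @property
    def n_proteins(self) -> int:
        return self.sequences.shape[0]

    @property
    def length(self) -> int:
        return self.sequences.shape[1]

    @property
    def gap_mask(self) -> np.ndarray:
        """(N, L) boolean, True at gap cells."""
        return self.sequences == GAP

    def validate(self) -> None:
        """Assert the gap-mask/sequence/coordinate consistency invariant."""
        gaps = self.gap_mask
        alpha_nan = np.isnan(self.alpha).any(axis=2)
        mc_nan = np.isnan(self.mass_center).any(axis=2)
        if not (np.array_equal(gaps, alpha_nan) and np.array_equal(gaps, mc_nan)):
            raise ValueError("gap mask and missing coordinates disagree")
        present = ~gaps
        if not np.isfinite(self.alpha[present]).all():
            raise ValueError("non-finite coordinates at non-gap cells")

    def copy(self) -> "AlignedFamily":
        return AlignedFamily(
            ids=list(self.ids),
            sequences=self.sequences.copy(),
            alpha=self.alpha.copy(),
            mass_center=self.mass_center.copy(),
        )

    def subset_columns(self, keep: np.ndarray) -> "AlignedFamily":
        """Return a new family restricted to the given column indices."""
        keep = np.asarray(keep, dtype=int)
        return AlignedFamily(
            ids=list(self.ids),
            sequences=self.sequences[:, keep].copy(),
            alpha=self.alpha[:, keep, :].copy(),
            mass_center=self.mass_center[:, keep, :].copy(),
        )
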