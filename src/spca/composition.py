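"""Amino-acid composition and frequency analysis of an aligned family.

The composition of the family is encoded as a binary tensor A (N x M x L)
over the 21-letter alphabet (gap + 20 natural amino acids); column-wise
frequencies, the consensus sequence, the most conservative positions
(consensus frequency strictly above 0.80) and gap-dominated column removal
(natural-residue occupancy strictly below 0.20) all derive from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .family import ALPHABET, GAP, AlignedFamily

M = len(ALPHABET)  # 21: gap + 20 amino acids
_CHAR_TO_INDEX = {c: k for k, c in enumerate(ALPHABET)}

#: consensus frequency above which a position counts as most conservative
CONSERVATION_THRESHOLD = 0.80
#: natural-residue occupancy below which a column is deleted as gap-dominated
GAP_OCCUPANCY_THRESHOLD = 0.20


@dataclass
class FrequencyTable:
    """Per-column amino-acid/gap frequencies of an aligned family.

    Attributes
    ----------
    freqs : (21, L) array in [0, 1]
        Row 0 is the gap; rows 1..20 the amino acids in alphabetical
        one-letter order. Every column sums to 1.
    consensus : (L,) array of single characters
        The most frequent symbol per column (may be the gap).
    consensus_freq : (L,) array
        Frequency of the consensus symbol.
    natural_freq : (L,) array
        q_l = 1 - gap frequency: total occupancy by the 20 amino acids.
    """

    freqs: np.ndarray
    consensus: np.ndarray
    consensus_freq: np.ndarray
    natural_freq: np.ndarray

    @property
    def length(self) -> int:
        return self.freqs.shape[1]

    def validate(self) -> None:
        colsums = self.freqs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-12, rtol=0):
            raise ValueError("frequency columns do not sum to 1")
        if not np.allclose(self.consensus_freq, self.freqs.max(axis=0), atol=1e-12, rtol=0):
            raise ValueError("consensus_freq is not the column maximum")


def composition_tensor(family: AlignedFamily) -> np.ndarray:
    """Binary composition tensor A of shape (N, 21, L).

    ``a[i, k, l]`` is 1 iff symbol k sits at column l of protein i; exactly
    one 1 per (protein, column) slice. Characters outside the 21-letter
    alphabet (e.g. B, Z, X, U, O) are mapped to the gap with a warning.
    """
    n, length = family.n_proteins, family.length
    tensor = np.zeros((n, M, length), dtype=np.uint8)
    unknown: set[str] = set()
    for i in range(n):
        for l in range(length):
            c = family.sequences[i, l]
            k = _CHAR_TO_INDEX.get(c)
            if k is None:
                unknown.add(c)
                k = 0
            tensor[i, k, l] = 1
    if unknown:
        warnings.warn(
            f"non-standard residue codes {sorted(unknown)} counted as gaps",
            stacklevel=2,
        )
    return tensor


def position_frequencies(tensor: np.ndarray) -> FrequencyTable:
    """Column-wise frequency table F (21 x L) from the composition tensor.

    The consensus is the argmax symbol per column; on ties the first symbol
    in alphabet order wins (gap, then alphabetical one-letter codes).
    """
    tensor = np.asarray(tensor)
    if tensor.ndim != 3 or tensor.shape[1] != M:
        raise ValueError(f"expected (N, {M}, L) tensor")
    n = tensor.shape[0]
    if n == 0:
        raise ValueError("empty tensor: N = 0")
    counts = tensor.sum(axis=0)     # (21, L)
    freqs = counts / n
    top = freqs.argmax(axis=0)      # first index on ties
    consensus = np.array([ALPHABET[k] for k in top], dtype="<U1")
    table = FrequencyTable(
        freqs=freqs,
        consensus=consensus,
        consensus_freq=freqs.max(axis=0),
        # from the non-gap count directly, so an exact-ratio occupancy like
        # 4/20 compares equal to a user threshold of 0.20
        natural_freq=(n - counts[0]) / n,
    )
    table.validate()
    return table


def conservative_positions(
    table: FrequencyTable, threshold: float = CONSERVATION_THRESHOLD
) -> np.ndarray:
    """Columns whose consensus amino acid has frequency strictly > threshold.

    A gap consensus never qualifies: conservation is defined on the most
    frequent amino acid, and conservative positions seed the structural
    core. Returns sorted 0-based column indices (possibly empty).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    flag = (table.consensus_freq > threshold) & (table.consensus != GAP)
    return np.flatnonzero(flag)


def reduce_gaps(
    family: AlignedFamily,
    table: FrequencyTable,
    q_threshold: float = GAP_OCCUPANCY_THRESHOLD,
) -> tuple[AlignedFamily, np.ndarray]:
    """Delete gap-dominated columns (natural occupancy q_l strictly < threshold).

    Returns the reduced family and the kept-column index map: 0-based original
    column indices of every retained column (presentation layers add 1).
    """
    if not 0 < q_threshold < 1:
        raise ValueError("q_threshold must be in (0, 1)")
    if table.length != family.length:
        raise ValueError("frequency table and family lengths differ")
    keep = np.flatnonzero(table.natural_freq >= q_threshold)
    if keep.size == 0:
        raise ValueError("gap reduction removed every column")
    return family.subset_columns(keep), keep
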