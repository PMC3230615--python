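"""Structural segments: contiguous runs of strongly coupled positions.

A segment is grown from the high-correlation pair list: pairs closer than a
small sequence window link their columns into an undirected graph, each
connected component is closed to its full contiguous interval (interior
columns are swept in even without a qualifying pair of their own), and
overlapping or touching intervals merge. Columns left over become singleton
segments. Segment coordinates are the per-protein mean of the member
alpha-carbon coordinates, and the whole displacement -> covariance ->
correlation analysis is then re-run at segment level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlation import (
    CorrelationResult,
    displacement_correlation,
    displacement_covariance,
)
from .family import AlignedFamily

#: maximum sequence separation |i - j| for a pair to link two columns.
DEFAULT_WINDOW = 4


@dataclass
class Segment:
    """A contiguous interval of alignment columns (0-based, inclusive)."""

    id: str
    start: int
    end: int

    @property
    def multi(self) -> bool:
        return self.end > self.start

    @property
    def n_positions(self) -> int:
        return self.end - self.start + 1

    @property
    def members(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)


@dataclass
class SegmentSet:
    """An ordered partition of all L columns into segments."""

    segments: list[Segment]
    length: int

    @property
    def total_count(self) -> int:
        return len(self.segments)

    @property
    def multi_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.multi]

    @property
    def multi_count(self) -> int:
        return len(self.multi_segments)

    @property
    def multi_positions(self) -> int:
        return sum(s.n_positions for s in self.multi_segments)

    def validate(self) -> None:
        """Every column in exactly one segment; sorted, non-overlapping."""
        covered = np.zeros(self.length, dtype=int)
        prev_end = -1
        for seg in self.segments:
            if seg.start <= prev_end:
                raise ValueError("segments overlap or are unsorted")
            covered[seg.start : seg.end + 1] += 1
            prev_end = seg.end
        if not (covered == 1).all():
            raise ValueError("segments do not partition the columns")


@dataclass
class SegmentFamily:
    """Per-protein segment coordinates and the segment-level analysis."""

    coords: np.ndarray                       # (N, K, 3), NaN where all members gapped
    displacement: np.ndarray | None = None   # (N, K)
    standard_coords: np.ndarray | None = None  # (K, 3)
    result: CorrelationResult | None = None

    @property
    def correlation(self) -> np.ndarray | None:
        return None if self.result is None else self.result.correlation


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def find_segments(
    pairs: list[tuple[int, int, float]],
    length: int,
    window: int = DEFAULT_WINDOW,
) -> SegmentSet:
    """Partition columns into segments from a high-correlation pair list.

    Parameters
    ----------
    pairs : (i, j, r) tuples with 0-based column indices
        Already thresholded (r above the correlation cutoff).
    length : number of alignment columns L.
    window : only pairs with |i - j| <= window link columns.

    Multi-position segments are labelled S1, S2, ... left to right; singleton
    segments P<column> (1-based).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    uf = _UnionFind(length)
    for i, j, _r in pairs:
        if not (0 <= i < length and 0 <= j < length):
            raise ValueError(f"pair index ({i}, {j}) outside 0..{length - 1}")
        if i != j and abs(i - j) <= window:
            uf.union(i, j)

    comp_cols: dict[int, list[int]] = {}
    linked = {c for i, j, _r in pairs if abs(i - j) <= window for c in (i, j)}
    for c in linked:
        comp_cols.setdefault(uf.find(c), []).append(c)

    intervals = sorted(
        (min(cols), max(cols)) for cols in comp_cols.values() if len(cols) > 1
    )
    # merge overlapping or touching intervals after closure
    merged: list[list[int]] = []
    for start, end in intervals:
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])

    segments: list[Segment] = []
    cursor = 0
    s_count = 0
    for start, end in merged:
        while cursor < start:
            segments.append(Segment(id=f"P{cursor + 1}", start=cursor, end=cursor))
            cursor += 1
        s_count += 1
        segments.append(Segment(id=f"S{s_count}", start=start, end=end))
        cursor = end + 1
    while cursor < length:
        segments.append(Segment(id=f"P{cursor + 1}", start=cursor, end=cursor))
        cursor += 1

    segset = SegmentSet(segments=segments, length=length)
    segset.validate()
    return segset


def segment_coordinates(family: AlignedFamily, segset: SegmentSet) -> SegmentFamily:
    """Per-protein segment coordinates: mean of member alpha-carbon coords.

    The unweighted mean runs over the segment's non-gap member positions for
    each protein; a segment cell is NaN when every member is a gap.
    """
    if segset.length != family.length:
        raise ValueError("segment set and family lengths differ")
    n, k = family.n_proteins, segset.total_count
    coords = np.full((n, k, 3), np.nan)
    present = ~family.gap_mask
    for s_idx, seg in enumerate(segset.segments):
        cols = seg.members
        counts = present[:, cols].sum(axis=1)
        sums = np.where(present[:, cols, None], family.alpha[:, cols, :], 0.0).sum(axis=1)
        ok = counts > 0
        coords[ok, s_idx] = sums[ok] / counts[ok, None]
    return SegmentFamily(coords=coords)


def segment_analysis(seg_family: SegmentFamily, segset: SegmentSet) -> SegmentFamily:
    """Segment-level displacement, covariance and correlation.

    The standard segment structure is the per-segment mean over proteins;
    displacements are distances to it; covariance/correlation reuse the
    position-level machinery on the (N, K) displacement matrix.
    """
    coords = seg_family.coords
    present = ~np.isnan(coords).any(axis=2)
    counts = present.sum(axis=0)
    if (counts == 0).any():
        raise ValueError("segment with no non-missing protein")
    standard = np.where(present[:, :, None], coords, 0.0).sum(axis=0) / counts[:, None]
    diff = coords - standard[None, :, :]
    displacement = np.sqrt((diff ** 2).sum(axis=2))
    result = displacement_correlation(displacement_covariance(displacement))
    seg_family.displacement = displacement
    seg_family.standard_coords = standard
    seg_family.result = result
    return seg_family
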