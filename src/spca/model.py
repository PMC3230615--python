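"""Model-level interface: the full structural position correlation analysis.

:class:`SPCA` wraps an aligned structural family together with the analysis
thresholds; :meth:`SPCA.fit` runs the pipeline — generalized superposition,
frequency analysis, refinement on the most conservative positions, gap
reduction, standard protein, displacement matrices, position correlation and
segment construction — and returns an :class:`SPCAResults` carrying every
intermediate product, a ``summary()`` table and writers for the artifact
files. All result labels use ORIGINAL 1-based alignment column numbers via
the kept-column index map, so they are citable against the input alignment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .composition import (
    CONSERVATION_THRESHOLD,
    GAP_OCCUPANCY_THRESHOLD,
    FrequencyTable,
    composition_tensor,
    conservative_positions,
    position_frequencies,
    reduce_gaps,
)
from .correlation import (
    CORRELATION_THRESHOLD,
    CorrelationResult,
    displacement_correlation,
    displacement_covariance,
    high_correlation_pairs,
)
from .family import AlignedFamily
from .reference import (
    DisplacementMatrix,
    StandardProtein,
    displacement_matrix,
    standard_protein,
)
from .segments import (
    DEFAULT_WINDOW,
    SegmentFamily,
    SegmentSet,
    find_segments,
    segment_analysis,
    segment_coordinates,
)
from .superposition import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    SuperpositionReport,
    generalized_superpose,
    refine_on_conservative,
)

logger = logging.getLogger(__name__)


def _subset_table(table: FrequencyTable, keep: np.ndarray) -> FrequencyTable:
    return FrequencyTable(
        freqs=table.freqs[:, keep].copy(),
        consensus=table.consensus[keep].copy(),
        consensus_freq=table.consensus_freq[keep].copy(),
        natural_freq=table.natural_freq[keep].copy(),
    )


class SPCA:
    """Structural position correlation analysis of a protein family.

    Parameters
    ----------
    family : AlignedFamily
        N structures scattered into the L columns of a gapped alignment.
    cons_threshold : consensus frequency above which a position is most
        conservative (strict), default 0.80.
    gap_threshold : natural-residue occupancy below which a column is
        deleted (strict), default 0.20.
    corr_threshold : displacement correlation above which a pair is strongly
        coupled (strict), default 0.60.
    segment_window : maximum sequence separation for a pair to link columns
        into a segment, default 4.
    flavor : displacement flavor driving segmentation, ``"alpha"`` (default)
        or ``"mass_center"``; both flavors are always computed.
    tol, max_iter : superposition convergence controls.
    """

    def __init__(
        self,
        family: AlignedFamily,
        cons_threshold: float = CONSERVATION_THRESHOLD,
        gap_threshold: float = GAP_OCCUPANCY_THRESHOLD,
        corr_threshold: float = CORRELATION_THRESHOLD,
        segment_window: int = DEFAULT_WINDOW,
        flavor: str = "alpha",
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
    ) -> None:
        family.validate()
        self.family = family
        self.cons_threshold = cons_threshold
        self.gap_threshold = gap_threshold
        self.corr_threshold = corr_threshold
        self.segment_window = segment_window
        self.flavor = flavor
        self.tol = tol
        self.max_iter = max_iter

    @classmethod
    def from_files(
        cls,
        pdb_paths: list,
        alignment_path,
        chain_map: dict[str, str] | None = None,
        **kwargs,
    ) -> "SPCA":
        """Build a model from PDB files and a gapped FASTA alignment.

        ``chain_map`` optionally selects a chain per structure id; rows of
        the alignment correspond to the structures by id (file stem).
        """
        from .io import build_family, read_alignment, read_structure

        chain_map = chain_map or {}
        structures = [
            read_structure(p, chain=chain_map.get(Path(p).stem)) for p in pdb_paths
        ]
        alignment = read_alignment(alignment_path)
        return cls(build_family(structures, alignment), **kwargs)

    @classmethod
    def from_spec(cls, spec, **kwargs) -> "SPCA":
        """Build a model from a synthetic :class:`~spca.synthetic.FamilySpec`."""
        from .synthetic import generate_aligned_family

        return cls(generate_aligned_family(spec), **kwargs)

    def fit(self) -> "SPCAResults":
        """Run the full analysis and return the results object."""
        fam = self.family
        logger.info("superposing %d proteins over %d columns", fam.n_proteins, fam.length)
        fam, report1 = generalized_superpose(fam, tol=self.tol, max_iter=self.max_iter)

        tensor = composition_tensor(fam)
        table = position_frequencies(tensor)
        cons = conservative_positions(table, self.cons_threshold)
        logger.info("%d most conservative positions", cons.size)

        report2: SuperpositionReport | None = None
        if cons.size >= 3:
            fam, report2 = refine_on_conservative(
                fam, cons, tol=self.tol, max_iter=self.max_iter
            )
        else:
            logger.warning(
                "only %d conservative positions (< 3); refinement stage skipped",
                cons.size,
            )

        reduced, column_map = reduce_gaps(fam, table, self.gap_threshold)
        logger.info(
            "gap reduction: %d -> %d columns", fam.length, reduced.length
        )
        reduced_table = _subset_table(table, column_map)

        p0 = standard_protein(reduced, reduced_table)
        displacements = {
            fl: displacement_matrix(reduced, p0, fl) for fl in ("alpha", "mass_center")
        }
        correlations = {
            fl: displacement_correlation(displacement_covariance(displacements[fl]))
            for fl in ("alpha", "mass_center")
        }
        pairs = high_correlation_pairs(correlations[self.flavor], self.corr_threshold)
        segset = find_segments(pairs, reduced.length, self.segment_window)
        logger.info(
            "%d segments (%d multi-position)", segset.total_count, segset.multi_count
        )
        seg_family = segment_analysis(segment_coordinates(reduced, segset), segset)

        return SPCAResults(
            model=self,
            superposed_family=fam,
            reduced_family=reduced,
            frequency_table=table,
            reduced_table=reduced_table,
            conservative=cons,
            column_map=column_map,
            standard=p0,
            displacements=displacements,
            correlations=correlations,
            pairs=pairs,
            segment_set=segset,
            segment_family=seg_family,
            superposition_reports=[r for r in (report1, report2) if r is not None],
        )


@dataclass
class SPCAResults:
    """Everything the analysis produced, with summary and writers.

    Position indices inside arrays are 0-based over the REDUCED columns;
    ``column_map`` maps them back to 0-based original columns, and all
    rendered output adds 1.
    """

    model: SPCA
    superposed_family: AlignedFamily       # full columns, superposed
    reduced_family: AlignedFamily          # after gap reduction
    frequency_table: FrequencyTable        # full columns
    reduced_table: FrequencyTable          # reduced columns
    conservative: np.ndarray               # 0-based original column indices
    column_map: np.ndarray                 # reduced -> original 0-based
    standard: StandardProtein
    displacements: dict[str, DisplacementMatrix]
    correlations: dict[str, CorrelationResult]
    pairs: list[tuple[int, int, float]]    # 0-based reduced indices
    segment_set: SegmentSet
    segment_family: SegmentFamily
    superposition_reports: list[SuperpositionReport] = field(default_factory=list)

    # -- labelling helpers -------------------------------------------------

    def original_position(self, reduced_index: int) -> int:
        """1-based original column number of a reduced column index."""
        return int(self.column_map[reduced_index]) + 1

    def segment_label(self, segment) -> str:
        """Segment id with singletons renamed to their original column."""
        if segment.multi:
            return segment.id
        return f"P{self.original_position(segment.start)}"

    @property
    def position_labels(self) -> list[str]:
        return [str(int(c) + 1) for c in self.column_map]

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Human-readable account of the fitted analysis."""
        m = self.model
        fam = self.superposed_family
        lines = [
            "Structural Position Correlation Analysis",
            "=" * 40,
            f"proteins (N):                 {fam.n_proteins}",
            f"alignment columns (L):        {fam.length}",
            f"columns after gap reduction:  {self.reduced_family.length}"
            f"  (q >= {m.gap_threshold:g} kept)",
            f"most conservative positions:  {self.conservative.size}"
            f"  (consensus frequency > {m.cons_threshold:g})",
        ]
        if self.conservative.size:
            lines.append("  position  residue  frequency")
            for c in self.conservative:
                lines.append(
                    f"  {c + 1:>8d}  {self.frequency_table.consensus[c]:>7s}"
                    f"  {self.frequency_table.consensus_freq[c]:9.4f}"
                )
        seg = self.segment_set
        lines += [
            f"high-correlation pairs (r > {m.corr_threshold:g}): {len(self.pairs)}",
            f"segments (K):                 {seg.total_count}",
            f"multi-position segments:      {seg.multi_count}"
            f"  ({seg.multi_positions} positions)",
        ]
        for s in seg.multi_segments:
            start = self.original_position(s.start)
            end = self.original_position(s.end)
            lines.append(f"  {s.id}: positions {start}-{end}  ({s.n_positions} positions)")
        return "\n".join(lines)

    # -- artifact output ---------------------------------------------------

    def save(self, outdir) -> Path:
        """Write all artifacts (TSV/FASTA/PDB) plus a run manifest JSON."""
        from . import io as spio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        labels = self.position_labels
        ids = self.reduced_family.ids

        spio.write_matrix(
            self.frequency_table.freqs,
            list("-ACDEFGHIKLMNPQRSTVWY"),
            [str(i + 1) for i in range(self.frequency_table.length)],
            outdir / "frequencies.tsv",
        )
        with open(outdir / "conservative_positions.tsv", "w") as fh:
            fh.write("position\tresidue\tfrequency\n")
            for c in self.conservative:
                fh.write(
                    f"{c + 1}\t{self.frequency_table.consensus[c]}\t"
                    f"{self.frequency_table.consensus_freq[c]!r}\n"
                )
        spio.write_fasta(
            [("standard_protein", "".join(self.standard.consensus))],
            outdir / "consensus.fasta",
        )
        spio.write_standard_protein(self.standard, outdir / "standard_protein.pdb")
        for fl, d in self.displacements.items():
            spio.write_matrix(d.values, ids, labels, outdir / f"displacement_{fl}.tsv")
            spio.write_matrix(
                d.column_means[None, :], ["mean"], labels,
                outdir / f"displacement_{fl}_means.tsv",
            )
        for fl, c in self.correlations.items():
            spio.write_matrix(c.covariance, labels, labels, outdir / f"covariance_{fl}.tsv")
            spio.write_matrix(c.correlation, labels, labels, outdir / f"correlation_{fl}.tsv")
        spio.write_pairs(
            [(self.column_map[i], self.column_map[j], r) for i, j, r in self.pairs],
            outdir / "high_correlation_pairs.tsv",
        )
        with open(outdir / "segments.tsv", "w") as fh:
            fh.write("id\tstart\tend\tn_positions\tmulti\n")
            for s in self.segment_set.segments:
                fh.write(
                    f"{self.segment_label(s)}\t{self.original_position(s.start)}\t"
                    f"{self.original_position(s.end)}\t{s.n_positions}\t"
                    f"{int(s.multi)}\n"
                )
        seg_labels = [self.segment_label(s) for s in self.segment_set.segments]
        spio.write_matrix(
            self.segment_family.correlation, seg_labels, seg_labels,
            outdir / "segment_correlation.tsv",
        )
        spio.write_matrix(
            self.segment_family.displacement, ids, seg_labels,
            outdir / "segment_displacement.tsv",
        )

        manifest = {
            "spca_version": __version__,
            "n_proteins": self.superposed_family.n_proteins,
            "n_columns": self.superposed_family.length,
            "n_columns_reduced": self.reduced_family.length,
            "column_map": [int(c) + 1 for c in self.column_map],
            "config": {
                "cons_threshold": self.model.cons_threshold,
                "gap_threshold": self.model.gap_threshold,
                "corr_threshold": self.model.corr_threshold,
                "segment_window": self.model.segment_window,
                "flavor": self.model.flavor,
                "tol": self.model.tol,
                "max_iter": self.model.max_iter,
            },
            "conservative_positions": [int(c) + 1 for c in self.conservative],
            "n_segments": self.segment_set.total_count,
            "n_multi_segments": self.segment_set.multi_count,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return outdir
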