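# Methods

## Model and assumptions

`spca` treats a protein family as N rigid bodies observed at L shared
positions. The column correspondence is an *input*: a gapped FASTA alignment
whose rows match the structures 1:1 by id. The package deliberately does not
compute a structure-based sequence alignment; assigning columns from
coordinates is a separate, under-determined problem, and taking the
alignment as given keeps every downstream quantity well defined. Within
that contract the analysis assumes:

- each structure contributes one chain, one model, one conformer
  (first model; highest-occupancy altloc, ties toward 'A'; HETATM residues
  ignored unless standard amino acids);
- gaps carry no coordinates. Gap cells are excluded from superposition
  means, from the standard-protein average and from covariance sums
  (pairwise-complete, with per-pair counts recorded). No imputation is
  performed anywhere — imputed coordinates would manufacture correlation;
- the displacement d_{i,l} = ‖x_{i,l} − x⁰_l‖ is a *norm*: it measures how
  far a member's residue sits from the family average, not in which
  direction. Correlation of these magnitudes is what the method detects.

## Pipeline order

Superposition of all columns → frequency table → most conservative
positions → second superposition restricted to them → gap reduction →
standard protein → displacements (both flavors) → position covariance /
correlation → high-correlation pairs → segments → segment-level analysis.
Gap reduction precedes the correlation step, so correlations are never
computed on gap-dominated columns; all reported position labels are mapped
back to original 1-based column numbers.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| conservation threshold | 0.80 (strict >) | frequency | flags most conservative positions; they seed the structural core used by the refinement superposition |
| gap occupancy threshold | 0.20 (strict <) | frequency | deletes gap-dominated indel columns |
| correlation threshold | 0.60 (strict >) | r | admits a position pair into segment construction |
| segment window | 4 | columns | maximum pair separation that links columns into one segment |
| superposition tol | 1e-4 | Å | stop when summed RMSD improves by less; well below PDB coordinate precision (3 decimals) |
| superposition max_iter | 100 | — | iteration cap |

Threshold comparisons are strict on purpose: a consensus frequency of
exactly 0.80 is not conservative, an occupancy of exactly 0.20 is retained.
Occupancy q_l is computed from the non-gap *count* divided by N (not as
1 − f_gap) so that exact ratios like 4/20 compare equal to a threshold of
0.20 in floating point.

## Numerical choices

- **Kabsch fit**: SVD-based with reflection correction (proper rotation
  enforced); collinear or < 3-point configurations are rejected. The test
  suite cross-checks RMSDs against an independent quaternion
  (Horn closed-form) implementation to 1e-9 Å.
- **Generalized superposition**: alternating fit-to-mean, initialised from
  the family as given (first protein's frame); the masked RMSD trace is
  non-increasing and convergence is declared when the improvement falls
  below tol. A protein with fewer than 3 usable masked cells, or a
  degenerate cloud, is left in place for that iteration. Columns need ≥ 2
  non-gap members to enter the mean.
- **Covariance divisor**: sample convention, N_ij − 1 over the jointly
  present members of each pair; column means are taken over each column's
  own present cells. The correlation matrix — the quantity actually
  thresholded — is identical under either divisor convention. Entries with
  N_ij < 3 and columns with < 3 present cells are set missing (logged),
  as are pairs involving zero-variance columns. Correlations are clipped
  into [−1, 1] against last-bit rounding; diagonals are exactly 1 where the
  variance is positive.
- **Consensus tie-break**: first symbol in alphabet order
  (gap, then A…Y). A gap may be the consensus of a column, but a
  gap-consensus column is never counted conservative: conservation is
  defined on amino acids, and the conservative set seeds the structural
  core, which a gap cannot.
- **Segment construction**: pairs with separation ≤ window link columns;
  connected components are closed to their full contiguous interval
  (interior columns are swept in even when no pair of their own qualifies —
  a run of positions is a physical unit, and a single below-threshold
  interior column does not split it), and overlapping or touching closed
  intervals merge. The window restriction keeps segments *contiguous*:
  without it, a strong sequence-distant pair (exactly the allosteric signal
  the segment-level analysis is meant to expose) would fuse two remote
  regions into one nominal "segment" and hide the coupling it represents.
  Multi-position segments are labelled S1…Sm left to right; singletons carry
  their original column number (P17, …).
- **Mass centers** are computed once from the original atom tables
  (Σ m·x / Σ m with element masses from gemmi) and co-transformed with the
  alpha carbons by every rigid fit thereafter.

## The synthetic generator

`spca.synthetic.FamilySpec` draws families with known truth from one seed:

- a smooth helix-like backbone (radius 2.3 Å, 100°/residue, 1.5 Å rise)
  plus isotropic Gaussian coordinate noise per position (default 0.3 Å);
- designated conserved columns emit a fixed residue with probability
  `p_cons` (default 0.95 at six columns), other columns draw uniformly;
- designated gap columns are gapped per member with probability `p_gap`
  (default 0.9 at two columns), so their expected occupancy of 0.1 falls
  below the 0.20 removal threshold;
- planted blocks: each block has a fixed random unit direction; every
  member draws one standard-normal scalar per latent group, and all blocks
  in the group are displaced by rho × 2 Å × scalar along their own
  directions (default: blocks 10–14 and 40–44 sharing one latent at
  rho = 0.9). Because the analysis correlates displacement *magnitudes*,
  the scalar is shared outright within a group rather than mixed with
  independent per-block noise: mixing would fold-normal-attenuate the
  magnitude correlation and make the planted coupling much weaker than the
  nominal rho suggests;
- optional random rigid jitter per member (on by default), which the
  superposition stage must remove; the jitter draws are consumed even when
  disabled so toggling it changes nothing else;
- residues are CA plus one dummy CB carbon at a fixed local offset, so the
  mass-center flavor is exercised without side-chain modelling.

Default sizes (N = 300, L = 60) keep a full pipeline run near one second,
so multi-seed recovery checks remain cheap.

What the generator does *not* emulate: realistic backbone geometry and
side chains, secondary-structure correlations between neighbouring columns,
alignment errors, and non-rigid (hinge/loop) deformations. Passing
recovery tests therefore shows the statistical machinery is correct under
the stated model, not that real families satisfy that model.

## Known limitations

- No significance calibration for r: the 0.60 cutoff is a fixed convention,
  and with small N the sampling noise of r is substantial.
- Raw member counts: redundant near-identical structures are not
  down-weighted, so heavily deposited subfamilies pull both consensus and
  average structure toward themselves.
- The standard protein is a plain coordinate average; for a family with
  genuinely multimodal conformations it can fall between modes, inflating
  displacements everywhere.
- Segments are contiguous intervals by construction; a functional unit
  assembled from sequence-distant positions appears only at the
  segment-correlation level, never as one segment.
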