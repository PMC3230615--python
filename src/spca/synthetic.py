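"""Seedable generator of synthetic aligned structural families.

The generator emulates the statistical structure the correlation analysis
assumes, with known ground truth: a conserved structural core on a smooth
helical backbone, per-position sequence conservation, gap-dominated columns,
and latent-factor-induced correlated displacements between designated
residue blocks. Blocks that share a latent id receive the SAME per-protein
standard-normal scalar, displacing their member positions along a fixed
per-block direction with amplitude rho * 2 Angstrom; because displacements
are norms, sharing the scalar itself (rather than mixing it with
independent noise) is what makes the displacement *magnitudes* of two
blocks correlate strongly.

All randomness flows from the single integer seed in the spec through one
numpy Generator; identical specs give bytewise-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .family import AA_LETTERS, GAP, ONE_TO_THREE, Residue, StructureRecord

#: displacement amplitude (Angstrom) of a latent at full strength rho = 1
LATENT_SCALE = 2.0
#: fixed local offset of the dummy CB atom from the CA, Angstrom
_CB_OFFSET = np.array([0.5, 0.5, 0.5])
_CARBON_MASS = 12.011


@dataclass
class Block:
    """A planted residue block driven by a latent displacement factor.

    ``start``/``end`` are 1-based inclusive column numbers; ``rho`` in [0, 1]
    scales the latent displacement amplitude; blocks with equal ``latent``
    ids share the per-protein latent draw.
    """

    start: int
    end: int
    rho: float
    latent: int = 0


@dataclass
class FamilySpec:
    """Parameters of a synthetic family; defaults are the study conditions.

    N = 300 proteins over L = 60 columns with 0.3 Angstrom isotropic
    coordinate noise, six conserved columns at conservation 0.95, two
    gap columns gapped with probability 0.9, and two blocks (columns 10-14
    and 40-44, 1-based) sharing one latent at strength rho = 0.9.
    """

    n_proteins: int = 300
    length: int = 60
    conserved_columns: tuple[int, ...] = (3, 18, 25, 48, 55, 58)  # 1-based
    p_cons: float = 0.95
    gap_columns: tuple[int, ...] = (21, 35)  # 1-based
    p_gap: float = 0.9
    planted_blocks: list[Block] = field(
        default_factory=lambda: [Block(10, 14, 0.9, 0), Block(40, 44, 0.9, 0)]
    )
    base_noise_sd: float = 0.3
    rigid_jitter: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.conserved_columns = tuple(self.conserved_columns)
        self.gap_columns = tuple(self.gap_columns)
        self.planted_blocks = [
            b if isinstance(b, Block) else Block(**b) for b in self.planted_blocks
        ]
        self.validate()

    def validate(self) -> None:
        for p, name in ((self.p_cons, "p_cons"), (self.p_gap, "p_gap")):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0 < self.p_cons):
            raise ValueError("p_cons must be in (0, 1]")
        taken = np.zeros(self.length, dtype=bool)
        for b in self.planted_blocks:
            if not (1 <= b.start <= b.end <= self.length):
                raise ValueError(f"block {b.start}-{b.end} outside 1..{self.length}")
            if not 0 <= b.rho <= 1:
                raise ValueError("block rho must be in [0, 1]")
            sl = slice(b.start - 1, b.end)
            if taken[sl].any():
                raise ValueError("planted blocks overlap")
            taken[sl] = True
        for c in (*self.conserved_columns, *self.gap_columns):
            if not 1 <= c <= self.length:
                raise ValueError(f"column {c} outside 1..{self.length}")

    @classmethod
    def from_json(cls, text: str) -> "FamilySpec":
        data = json.loads(text)
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class GroundTruth:
    """Machine-readable truth for parameter-recovery tests (1-based columns)."""

    conserved_columns: list[int]
    expected_removed_columns: list[int]
    block_intervals: list[tuple[int, int]]
    latent_groups: list[int]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        data = json.loads(text)
        data["block_intervals"] = [tuple(iv) for iv in data["block_intervals"]]
        return cls(**data)


def ground_truth(spec: FamilySpec) -> GroundTruth:
    """Ground truth of a spec: conserved set, columns expected to be deleted
    by gap reduction (expected natural occupancy 1 - p_gap below 0.20), and
    the planted block intervals with their latent group ids."""
    removed = list(spec.gap_columns) if 1.0 - spec.p_gap < 0.20 else []
    return GroundTruth(
        conserved_columns=sorted(spec.conserved_columns),
        expected_removed_columns=sorted(removed),
        block_intervals=[(b.start, b.end) for b in spec.planted_blocks],
        latent_groups=[b.latent for b in spec.planted_blocks],
    )


def _backbone(length: int) -> np.ndarray:
    """Smooth helix-like parametric curve, ~alpha-helical dimensions."""
    t = np.arange(length, dtype=float)
    theta = t * (100.0 * np.pi / 180.0)
    return np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * t])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def generate_family(spec: FamilySpec) -> tuple[list[StructureRecord], str]:
    """Generate PDB-style structure records and a gapped FASTA alignment.

    Residues are CA-only plus one dummy CB carbon at a fixed local offset so
    the residue mass center is distinct from the alpha carbon. Returns the
    structure list and the alignment as FASTA text.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, length = spec.n_proteins, spec.length
    base = _backbone(length)

    # family-level draws: consensus residue per column, block directions, latents
    consensus = rng.choice(list(AA_LETTERS), size=length)
    cons_cols = np.array(spec.conserved_columns, dtype=int) - 1
    gap_cols = np.array(spec.gap_columns, dtype=int) - 1

    directions = {}
    for b_idx, b in enumerate(spec.planted_blocks):
        v = rng.normal(size=3)
        directions[b_idx] = v / np.linalg.norm(v)
    latent_ids = sorted({b.latent for b in spec.planted_blocks})
    latents = {g: rng.standard_normal(n) for g in latent_ids}

    structures: list[StructureRecord] = []
    rows: list[tuple[str, str]] = []
    width = len(str(max(n - 1, 1)))
    for i in range(n):
        coords = base + rng.normal(scale=spec.base_noise_sd, size=(length, 3))
        for b_idx, b in enumerate(spec.planted_blocks):
            shift = b.rho * LATENT_SCALE * latents[b.latent][i] * directions[b_idx]
            coords[b.start - 1 : b.end] += shift

        seq = consensus.copy()
        non_cons = np.setdiff1d(np.arange(length), cons_cols)
        seq[non_cons] = rng.choice(list(AA_LETTERS), size=non_cons.size)
        for c in cons_cols:
            if rng.random() >= spec.p_cons:
                others = [a for a in AA_LETTERS if a != consensus[c]]
                seq[c] = rng.choice(others)
        gapped = np.zeros(length, dtype=bool)
        for c in gap_cols:
            gapped[c] = rng.random() < spec.p_gap
        seq = np.where(gapped, GAP, seq)

        cb_coords = coords + _CB_OFFSET  # local offset, co-transformed below
        # jitter draws are consumed either way so that toggling rigid_jitter
        # changes only the rigid motions, not the noise stream
        rot = _random_rotation(rng)
        trans = rng.uniform(-20.0, 20.0, size=3)
        if spec.rigid_jitter:
            coords = coords @ rot.T + trans
            cb_coords = cb_coords @ rot.T + trans

        residues = []
        for l in range(length):
            if gapped[l]:
                continue
            ca = coords[l]
            cb = cb_coords[l]
            residues.append(
                Residue(
                    name=ONE_TO_THREE[str(seq[l])],
                    alpha=ca,
                    elements=["C", "C"],
                    masses=np.array([_CARBON_MASS, _CARBON_MASS]),
                    coords=np.vstack([ca, cb]),
                )
            )
        rid = f"syn{i:0{width}d}"
        structures.append(StructureRecord(id=rid, residues=residues))
        rows.append((rid, "".join(seq)))

    fasta = "".join(f">{rid}\n{row}\n" for rid, row in rows)
    return structures, fasta


def generate_aligned_family(spec: FamilySpec):
    """Convenience: generate and assemble directly into an AlignedFamily."""
    from .io import build_family, parse_fasta

    structures, fasta = generate_family(spec)
    return build_family(structures, parse_fasta(fasta))
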