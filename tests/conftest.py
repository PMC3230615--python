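import numpy as np
import pytest

from spca.family import AlignedFamily, Residue, StructureRecord
from spca.synthetic import FamilySpec, generate_aligned_family


def format_pdb(residues, chain="A"):
    """Render [(resname, [(atomname, element, (x, y, z)), ...]), ...] as PDB text."""
    lines = []
    serial = 1
    for resnum, (resname, atoms) in enumerate(residues, start=1):
        for name, element, (x, y, z) in atoms:
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {resname:<3s} {chain}{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


GLYCINE_ATOMS = [
    ("N", "N", (-0.527, 1.360, 0.000)),
    ("CA", "C", (0.000, 0.000, 0.000)),
    ("C", "C", (1.521, 0.000, 0.000)),
    ("O", "O", (2.200, 1.020, 0.000)),
]


@pytest.fixture
def glycine_pdb(tmp_path):
    path = tmp_path / "gly.pdb"
    path.write_text(format_pdb([("GLY", GLYCINE_ATOMS)]))
    return path


def make_residue(coord, name="ALA"):
    """Single-carbon residue at the given alpha coordinate."""
    coord = np.asarray(coord, dtype=float)
    return Residue(
        name=name,
        alpha=coord,
        elements=["C"],
        masses=np.array([12.011]),
        coords=coord.reshape(1, 3),
    )


def make_structure(sid, coords, names=None):
    coords = np.asarray(coords, dtype=float)
    names = names or ["ALA"] * len(coords)
    return StructureRecord(
        id=sid, residues=[make_residue(c, n) for c, n in zip(coords, names)]
    )


def family_from_arrays(sequences, alpha, mass_center=None, ids=None):
    """Build an AlignedFamily directly from arrays (NaN at gap cells)."""
    sequences = np.asarray(sequences, dtype="<U1")
    alpha = np.asarray(alpha, dtype=float)
    if mass_center is None:
        mass_center = alpha.copy()
    ids = ids or [f"p{i}" for i in range(sequences.shape[0])]
    fam = AlignedFamily(
        ids=ids, sequences=sequences, alpha=alpha, mass_center=np.asarray(mass_center, float)
    )
    fam.validate()
    return fam


def random_ungapped_family(rng, n=6, length=8, scale=1.0):
    """Gap-free family with Gaussian coordinates, for oracle comparisons."""
    alpha = rng.normal(scale=scale, size=(n, length, 3)) + np.arange(length)[None, :, None]
    letters = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=(n, length))
    return family_from_arrays(letters, alpha)


@pytest.fixture
def small_synthetic_family():
    """Small generated family exercising gaps, conservation and one block."""
    spec = FamilySpec(
        n_proteins=30,
        length=20,
        conserved_columns=(2, 9, 16),
        p_cons=1.0,
        gap_columns=(6,),
        p_gap=0.9,
        planted_blocks=[],
        base_noise_sd=0.2,
        rigid_jitter=False,
        seed=7,
    )
    return generate_aligned_family(spec)
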