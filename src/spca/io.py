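"""Readers and writers: PDB structures, gapped FASTA alignments, TSV matrices.

PDB handling goes through gemmi. Only the first model is used; for alternate
conformations the highest-occupancy altloc wins (ties broken toward 'A');
HETATM residues are ignored unless they are one of the 20 standard amino
acids. Positions in every written artifact are 1-based.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO

from .family import (
    GAP,
    ONE_TO_THREE,
    THREE_TO_ONE,
    AlignedFamily,
    Residue,
    StructureRecord,
)
from .reference import StandardProtein, residue_mass_center

logger = logging.getLogger(__name__)

_STANDARD_RESIDUES = set(THREE_TO_ONE)


def _pick_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """One atom per atom name: highest occupancy, ties toward altloc 'A'."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            continue
        key = (atom.occ, -ord(atom.altloc or "A"))
        prev_key = (prev.occ, -ord(prev.altloc or "A"))
        if key > prev_key:
            by_name[atom.name] = atom
    return list(by_name.values())


def read_structure(path: str | Path, chain: str | None = None) -> StructureRecord:
    """Read one chain of a PDB file into a :class:`StructureRecord`.

    Parameters
    ----------
    path : path to a PDB file
    chain : chain identifier; default is the first chain of the first model.

    Residues without an alpha carbon (atom name ``CA``) are dropped with a
    logged warning; an unparseable file raises a ``ValueError`` naming it.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except Exception as exc:  # gemmi raises RuntimeError on parse failure
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"cannot parse PDB file {path}: no models")
    model = st[0]
    if chain is None:
        if len(model) == 0:
            raise ValueError(f"cannot parse PDB file {path}: no chains")
        gchain = model[0]
    else:
        gchain = model.find_chain(chain)
        if gchain is None:
            raise ValueError(f"chain {chain!r} not found in {path}")

    residues: list[Residue] = []
    for res in gchain:
        if res.name not in _STANDARD_RESIDUES:
            continue
        atoms = _pick_altlocs(res)
        ca = next((a for a in atoms if a.name == "CA"), None)
        if ca is None:
            logger.warning(
                "%s: residue %s %s has no CA atom; dropped",
                path.name, res.name, res.seqid,
            )
            continue
        elements = [a.element.name for a in atoms]
        masses = np.array([a.element.weight for a in atoms], dtype=float)
        coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms], dtype=float)
        residues.append(
            Residue(
                name=res.name,
                alpha=np.array([ca.pos.x, ca.pos.y, ca.pos.z], dtype=float),
                elements=elements,
                masses=masses,
                coords=coords,
            )
        )
    return StructureRecord(id=path.stem, residues=residues)


def read_alignment(path: str | Path) -> list[tuple[str, str]]:
    """Read a gapped FASTA alignment as ordered (id, row) pairs."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    widths = {len(s) for _, s in records}
    if len(widths) != 1:
        raise ValueError(f"alignment rows in {path} have unequal lengths {sorted(widths)}")
    return records


def parse_fasta(text: str) -> list[tuple[str, str]]:
    """Parse FASTA-formatted text into ordered (id, sequence) pairs."""
    records: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks)))
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line.upper())
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def build_family(
    structures: list[StructureRecord],
    alignment: list[tuple[str, str]],
) -> AlignedFamily:
    """Scatter structure coordinates into alignment columns.

    The alignment rows must correspond 1:1 (by id) to the structures, and each
    row's non-gap character count must equal the residue count of its
    structure; a mismatch is a hard error naming the offending id.
    """
    by_id = {s.id: s for s in structures}
    if len(by_id) != len(structures):
        raise ValueError("duplicate structure ids")
    missing = [rid for rid, _ in alignment if rid not in by_id]
    if missing:
        raise ValueError(f"alignment rows without structures: {missing}")
    if len(alignment) != len(structures):
        raise ValueError(
            f"{len(alignment)} alignment rows for {len(structures)} structures"
        )

    n = len(alignment)
    length = len(alignment[0][1])
    ids = [rid for rid, _ in alignment]
    sequences = np.full((n, length), GAP, dtype="<U1")
    alpha = np.full((n, length, 3), np.nan)
    mass_center = np.full((n, length, 3), np.nan)

    for i, (rid, row) in enumerate(alignment):
        record = by_id[rid]
        cols = [j for j, c in enumerate(row) if c != GAP]
        if len(cols) != len(record):
            raise ValueError(
                f"{rid}: alignment row has {len(cols)} non-gap columns but the "
                f"structure has {len(record)} residues"
            )
        for res, j in zip(record.residues, cols):
            sequences[i, j] = row[j]
            alpha[i, j] = res.alpha
            mass_center[i, j] = residue_mass_center(res)

    fam = AlignedFamily(ids=ids, sequences=sequences, alpha=alpha, mass_center=mass_center)
    fam.validate()
    return fam


def write_matrix(
    matrix: np.ndarray,
    row_labels: list,
    col_labels: list,
    path: str | Path,
) -> None:
    """Write a labelled 2-D matrix as TSV with repr (round-trippable) floats."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if len(row_labels) != matrix.shape[0] or len(col_labels) != matrix.shape[1]:
        raise ValueError("label counts do not match matrix dimensions")
    with open(path, "w") as fh:
        fh.write("\t".join([""] + [str(c) for c in col_labels]) + "\n")
        for lab, row in zip(row_labels, matrix):
            fh.write("\t".join([str(lab)] + [repr(float(v)) for v in row]) + "\n")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a TSV written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]


def write_standard_protein(p0: StandardProtein, path: str | Path) -> None:
    """Write the standard protein as a CA-only PDB trace.

    One CA pseudo-atom per retained position; residue name is the consensus
    amino acid (``UNK`` where the consensus is a gap); residue number is the
    1-based position index.
    """
    with open(path, "w") as fh:
        for idx, (aa, xyz) in enumerate(zip(p0.consensus, p0.alpha_coords), start=1):
            resname = ONE_TO_THREE.get(aa, "UNK")
            fh.write(
                f"ATOM  {idx:5d}  CA  {resname:<3s} A{idx:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write (id, sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def write_pairs(pairs: list[tuple[int, int, float]], path: str | Path) -> None:
    """Write (i, j, r) high-correlation pairs as 3-column TSV, 1-based."""
    with open(path, "w") as fh:
        fh.write("position_i\tposition_j\tr\n")
        for i, j, r in pairs:
            fh.write(f"{i + 1}\t{j + 1}\t{repr(float(r))}\n")


def read_pairs(path: str | Path) -> list[tuple[int, int, float]]:
    """Read a 3-column (i, j, r) TSV; positions converted to 0-based."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 3:
        raise ValueError(f"expected 3 columns in {path}, got {df.shape[1]}")
    out = []
    for i, j, r in df.itertuples(index=False):
        out.append((int(i) - 1, int(j) - 1, float(r)))
    return out
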