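"""Alignment-quality metrics: coverage and aligned-region RMSD.

Coverage is aligned length over query length.  The aligned-region RMSD
superposes the backbone heavy atoms of the aligned template residues onto the
corresponding native residues with an optimal rigid-body (Kabsch) fit and
reports the root-mean-square deviation; computing it in the raw crystal
frames would be meaningless across PDB entries, so superposition is always
applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .align import Alignment

__all__ = [
    "BACKBONE_ATOMS",
    "alignment_coverage",
    "aligned_region_rmsd",
    "RmsdReport",
    "read_pdb_coords",
]

# backbone heavy atoms, including the ribose O2'
BACKBONE_ATOMS = (
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'", "C2'", "C1'", "O4'", "O2'",
)

CoordinateSet = dict[int, dict[str, tuple[float, float, float]]]


def alignment_coverage(aln: Alignment, query_length: int) -> float:
    """Aligned length divided by query length."""
    if query_length <= 0:
        raise ValueError("query length must be positive")
    return len(aln.pairs) / query_length


@dataclass(frozen=True)
class RmsdReport:
    rmsd: float
    n_atoms: int
    n_dropped: int  # atoms present on only one side, dropped symmetrically


def aligned_region_rmsd(
    aln: Alignment,
    template_coords: CoordinateSet,
    native_coords: CoordinateSet,
    atoms: tuple[str, ...] = BACKBONE_ATOMS,
) -> RmsdReport:
    """RMSD over backbone heavy atoms of the aligned region.

    For each aligned (query, template) residue pair, atoms are intersected by
    name between the native (query-side) and template coordinate sets; atoms
    missing on either side are dropped and counted.  The two point clouds are
    then optimally superposed before the deviation is computed.
    """
    A: list[tuple[float, float, float]] = []
    B: list[tuple[float, float, float]] = []
    dropped = 0
    for qres, tres in aln.pairs:
        ta = template_coords.get(tres, {})
        na = native_coords.get(qres, {})
        for atom in atoms:
            in_t, in_n = atom in ta, atom in na
            if in_t and in_n:
                A.append(ta[atom])
                B.append(na[atom])
            elif in_t or in_n:
                dropped += 1
    if len(A) < 3:
        raise ValueError(
            f"only {len(A)} matched atoms; superposition needs at least 3"
        )
    X = np.asarray(A, dtype=float)
    Y = np.asarray(B, dtype=float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    rot, rssd = Rotation.align_vectors(Yc, Xc)
    rmsd = rssd / np.sqrt(len(A))
    return RmsdReport(rmsd=float(rmsd), n_atoms=len(A), n_dropped=dropped)


def read_pdb_coords(text: str, altloc_ok: tuple[str, ...] = (" ", "A")) -> CoordinateSet:
    """Coordinates of RNA residues from PDB ATOM records (first model only,
    altloc blank or 'A'), keyed by residue sequence number."""
    import io

    from Bio.PDB import PDBParser

    structure = PDBParser(QUIET=True).get_structure("template", io.StringIO(text))
    model = next(structure.get_models())
    coords: CoordinateSet = {}
    for chain in model:
        for residue in chain:
            hetfield, resseq, _ = residue.id
            if hetfield.strip():
                continue
            res = coords.setdefault(resseq, {})
            for atom in residue:
                if atom.get_altloc() not in altloc_ok:
                    continue
                if atom.get_name() not in res:
                    res[atom.get_name()] = tuple(float(v) for v in atom.coord)
    return coords
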