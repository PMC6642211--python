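"""Protein-RNA complex contact statistics from 3D coordinates.

For each RNA chain / protein chain pair in a complex, two contact counts
are taken at a 7 Å cutoff: *internal* contacts are unordered pairs of
phosphate (P) atoms from distinct nucleotides (a proxy for the amount of
RNA structure) and *external* contacts are phosphate / C-alpha cross pairs
(a proxy for the amount of protein contact).  Counts are length-normalised
on a log2 scale:

    internal_score = log2((1 + n_internal) / length_RNA**2)
    external_score = log2((1 + n_external) / (length_RNA * length_protein))

Across a dataset of complexes the two scores are summarised by their
Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, FormatError

DEFAULT_CUTOFF = 7.0  # Angstrom, strict upper bound

#: standard ribonucleotide residue names in PDB files
RNA_RESIDUES = {"A", "C", "G", "U", "I", "N"}


@dataclass
class ComplexGeometry:
    """Phosphate and C-alpha coordinates of one protein-RNA chain pair."""

    complex_id: str
    phosphate_index: np.ndarray  # nucleotide index per P atom
    phosphate_xyz: np.ndarray    # (n, 3) Angstrom
    calpha_index: np.ndarray
    calpha_xyz: np.ndarray
    length_rna: int
    length_protein: int

    def __post_init__(self) -> None:
        self.phosphate_index = np.asarray(self.phosphate_index, dtype=np.int64)
        self.calpha_index = np.asarray(self.calpha_index, dtype=np.int64)
        self.phosphate_xyz = np.asarray(self.phosphate_xyz, dtype=float).reshape(-1, 3)
        self.calpha_xyz = np.asarray(self.calpha_xyz, dtype=float).reshape(-1, 3)
        if self.length_rna < 1 or self.length_protein < 1:
            raise FormatError(f"{self.complex_id}: chain lengths must be >= 1")
        if len(np.unique(self.phosphate_index)) != len(self.phosphate_index):
            raise FormatError(f"{self.complex_id}: duplicate phosphate per nucleotide")
        for xyz in (self.phosphate_xyz, self.calpha_xyz):
            if not np.all(np.isfinite(xyz)):
                raise FormatError(f"{self.complex_id}: non-finite coordinates")


@dataclass
class ContactScores:
    """Counts and length-normalised contact scores of one chain pair."""

    complex_id: str
    internal_count: int
    external_count: int
    internal_score: float
    external_score: float


def count_internal(geometry: ComplexGeometry, cutoff: float = DEFAULT_CUTOFF) -> int:
    """Unordered P-P pairs of distinct nucleotides at distance < cutoff."""
    xyz = geometry.phosphate_xyz
    if len(xyz) < 1:
        raise DegenerateInputError("no phosphate atoms")
    if len(xyz) < 2:
        return 0
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return 0
    d = np.linalg.norm(xyz[pairs[:, 0]] - xyz[pairs[:, 1]], axis=1)
    idx = geometry.phosphate_index
    distinct = idx[pairs[:, 0]] != idx[pairs[:, 1]]
    return int(np.sum((d < cutoff) & distinct))


def count_external(geometry: ComplexGeometry, cutoff: float = DEFAULT_CUTOFF) -> int:
    """P / C-alpha cross pairs at distance < cutoff."""
    if len(geometry.phosphate_xyz) < 1:
        raise DegenerateInputError("no phosphate atoms")
    if len(geometry.calpha_xyz) < 1:
        raise DegenerateInputError("no C-alpha atoms")
    tree = cKDTree(geometry.calpha_xyz)
    neighbours = tree.query_ball_point(geometry.phosphate_xyz, cutoff)
    count = 0
    for p_xyz, idxs in zip(geometry.phosphate_xyz, neighbours):
        if idxs:
            d = np.linalg.norm(geometry.calpha_xyz[idxs] - p_xyz, axis=1)
            count += int(np.sum(d < cutoff))
    return count


def score_contacts(
    internal_count: int,
    external_count: int,
    length_rna: int,
    length_protein: int,
    complex_id: str = "",
) -> ContactScores:
    """Length-normalised log2 contact scores from raw counts."""
    if length_rna < 1 or length_protein < 1:
        raise ValueError("lengths must be >= 1")
    if internal_count < 0 or external_count < 0:
        raise ValueError("counts must be >= 0")
    internal_score = math.log2((1 + internal_count) / length_rna**2)
    external_score = math.log2((1 + external_count) / (length_rna * length_protein))
    return ContactScores(complex_id, internal_count, external_count,
                         internal_score, external_score)


def score_geometry(
    geometry: ComplexGeometry,
    cutoff: float = DEFAULT_CUTOFF,
    ordered_internal: bool = False,
) -> ContactScores:
    """Count and score one chain pair.

    ``ordered_internal`` doubles the internal count for the reading where
    each P-P contact is counted from both partners.
    """
    internal = count_internal(geometry, cutoff)
    if ordered_internal:
        internal *= 2
    external = count_external(geometry, cutoff)
    return score_contacts(internal, external, geometry.length_rna,
                          geometry.length_protein, geometry.complex_id)


def dataset_correlation(scores: Sequence[ContactScores]) -> float:
    """Pearson r between internal and external scores across complexes."""
    if len(scores) < 3:
        raise DegenerateInputError("need at least 3 complexes")
    internal = np.array([s.internal_score for s in scores])
    external = np.array([s.external_score for s in scores])
    if np.ptp(internal) == 0 or np.ptp(external) == 0:
        raise DegenerateInputError("zero variance in contact scores")
    return float(stats.pearsonr(internal, external).statistic)


# ---------------------------------------------------------------------------
# structure-file parsing


def parse_structures(path) -> list[ComplexGeometry]:
    """Extract every (RNA chain, protein chain) pair from a structure file.

    Reads standard PDB or mmCIF (first model only, highest-occupancy
    altloc, hetero/solvent records skipped).  RNA chains are recognised by
    ribonucleotide residue names and contribute P atoms; protein chains by
    amino-acid residues and contribute CA atoms.  Chain length is the number
    of residues observed in the chain, so residues missing their P/CA atom
    still count towards length.  Returns one geometry per chain pair; an
    empty list if the file holds no protein-RNA pair.
    """
    import warnings

    import biotite.structure as struc
    from biotite.structure.io import load_structure

    path = Path(path)
    try:
        atoms = load_structure(str(path), model=1, altloc="occupancy")
    except Exception as exc:  # biotite raises format-specific errors
        raise FormatError(f"{path.name}: cannot parse structure ({exc})") from exc
    atoms = atoms[~atoms.hetero]
    rna_chains, protein_chains = {}, {}
    for chain_id in np.unique(atoms.chain_id):
        chain = atoms[atoms.chain_id == chain_id]
        res_names = set(chain.res_name)
        aa_mask = struc.filter_amino_acids(chain)
        if res_names <= RNA_RESIDUES:
            n_res = len(np.unique(chain.res_id))
            p = chain[chain.atom_name == "P"]
            rna_chains[str(chain_id)] = (p.res_id, p.coord, n_res)
        elif np.all(aa_mask) and len(chain) > 0:
            n_res = len(np.unique(chain.res_id))
            ca = chain[chain.atom_name == "CA"]
            protein_chains[str(chain_id)] = (ca.res_id, ca.coord, n_res)
    geometries = []
    for r_id, (p_idx, p_xyz, n_rna) in sorted(rna_chains.items()):
        for c_id, (ca_idx, ca_xyz, n_prot) in sorted(protein_chains.items()):
            geometries.append(ComplexGeometry(
                complex_id=f"{path.stem}_{r_id}_{c_id}",
                phosphate_index=p_idx, phosphate_xyz=p_xyz,
                calpha_index=ca_idx, calpha_xyz=ca_xyz,
                length_rna=n_rna, length_protein=n_prot,
            ))
    if not geometries:
        warnings.warn(f"{path.name}: no protein-RNA chain pair found")
    return geometries


def score_structures(
    paths: Iterable, cutoff: float = DEFAULT_CUTOFF
) -> list[ContactScores]:
    """Parse and score every chain pair of every structure file."""
    out = []
    for path in paths:
        for geometry in parse_structures(path):
            out.append(score_geometry(geometry, cutoff=cutoff))
    return out
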