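"""Contact counting, normalised scores and structure-file parsing."""

import math
import textwrap

import numpy as np
import pytest

from structbind.contacts import (
    ComplexGeometry,
    count_external,
    count_internal,
    dataset_correlation,
    parse_structures,
    score_contacts,
    score_geometry,
)
from structbind.errors import DegenerateInputError
from structbind.synthetic import generate_complexes


def geometry(p_xyz, ca_xyz=None, p_idx=None):
    p_xyz = np.asarray(p_xyz, dtype=float).reshape(-1, 3)
    ca_xyz = (np.zeros((0, 3)) if ca_xyz is None
              else np.asarray(ca_xyz, dtype=float).reshape(-1, 3))
    n_p, n_ca = len(p_xyz), len(ca_xyz)
    return ComplexGeometry(
        "g", p_idx if p_idx is not None else np.arange(1, n_p + 1), p_xyz,
        np.arange(1, n_ca + 1), ca_xyz,
        length_rna=max(n_p, 1), length_protein=max(n_ca, 1),
    )


def brute_internal(geom, cutoff=7.0):
    count = 0
    for i in range(len(geom.phosphate_xyz)):
        for j in range(i + 1, len(geom.phosphate_xyz)):
            if geom.phosphate_index[i] == geom.phosphate_index[j]:
                continue
            d = np.linalg.norm(geom.phosphate_xyz[i] - geom.phosphate_xyz[j])
            if d < cutoff:
                count += 1
    return count


def brute_external(geom, cutoff=7.0):
    count = 0
    for p in geom.phosphate_xyz:
        for ca in geom.calpha_xyz:
            if np.linalg.norm(p - ca) < cutoff:
                count += 1
    return count


class TestCounts:
    def test_collinear_phosphates(self):
        geom = geometry([[0, 0, 0], [4, 0, 0], [8, 0, 0]])
        assert count_internal(geom) == 2  # the 8-A pair is out

    def test_single_phosphate(self):
        assert count_internal(geometry([[0, 0, 0]])) == 0

    def test_exact_cutoff_excluded(self):
        geom = geometry([[0, 0, 0], [7.0, 0, 0]])
        assert count_internal(geom) == 0
        geom2 = geometry([[0, 0, 0]], ca_xyz=[[0, 7.0, 0]])
        assert count_external(geom2) == 0

    def test_external_hand_distances(self):
        geom = geometry([[0, 0, 0]], ca_xyz=[[3, 0, 0], [10, 0, 0]])
        assert count_external(geom) == 1

    def test_one_phosphate_per_nucleotide_enforced(self):
        from structbind.errors import FormatError

        geom = ComplexGeometry("g", [1, 2], [[0, 0, 0], [1, 0, 0]],
                               [1], [[50, 50, 50]], 2, 1)
        assert count_internal(geom) == 1
        with pytest.raises(FormatError):
            ComplexGeometry("g", [1, 1], [[0, 0, 0], [1, 0, 0]],
                            [1], [[50, 50, 50]], 2, 1)

    def test_missing_protein_rejected(self):
        with pytest.raises(DegenerateInputError):
            count_external(geometry([[0, 0, 0]]))

    def test_matches_brute_force_on_random_geometries(self, rng):
        for _ in range(100):
            n_p = int(rng.integers(1, 25))
            n_ca = int(rng.integers(1, 40))
            span = float(rng.uniform(5, 30))
            geom = geometry(rng.uniform(0, span, (n_p, 3)),
                            rng.uniform(0, span, (n_ca, 3)))
            assert count_internal(geom) == brute_internal(geom)
            assert count_external(geom) == brute_external(geom)

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        geom = geometry(rng.uniform(0, 15, (12, 3)),
                        rng.uniform(0, 15, (20, 3)))
        rot = Rotation.random(rng=123).as_matrix()
        shift = np.array([100.0, -40.0, 7.5])
        moved = geometry(geom.phosphate_xyz @ rot.T + shift,
                         geom.calpha_xyz @ rot.T + shift)
        assert count_internal(moved) == count_internal(geom)
        assert count_external(moved) == count_external(geom)


class TestScores:
    def test_zero_contact_closed_form(self):
        s = score_contacts(0, 0, length_rna=10, length_protein=5)
        assert s.internal_score == pytest.approx(math.log2(1 / 100))
        assert s.external_score == pytest.approx(math.log2(1 / 50))

    def test_hand_arithmetic(self):
        s = score_contacts(3, 7, length_rna=4, length_protein=2)
        assert s.internal_score == pytest.approx(-2.0)
        assert s.external_score == pytest.approx(0.0)

    def test_monotone_in_counts_and_lengths(self):
        base = score_contacts(5, 5, 10, 10)
        more = score_contacts(6, 5, 10, 10)
        longer = score_contacts(5, 5, 12, 10)
        assert more.internal_score > base.internal_score
        assert longer.internal_score < base.internal_score

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            score_contacts(-1, 0, 4, 4)
        with pytest.raises(ValueError):
            score_contacts(0, 0, 0, 4)


class TestDatasetCorrelation:
    def test_perfect_positive_and_negative(self):
        shifted = [score_contacts(2 ** k - 1, 2 ** (k + 1) - 1, 1, 1, str(k))
                   for k in range(5)]
        assert dataset_correlation(shifted) == pytest.approx(1.0)
        flipped = [
            score_contacts(2 ** k - 1, 2 ** (5 - k) - 1, 1, 1, str(k))
            for k in range(5)
        ]
        assert dataset_correlation(flipped) == pytest.approx(-1.0)

    def test_hand_pearson(self):
        # internal/external score pairs (0,0), (1,2), (2,3)
        scores = [score_contacts(0, 0, 1, 1), score_contacts(1, 3, 1, 1),
                  score_contacts(3, 7, 1, 1)]
        assert dataset_correlation(scores) == pytest.approx(0.9820, abs=1e-4)

    def test_degenerate_inputs(self):
        two = [score_contacts(1, 1, 2, 2), score_contacts(2, 2, 2, 2)]
        with pytest.raises(DegenerateInputError):
            dataset_correlation(two)
        flat = [score_contacts(1, k, 2, 2, str(k)) for k in range(4)]
        with pytest.raises(DegenerateInputError):
            dataset_correlation(flat)

    def test_coupled_synthetic_densities_correlate(self):
        geoms = generate_complexes(200, seed=9, contact_level=1.0)
        scores = [score_geometry(g) for g in geoms]
        assert dataset_correlation(scores) > 0.5


def pdb_line(serial, name, altloc, resname, chain, resseq, x, y, z, occ, elem):
    return (
        f"ATOM  {serial:5d} {name:<4s}{altloc:1s}{resname:>3s} {chain:1s}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {elem:>2s}"
    )


PDB_FIXTURE = "\n".join(
    [pdb_line(i + 1, " P", " ", "A", "R", i + 1, 4.0 * i, 0, 0, 1.0, "P")
     for i in range(4)]
    + [pdb_line(5 + i, " CA", " ", "ALA", "B", i + 1, 0, 3.0 + 10.0 * i, 0,
                1.0, "C")
       for i in range(5)]
    + ["END", ""]
)

PDB_ALTLOC = "\n".join(
    [
        pdb_line(1, " P", "A", "A", "R", 1, 0.0, 0, 0, 0.60, "P"),
        pdb_line(2, " P", "B", "A", "R", 1, 2.0, 0, 0, 0.40, "P"),
        pdb_line(3, " P", " ", "A", "R", 2, 4.0, 0, 0, 1.0, "P"),
        pdb_line(4, " CA", " ", "ALA", "B", 1, 0, 3.0, 0, 1.0, "C"),
        pdb_line(5, " CA", " ", "ALA", "B", 2, 0, 6.0, 0, 1.0, "C"),
        pdb_line(6, " CA", " ", "ALA", "B", 3, 0, 9.0, 0, 1.0, "C"),
        "END",
        "",
    ]
)

PDB_PROTEIN_ONLY = "\n".join(
    [
        pdb_line(1, " CA", " ", "GLY", "A", 1, 0, 0, 0, 1.0, "C"),
        pdb_line(2, " CA", " ", "GLY", "A", 2, 3.8, 0, 0, 1.0, "C"),
        "END",
        "",
    ]
)


class TestParseStructures:
    def test_two_chain_fixture(self, tmp_path):
        path = tmp_path / "pair.pdb"
        path.write_text(PDB_FIXTURE)
        geoms = parse_structures(path)
        assert len(geoms) == 1
        geom = geoms[0]
        assert geom.length_rna == 4
        assert geom.length_protein == 5
        assert count_internal(geom) == 3  # adjacent 4-A pairs
        assert count_external(geom) == 2  # first CA is near P1 (3 A), P2 (5 A)

    def test_protein_only_gives_empty_result(self, tmp_path):
        path = tmp_path / "protein.pdb"
        path.write_text(PDB_PROTEIN_ONLY)
        with pytest.warns(UserWarning):
            assert parse_structures(path) == []

    def test_altloc_keeps_single_highest_occupancy(self, tmp_path):
        path = tmp_path / "altloc.pdb"
        path.write_text(PDB_ALTLOC)
        geoms = parse_structures(path)
        assert len(geoms) == 1
        geom = geoms[0]
        assert len(geom.phosphate_xyz) == 2  # one P kept for residue 1
        assert geom.phosphate_xyz[0, 0] == pytest.approx(0.0)  # occupancy 0.60

    def test_round_trip_of_synthetic_complex(self, tmp_path):
        from structbind.synthetic import write_complex_pdb

        geom = generate_complexes(1, seed=4, contact_level=1.0)[0]
        path = tmp_path / "synthetic.pdb"
        write_complex_pdb(geom, path)
        parsed = parse_structures(path)
        assert len(parsed) == 1
        assert parsed[0].length_rna == geom.length_rna
        assert parsed[0].length_protein == geom.length_protein
        # PDB files store 3 decimals; compare against the rounded original
        rounded = geometry(np.round(geom.phosphate_xyz, 3),
                           np.round(geom.calpha_xyz, 3))
        assert count_internal(parsed[0]) == count_internal(rounded)
        assert count_external(parsed[0]) == count_external(rounded)
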