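import math
from itertools import combinations

import numpy as np
import pytest

from srnase_evol import (
    alignment_from_strings,
    category_surface_stats,
    lysine_profile,
    mann_whitney,
    map_alignment_to_structure,
    parse_structure,
    shrake_rupley_asa,
)
from srnase_evol.io import ProbabilityTrack, SequenceRecord
from srnase_evol.selection import call_pss
from srnase_evol.structure import Atom, StructureModel

AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def _atom_line(serial, name, resname, chain, resseq, x, y, z, element,
               record="ATOM"):
    return (
        f"{record:<6s}{serial:>5d} {name:<4s} {resname:>3s} {chain:1s}"
        f"{resseq:>4d}    {x:>8.3f}{y:>8.3f}{z:>8.3f}{1.0:>6.2f}{0.0:>6.2f}"
        f"          {element:>2s}"
    )


def _write_chain(tmp_path, sequence, name="toy.pdb"):
    """One CA carbon per residue, 4 Å apart along x."""
    lines = []
    for i, aa in enumerate(sequence, start=1):
        lines.append(_atom_line(i, "CA", AA3[aa], "A", i, 4.0 * i, 0.0, 0.0, "C"))
    lines.append("END")
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


class TestParse:
    def test_single_atom_with_element_radius(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(_atom_line(1, "SG", "CYS", "A", 1, 0, 0, 0, "S") + "\nEND\n")
        model = parse_structure(path)
        assert len(model.atoms) == 1
        assert model.atoms[0].radius == 1.80
        assert model.sequence == "C"

    def test_waters_and_hydrogens_excluded(self, tmp_path):
        path = tmp_path / "wet.pdb"
        path.write_text(
            "\n".join(
                [
                    _atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0, "C"),
                    _atom_line(2, "H", "ALA", "A", 1, 1, 0, 0, "H"),
                    _atom_line(3, "O", "HOH", "A", 2, 9, 9, 9, "O", record="HETATM"),
                ]
            )
            + "\nEND\n"
        )
        model = parse_structure(path)
        assert len(model.atoms) == 1 and model.atoms[0].element == "C"

    def test_multi_model_uses_first(self, tmp_path):
        path = tmp_path / "nmr.pdb"
        path.write_text(
            "MODEL        1\n"
            + _atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0, "C")
            + "\nENDMDL\nMODEL        2\n"
            + _atom_line(1, "CA", "ALA", "A", 1, 5, 5, 5, "C")
            + "\n"
            + _atom_line(2, "CA", "GLY", "A", 2, 9, 5, 5, "C")
            + "\nENDMDL\nEND\n"
        )
        model = parse_structure(path)
        assert len(model.atoms) == 1

    def test_no_atoms_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(ValueError):
            parse_structure(path)


class TestASA:
    def test_isolated_atom_matches_sphere_area(self, tmp_path):
        path = tmp_path / "c.pdb"
        path.write_text(_atom_line(1, "C", "ALA", "A", 1, 0, 0, 0, "C") + "\nEND\n")
        model = parse_structure(path)
        asa = shrake_rupley_asa(model)
        expected = 4 * math.pi * (1.7 + 1.4) ** 2  # 120.76 square angstroms
        assert asa[("A", 1)] == pytest.approx(expected, rel=0.01)

    def test_fully_caged_atom_is_buried(self):
        directions = []
        for axis in range(3):
            for sign in (1, -1):
                d = [0.0, 0.0, 0.0]
                d[axis] = sign
                directions.append(d)
        for corner in ((1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
                       (-1, 1, 1), (-1, 1, -1), (-1, -1, 1), (-1, -1, -1)):
            n = math.sqrt(3)
            directions.append([c / n for c in corner])
        atoms = [Atom("C", "A", 1, (0.0, 0.0, 0.0), 1.7)]
        for i, d in enumerate(directions, start=2):
            atoms.append(
                Atom("C", "B", i, (2.0 * d[0], 2.0 * d[1], 2.0 * d[2]), 1.7)
            )
        model = StructureModel(
            atoms=tuple(atoms),
            residues=tuple((a.chain, a.resseq, "A") for a in atoms),
        )
        asa = shrake_rupley_asa(model)
        assert asa[("A", 1)] == pytest.approx(0.0, abs=1e-9)

    def test_translation_invariance_and_additivity(self):
        a1 = Atom("C", "A", 1, (0.0, 0.0, 0.0), 1.7)
        a2 = Atom("O", "A", 2, (2.0, 0.0, 0.0), 1.52)
        pair = StructureModel(
            atoms=(a1, a2),
            residues=(("A", 1, "A"), ("A", 2, "A")),
        )
        shifted = StructureModel(
            atoms=(
                Atom("C", "A", 1, (10.0, -3.0, 7.0), 1.7),
                Atom("O", "A", 2, (12.0, -3.0, 7.0), 1.52),
            ),
            residues=pair.residues,
        )
        asa1 = shrake_rupley_asa(pair)
        asa2 = shrake_rupley_asa(shifted)
        for key in asa1:
            assert asa1[key] == pytest.approx(asa2[key], abs=1e-9)
        # two far-apart atoms: ASA equals the isolated-sphere sum
        far = StructureModel(
            atoms=(a1, Atom("O", "B", 1, (100.0, 0.0, 0.0), 1.52)),
            residues=(("A", 1, "A"), ("B", 1, "A")),
        )
        asa3 = shrake_rupley_asa(far)
        assert asa3[("A", 1)] == pytest.approx(4 * math.pi * 3.1**2, rel=1e-9)
        assert asa3[("B", 1)] == pytest.approx(4 * math.pi * 2.92**2, rel=1e-9)

    def test_rotation_invariance_within_sampling_error(self):
        # a fixed point set is only rotation invariant up to its resolution
        theta = 0.7
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0.0],
                [math.sin(theta), math.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 1.0, 0.5], [0.5, 2.5, 1.0]])
        def model_from(c):
            return StructureModel(
                atoms=tuple(
                    Atom("C", "A", i + 1, tuple(map(float, xyz)), 1.7)
                    for i, xyz in enumerate(c)
                ),
                residues=tuple(("A", i + 1, "A") for i in range(len(c))),
            )
        asa1 = shrake_rupley_asa(model_from(coords))
        asa2 = shrake_rupley_asa(model_from(coords @ rot.T))
        total1, total2 = sum(asa1.values()), sum(asa2.values())
        assert total2 == pytest.approx(total1, rel=0.02)


class TestMannWhitney:
    @staticmethod
    def _brute(x, y, alternative):
        pool = list(x) + list(y)
        n1 = len(x)

        def u_stat(xs, ys):
            return sum(1 for a in xs for b in ys if a > b)

        obs = u_stat(x, y)
        us = []
        for idx in combinations(range(len(pool)), n1):
            xs = [pool[i] for i in idx]
            ys = [pool[i] for i in range(len(pool)) if i not in idx]
            us.append(u_stat(xs, ys))
        lo = sum(u <= obs for u in us) / len(us)
        hi = sum(u >= obs for u in us) / len(us)
        if alternative == "less":
            return lo
        if alternative == "greater":
            return hi
        return min(1.0, 2 * min(lo, hi))

    def test_separated_samples_one_sided(self):
        _u, p = mann_whitney([1, 2, 3], [4, 5, 6], alternative="less")
        assert p == pytest.approx(1 / 20)

    @pytest.mark.parametrize("alternative", ["less", "greater", "two-sided"])
    def test_matches_brute_force_enumeration(self, alternative):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 11 - n1))
            vals = rng.permutation(50)[: n1 + n2].tolist()
            x, y = vals[:n1], vals[n1:]
            _u, p = mann_whitney(x, y, alternative=alternative)
            assert p == pytest.approx(self._brute(x, y, alternative), abs=1e-12)


class TestSurfaceStats:
    def _profile(self, n, pss):
        return call_pss(
            ProbabilityTrack(
                [0.99 if k + 1 in pss else 0.0 for k in range(n)],
                [0.99 if k + 1 in pss else 0.0 for k in range(n)],
                [False] * n,
            )
        )

    def test_fractions_sum_to_one_and_means(self):
        asa = {("A", i): float(i * 10) for i in range(1, 7)}
        mapping = {i: ("A", i) for i in range(1, 7)}
        report = category_surface_stats(asa, self._profile(6, {4, 5, 6}), mapping)
        assert report.exposed_fraction_pss + report.exposed_fraction_npss == pytest.approx(1.0)
        assert report.mean_asa_pss == pytest.approx(50.0)
        assert report.mean_asa_npss == pytest.approx(20.0)
        assert report.p_value == pytest.approx(2 / 20)  # two-sided exact

    def test_empty_category_rejected(self):
        asa = {("A", 1): 1.0, ("A", 2): 2.0}
        mapping = {1: ("A", 1), 2: ("A", 2)}
        with pytest.raises(ValueError):
            category_surface_stats(asa, self._profile(2, set()), mapping)


class TestMapping:
    def test_identity_map(self, tmp_path):
        seq = "MKWVLLLSLV"
        path = _write_chain(tmp_path, seq)
        model = parse_structure(path)
        codons = {"M": "ATG", "K": "AAA", "W": "TGG", "V": "GTT", "L": "CTG",
                  "S": "TCT"}
        ref = SequenceRecord(
            id="ref", genus="ref", residues="".join(codons[a] for a in seq)
        )
        mapping = map_alignment_to_structure(ref, model)
        assert mapping == {i: ("A", i) for i in range(1, len(seq) + 1)}

    def test_reference_insertion_unmapped(self, tmp_path):
        struct_seq = "MKWVLLLSLV"
        path = _write_chain(tmp_path, struct_seq)
        model = parse_structure(path)
        codons = {"M": "ATG", "K": "AAA", "W": "TGG", "V": "GTT", "L": "CTG",
                  "S": "TCT", "G": "GGA"}
        ref_seq = struct_seq[:5] + "GGG" + struct_seq[5:]
        ref = SequenceRecord(
            id="ref", genus="ref", residues="".join(codons[a] for a in ref_seq)
        )
        mapping = map_alignment_to_structure(ref, model)
        assert 6 not in mapping or mapping[6] != ("A", 6)
        assert mapping[1] == ("A", 1)
        assert mapping[len(ref_seq)] == ("A", len(struct_seq))

    def test_leading_truncation_offset(self, tmp_path):
        struct_seq = "MKWVLLLSLV"
        path = _write_chain(tmp_path, struct_seq)
        model = parse_structure(path)
        codons = {"W": "TGG", "V": "GTT", "L": "CTG", "S": "TCT"}
        ref_seq = struct_seq[2:]  # reference starts at the third residue
        ref = SequenceRecord(
            id="ref", genus="ref", residues="".join(codons[a] for a in ref_seq)
        )
        mapping = map_alignment_to_structure(ref, model)
        assert mapping[1] == ("A", 3)
        assert mapping[len(ref_seq)] == ("A", len(struct_seq))


class TestLysines:
    def test_fully_conserved(self):
        aln = alignment_from_strings(
            [("r", "AAAGGG"), ("b", "AAAGGA"), ("c", "AAGGGG")]
        )
        profile = lysine_profile(aln, "r")
        assert profile.lysines == {1: (1.0, ">75%")}

    def test_intermediate_bin(self):
        rows = [("r", "AAA")] + [
            (f"s{i}", "AAA" if i < 5 else "AGA") for i in range(9)
        ]
        profile = lysine_profile(alignment_from_strings(rows), "r")
        freq, label = profile.lysines[1]
        assert freq == pytest.approx(0.6) and label == "50-75%"

    def test_gaps_excluded_from_denominator(self):
        aln = alignment_from_strings(
            [("r", "AAA"), ("b", "---"), ("c", "AAG"), ("d", "---")]
        )
        freq, label = lysine_profile(aln, "r").lysines[1]
        assert freq == 1.0 and label == ">75%"

    def test_reference_without_lysine_rejected(self):
        aln = alignment_from_strings([("r", "GGG"), ("b", "GGA")])
        with pytest.raises(ValueError):
            lysine_profile(aln, "r")
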