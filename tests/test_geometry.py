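"""Torsions, contacts, hydrogen bonds, turns and superposition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snnkit.geometry import (
    GeometryError,
    backbone_dihedrals,
    contacts,
    detect_turns,
    dihedral,
    hydrogen_bonds,
    sidechain_dihedrals,
    superpose,
)
from snnkit.structure import Atom, Residue, Structure, select_residue
from snnkit.synth import PeptideBuildSpec, ResidueTorsions, build_peptide


def oracle_dihedral(p1, p2, p3, p4):
    """Independent torsion oracle: explicit Newman-projection construction
    (project the outer bonds onto the plane normal to the central bond and
    measure the signed angle between the projections)."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    b2 = p4 - p3
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


coords3 = st.tuples(*[st.floats(-10, 10) for _ in range(3)]).map(np.array)


def _nondegenerate(ps):
    p1, p2, p3, p4 = ps
    if min(np.linalg.norm(b - a) for a, b in ((p1, p2), (p2, p3), (p3, p4))) < 1e-2:
        return False
    n1 = np.cross(p2 - p1, p3 - p2)
    n2 = np.cross(p3 - p2, p4 - p3)
    return min(np.linalg.norm(n1), np.linalg.norm(n2)) > 1e-2


points4 = st.tuples(coords3, coords3, coords3, coords3).filter(_nondegenerate)


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]) == pytest.approx(0.0)

    def test_planar_trans_is_180(self):
        val = dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0])
        assert abs(val) == pytest.approx(180.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(points4)
    def test_matches_brute_force_oracle(self, ps):
        assert dihedral(*ps) == pytest.approx(oracle_dihedral(*ps), abs=1e-6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(points4)
    def test_reversal_preserves_iupac_torsion(self, ps):
        # IUPAC torsions are invariant under full point reversal ...
        fwd = dihedral(*ps)
        rev = dihedral(*reversed(ps))
        assert rev == pytest.approx(fwd, abs=1e-6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(points4)
    def test_mirror_negates_torsion(self, ps):
        # ... and change sign under reflection (chirality flip)
        mirrored = [p * np.array([1, 1, -1]) for p in ps]
        fwd = dihedral(*ps)
        mir = dihedral(*mirrored)
        if abs(abs(fwd) - 180.0) > 1e-6:
            assert mir == pytest.approx(-fwd, abs=1e-6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(points4, st.floats(-180, 180), coords3)
    def test_rigid_motion_invariance(self, ps, angle, shift):
        theta = math.radians(angle)
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0],
                [math.sin(theta), math.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = [rot @ p + shift for p in ps]
        assert dihedral(*moved) == pytest.approx(dihedral(*ps), abs=1e-6)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(GeometryError):
            dihedral([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])
        with pytest.raises(GeometryError):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])


class TestResidueTorsions:
    @pytest.mark.parametrize(
        "phi,psi,chi1,chi2",
        [
            (42.6, -128.8, 127.3, 179.4),     # succinimide-site values (WT)
            (-129.3, 148.6, 173.9, -99.6),    # intact-Asn double-mutant values
            (-120.0, -120.0, 120.0, 90.0),
        ],
    )
    def test_builder_round_trip(self, phi, psi, chi1, chi2):
        tors = [
            ResidueTorsions(),
            ResidueTorsions(phi=phi, psi=psi, chi1=chi1, chi2=chi2),
            ResidueTorsions(),
        ]
        stru = build_peptide(PeptideBuildSpec("ANA", tors))
        bb = backbone_dihedrals(stru, "A", 2)
        assert bb.phi == pytest.approx(phi, abs=0.1)
        assert bb.psi == pytest.approx(psi, abs=0.1)
        c1, c2 = sidechain_dihedrals(select_residue(stru, "A", 2))
        assert c1 == pytest.approx(chi1, abs=0.1)
        assert c2 == pytest.approx(chi2, abs=0.1)

    def test_termini_are_undefined_not_errors(self, extended_strand):
        first = backbone_dihedrals(extended_strand, "A", 1)
        last = backbone_dihedrals(extended_strand, "A", 9)
        assert first.phi is None and first.omega is None
        assert last.psi is None
        assert first.psi is not None and last.phi is not None

    def test_missing_sidechain_atoms_give_none(self):
        res = Residue("A", 1, "ASN")
        res.add_atom(Atom("N", "N", [0, 0, 0]))
        res.add_atom(Atom("CA", "C", [1.5, 0, 0]))
        assert sidechain_dihedrals(res) == (None, None)


def _two_atom_structure(d):
    st_ = Structure()
    r1 = Residue("A", 1, "ALA")
    r1.add_atom(Atom("CB", "C", [0.0, 0.0, 0.0]))
    r5 = Residue("A", 5, "ALA")
    r5.add_atom(Atom("CB", "C", [d, 0.0, 0.0]))
    st_.add_residue(r1)
    st_.add_residue(r5)
    return st_


class TestContacts:
    def test_inside_cutoff_found(self):
        st_ = _two_atom_structure(3.9)
        recs = contacts(st_, st_.chain("A")[0], cutoff=4.0)
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(3.9)

    def test_outside_cutoff_empty(self):
        st_ = _two_atom_structure(4.1)
        assert contacts(st_, st_.chain("A")[0], cutoff=4.0) == []

    def test_empty_target_rejected(self, extended_strand):
        with pytest.raises(GeometryError):
            contacts(extended_strand, [], cutoff=4.0)

    def test_monotone_in_cutoff_and_matches_brute_force(self, alpha_helix):
        target = select_residue(alpha_helix, "A", 5)
        small = contacts(alpha_helix, target, cutoff=3.0)
        large = contacts(alpha_helix, target, cutoff=4.5)
        small_keys = {(r.atom_a, r.atom_b) for r in small}
        large_keys = {(r.atom_a, r.atom_b) for r in large}
        assert small_keys <= large_keys

        # O(n²) brute-force oracle over all heavy-atom pairs
        target_atoms = {id(a) for a in target.heavy_atoms()}
        expected = set()
        for res_o in alpha_helix.residues():
            for atom_o in res_o.heavy_atoms():
                if id(atom_o) in target_atoms:
                    continue
                for atom_t in target.heavy_atoms():
                    d = atom_t.distance(atom_o)
                    if d <= 4.5 and abs(res_o.number - 5) > 1:
                        expected.add((atom_t.name, res_o.number, atom_o.name))
        got = {
            (r.atom_a[1], int(r.atom_b[0].split("ALA")[1]), r.atom_b[1])
            for r in large
            if abs(int(r.atom_b[0].split("ALA")[1]) - 5) > 1
        }
        assert got == expected

    def test_sorted_by_distance(self, alpha_helix):
        recs = contacts(alpha_helix, select_residue(alpha_helix, "A", 5), cutoff=5.0)
        dists = [r.distance for r in recs]
        assert dists == sorted(dists)


class TestHydrogenBonds:
    def _pair(self, d):
        rd = Residue("A", 1, "ASN")
        rd.add_atom(Atom("N", "N", [0.0, 0.0, 0.0]))
        ra = Residue("A", 5, "ASP")
        ra.add_atom(Atom("O", "O", [d, 0.0, 0.0]))
        return (rd, rd["N"]), (ra, ra["O"])

    def test_distance_and_angle_accepted(self):
        donor, acceptor = self._pair(3.4)
        h = Residue("A", 1, "ASN")
        h.add_atom(Atom("H", "H", [1.0, 0.05, 0.0]))  # nearly linear: angle ~177°
        out = hydrogen_bonds([donor], [acceptor], require_angle=True,
                             hydrogens={id(donor[1]): (h, h["H"])})
        assert len(out) == 1
        assert out[0].angle_DHA > 140

    def test_low_angle_rejected_in_angle_mode(self):
        # a 3.3 Å pair at a ~75° angle fails the >140° criterion
        donor, acceptor = self._pair(3.3)
        h = Residue("A", 1, "ASN")
        h.add_atom(Atom("H", "H", [0.26, 0.97, 0.0]))
        hyd = {id(donor[1]): (h, h["H"])}
        out = hydrogen_bonds([donor], [acceptor], require_angle=True, hydrogens=hyd)
        assert out == []
        # same geometry passes in crystal (distance-only) mode
        assert len(hydrogen_bonds([donor], [acceptor])) == 1

    def test_long_distance_rejected_any_mode(self):
        donor, acceptor = self._pair(3.6)
        assert hydrogen_bonds([donor], [acceptor]) == []

    def test_angle_mode_without_hydrogens_is_error(self):
        donor, acceptor = self._pair(3.0)
        with pytest.raises(GeometryError):
            hydrogen_bonds([donor], [acceptor], require_angle=True)


class TestTurns:
    def test_helix_has_alpha_and_beta_turns(self, alpha_helix):
        turns = detect_turns(alpha_helix, "A", 1, 9)
        kinds = {t.kind for t in turns}
        assert "alpha" in kinds and "beta" in kinds

    def test_extended_strand_has_no_turns(self, extended_strand):
        assert detect_turns(extended_strand, "A", 1, 9) == []


class TestSuperpose:
    def test_identical_sets_rmsd_zero(self, rng):
        coords = rng.normal(size=(20, 3)) * 5
        res = superpose(coords, coords)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.retained_pairs == 20

    def test_recovers_known_transform(self, rng):
        coords = rng.normal(size=(30, 3)) * 5
        theta = 0.7
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0],
                [math.sin(theta), math.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        shift = np.array([1.0, -2.0, 3.0])
        reference = coords @ rot.T + shift
        res = superpose(coords, reference)
        assert res.rmsd < 1e-6
        np.testing.assert_allclose(res.rotation, rot, atol=1e-8)
        np.testing.assert_allclose(res.apply(coords), reference, atol=1e-8)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_outlier_rejected(self, rng):
        coords = rng.normal(size=(15, 3)) * 5
        reference = coords.copy()
        reference[7] += [10.0, 0.0, 0.0]
        res = superpose(coords, reference, cycles=5, reject_factor=2.0)
        assert res.retained_pairs == 14
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rmsd_never_increases_over_cycles(self, rng):
        coords = rng.normal(size=(40, 3)) * 5
        reference = coords + rng.normal(scale=0.3, size=coords.shape)
        reference[3] += 8
        rmsds = [
            superpose(coords, reference, cycles=c).rmsd for c in range(0, 6)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(rmsds, rmsds[1:]))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(GeometryError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
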