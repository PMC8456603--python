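"""Geometric H-bond detection, hydrogen placement, and latch reports."""

import math
import warnings

import numpy as np
import pytest

from motormetrics import detect_hbonds, latch_report, place_amide_hydrogens, read_structure
from motormetrics.hbonds import (
    Atom,
    PDBParseError,
    Structure,
    enumerate_donors_acceptors,
    write_pdb,
)
from motormetrics import synthetic as syn

TABLE_COUNTS = {
    "wt_cin8": 4,
    "cin8_nl_eg5": 4,
    "cin8_g522n": 2,
    "cin8_nl_eg5_ng": 2,
    "cin8_nl_cut7": 1,
    "cin8_nl_cut7_ng": 1,
}


def _minimal_pair(d_a=3.0, angle_deg=0.0):
    """A glycine donor N-H and a glycine acceptor O at chosen geometry."""
    h_dir = np.array(
        [math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg)), 0.0]
    )
    atoms = [
        Atom("A", 1, "GLY", "N", "N", 0.0, 0.0, 0.0),
        Atom("A", 1, "GLY", "H", "H", *(1.01 * h_dir)),
        Atom("A", 1, "GLY", "CA", "C", -1.0, -1.0, 0.0),
        Atom("A", 1, "GLY", "C", "C", -2.0, -1.5, 0.0),
        Atom("A", 1, "GLY", "O", "O", -2.5, -2.5, 0.0),
        Atom("A", 9, "GLY", "O", "O", d_a, 0.0, 0.0),
        Atom("A", 9, "GLY", "N", "N", d_a + 8.0, 0.0, 0.0),
        Atom("A", 9, "GLY", "CA", "C", d_a + 9.0, 1.0, 0.0),
        Atom("A", 9, "GLY", "C", "C", d_a + 10.0, 2.0, 0.0),
    ]
    return Structure(atoms)


class TestDetect:
    def test_ideal_geometry_bonds(self):
        bonds = detect_hbonds(_minimal_pair(d_a=3.0, angle_deg=0.0))
        assert len(bonds) == 1
        b = bonds[0]
        assert b.d_da_nm == pytest.approx(0.30)
        assert b.angle_adh_deg == pytest.approx(0.0, abs=1e-9)
        assert b.donor[1] == 1 and b.acceptor[1] == 9

    def test_printed_cutoffs_differ_at_0355_nm(self):
        s = _minimal_pair(d_a=3.55)
        assert len(detect_hbonds(s, dmax_nm=0.36)) == 1
        assert len(detect_hbonds(s, dmax_nm=0.35)) == 0

    def test_wide_angle_rejected(self):
        assert detect_hbonds(_minimal_pair(d_a=3.0, angle_deg=35.0)) == []

    def test_distance_monotonicity(self):
        s = _minimal_pair(d_a=3.3, angle_deg=20.0)
        tight = detect_hbonds(s, dmax_nm=0.34, angle_max_deg=25.0)
        loose = detect_hbonds(s, dmax_nm=0.36, angle_max_deg=30.0)
        assert len(loose) >= len(tight)

    def test_rigid_motion_invariance(self):
        s = _minimal_pair(d_a=3.2, angle_deg=15.0)
        theta = 0.7
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0],
                [math.sin(theta), math.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        shift = np.array([11.0, -3.0, 5.0])
        moved = Structure(
            [
                Atom(a.chain, a.resnum, a.resname, a.name, a.element,
                     *(rot @ a.pos + shift))
                for a in s.atoms
            ]
        )
        b0, b1 = detect_hbonds(s), detect_hbonds(moved)
        assert len(b0) == len(b1) == 1
        assert b1[0].d_da_nm == pytest.approx(b0[0].d_da_nm, abs=1e-6)
        assert b1[0].angle_adh_deg == pytest.approx(b0[0].angle_adh_deg, abs=1e-6)

    def test_matches_bruteforce_oracle_on_random_structures(self):
        for seed in range(8):
            s = _random_structure(seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = {
                    (b.donor[1], b.donor[3], b.acceptor[1], b.acceptor[3])
                    for b in detect_hbonds(s, allow_virtual_h=False)
                }
            assert got == _oracle_bonds(s)


def _random_structure(seed):
    """Random small glycine/serine cloud with explicit hydrogens."""
    rng = np.random.default_rng(200 + seed)
    atoms = []
    for r in range(1, 7):
        resname = "GLY" if r % 2 else "SER"
        base = rng.uniform(0, 9, 3)
        n = base + rng.normal(0, 0.5, 3)
        atoms += [
            Atom("A", r, resname, "N", "N", *n),
            Atom("A", r, resname, "H", "H", *(n + _rand_unit(rng) * 1.01)),
            Atom("A", r, resname, "CA", "C", *(base + rng.normal(0, 0.5, 3))),
            Atom("A", r, resname, "C", "C", *(base + rng.normal(0, 0.5, 3))),
            Atom("A", r, resname, "O", "O", *(base + rng.normal(0, 0.8, 3))),
        ]
        if resname == "SER":
            og = base + rng.normal(0, 0.8, 3)
            atoms += [
                Atom("A", r, resname, "OG", "O", *og),
                Atom("A", r, resname, "HG", "H", *(og + _rand_unit(rng) * 0.96)),
            ]
    return Structure(atoms)


def _rand_unit(rng):
    v = rng.normal(0, 1, 3)
    return v / np.linalg.norm(v)


def _oracle_bonds(s, dmax_a=3.6, angle_max=30.0, covalent_a=2.0):
    """All-pairs re-derivation of the criteria with explicit loops."""
    donors, acceptors = [], []
    for a in s.atoms:
        if a.name == "N" and a.resname != "PRO":
            hs = [h for h in s.atoms
                  if (h.chain, h.resnum) == (a.chain, a.resnum) and h.name == "H"]
            donors.append((a, hs))
        if a.name == "OG" and a.resname == "SER":
            hs = [h for h in s.atoms
                  if (h.chain, h.resnum) == (a.chain, a.resnum) and h.name == "HG"]
            donors.append((a, hs))
        if a.name == "O":
            acceptors.append(a)
        if a.name == "OG" and a.resname == "SER":
            acceptors.append(a)
    out = set()
    for d, hs in donors:
        if not hs:
            continue
        for acc in acceptors:
            if (d.chain, d.resnum, d.name) == (acc.chain, acc.resnum, acc.name):
                continue
            same_res = (d.chain, d.resnum) == (acc.chain, acc.resnum)
            backbone = {"N", "CA", "C", "O"}
            if same_res and d.name in backbone and acc.name in backbone:
                continue
            dist = float(np.linalg.norm(d.pos - acc.pos))
            if dist >= dmax_a or dist < covalent_a:
                continue
            da = (acc.pos - d.pos) / dist
            best = min(
                math.degrees(
                    math.acos(
                        np.clip(
                            np.dot(da, (h.pos - d.pos) / np.linalg.norm(h.pos - d.pos)),
                            -1,
                            1,
                        )
                    )
                )
                for h in hs
            )
            if best < angle_max:
                out.add((d.resnum, d.name, acc.resnum, acc.name))
    return out


class TestVariantFixtures:
    def test_bond_counts_match_the_reported_arrays(self, variant_fixtures):
        for name, structure in variant_fixtures.items():
            bonds = detect_hbonds(structure)
            assert len(bonds) == TABLE_COUNTS[name], name

    def test_wt_bond_set_is_exact(self, variant_fixtures):
        bonds = detect_hbonds(variant_fixtures["wt_cin8"])
        got = {
            frozenset(((b.donor[1], b.donor[3]), (b.acceptor[1], b.acceptor[3])))
            for b in bonds
        }
        want = {
            frozenset(((524, "N"), (412, "O"))),
            frozenset(((523, "OG"), (412, "O"))),
            frozenset(((524, "N"), (523, "OG"))),
            frozenset(((522, "N"), (157, "O"))),
        }
        assert got == want

    def test_latch_regions_and_conserved_flag(self, variant_fixtures):
        rep = latch_report(detect_hbonds(variant_fixtures["wt_cin8"]))
        assert rep.region_counts["N-latch"] == 1
        assert rep.region_counts["beta7-beta10"] == 2
        assert rep.region_counts["intra-NL"] == 1
        assert rep.conserved_latch_bond

        rep = latch_report(detect_hbonds(variant_fixtures["cin8_nl_cut7"]))
        assert rep.total == 1
        assert rep.region_counts["beta7-beta10"] == 0
        assert rep.conserved_latch_bond

        rep = latch_report(detect_hbonds(variant_fixtures["cin8_nl_cut7_ng"]))
        assert not rep.conserved_latch_bond

    def test_empty_bond_spec_detects_nothing(self):
        s = syn.build_hbond_fixture(
            syn.BondFixtureSpec(
                bonds=[], decoys=[((157, "GLY", "O"), (522, "GLY", "N"))]
            )
        )
        assert detect_hbonds(s) == []


class TestHydrogenPlacement:
    def _dipeptide(self):
        # residue 1 C placed at peptide-bond distance from residue 2 N
        atoms = [
            Atom("A", 1, "GLY", "N", "N", -2.4, 1.0, 0.0),
            Atom("A", 1, "GLY", "CA", "C", -2.0, 0.0, 0.0),
            Atom("A", 1, "GLY", "C", "C", -1.3, 0.0, 0.0),
            Atom("A", 1, "GLY", "O", "O", -1.3, 1.2, 0.0),
            Atom("A", 2, "GLY", "N", "N", 0.0, 0.0, 0.0),
            Atom("A", 2, "GLY", "CA", "C", 0.9, 1.1, 0.0),
            Atom("A", 2, "GLY", "C", "C", 2.3, 0.9, 0.0),
            Atom("A", 2, "GLY", "O", "O", 2.9, -0.1, 0.0),
        ]
        return Structure(atoms)

    def test_amide_h_bisects_c_n_ca(self):
        s = place_amide_hydrogens(self._dipeptide())
        h = s.get("A", 2, "H")
        assert h is not None
        n, ca = s.get("A", 2, "N"), s.get("A", 2, "CA")
        c_prev = s.get("A", 1, "C")
        assert np.linalg.norm(h.pos - n.pos) == pytest.approx(1.01, abs=1e-9)

        def angle(a, b, c):
            u = (a.pos - b.pos) / np.linalg.norm(a.pos - b.pos)
            v = (c.pos - b.pos) / np.linalg.norm(c.pos - b.pos)
            return math.degrees(math.acos(np.clip(np.dot(u, v), -1, 1)))

        assert abs(angle(c_prev, n, h) - angle(ca, n, h)) < 1.0

    def test_proline_gets_no_hydrogen(self):
        atoms = [
            Atom("A", 1, "GLY", "C", "C", -1.3, 0.0, 0.0),
            Atom("A", 2, "PRO", "N", "N", 0.0, 0.0, 0.0),
            Atom("A", 2, "PRO", "CA", "C", 1.0, 1.0, 0.0),
        ]
        s = place_amide_hydrogens(Structure(atoms))
        assert s.get("A", 2, "H") is None

    def test_existing_hydrogens_preserved(self):
        base = self._dipeptide()
        with_h = place_amide_hydrogens(base)
        again = place_amide_hydrogens(with_h)
        assert len(again) == len(with_h)

    def test_chain_terminus_skipped(self):
        s = place_amide_hydrogens(
            Structure(
                [
                    Atom("A", 5, "GLY", "N", "N", 0.0, 0.0, 0.0),
                    Atom("A", 5, "GLY", "CA", "C", 1.4, 0.0, 0.0),
                ]
            )
        )
        assert s.get("A", 5, "H") is None


class TestEnumerate:
    def test_glycine_roles(self):
        s = _minimal_pair()
        donors, acceptors = enumerate_donors_acceptors(s)
        donor_names = {(d.resnum, d.name) for d, _ in donors}
        assert (1, "N") in donor_names
        assert any(a.name == "O" for a in acceptors)

    def test_asparagine_sidechain_roles(self):
        atoms = [
            Atom("A", 3, "ASN", "N", "N", 0, 0, 0),
            Atom("A", 3, "ASN", "CA", "C", 1.4, 0, 0),
            Atom("A", 3, "ASN", "O", "O", 2.0, 1.0, 0),
            Atom("A", 3, "ASN", "ND2", "N", 3.0, 3.0, 0),
            Atom("A", 3, "ASN", "HD21", "H", 3.5, 3.8, 0),
            Atom("A", 3, "ASN", "OD1", "O", 4.0, 2.0, 0),
        ]
        donors, acceptors = enumerate_donors_acceptors(Structure(atoms))
        assert any(d.name == "ND2" and hs for d, hs in donors)
        assert any(a.name == "OD1" for a in acceptors)

    def test_proline_has_no_backbone_donor(self):
        atoms = [
            Atom("A", 4, "PRO", "N", "N", 0, 0, 0),
            Atom("A", 4, "PRO", "O", "O", 3, 0, 0),
        ]
        donors, _ = enumerate_donors_acceptors(Structure(atoms))
        assert not any(d.name == "N" for d, _ in donors)


class TestPDBIO:
    def test_roundtrip_preserves_coordinates(self, variant_fixtures):
        s = variant_fixtures["wt_cin8"]
        text = write_pdb(s)
        back = read_structure(text)
        assert len(back) == len(s)
        for a in s.atoms:
            b = back.get(a.chain, a.resnum, a.name)
            assert b is not None
            assert np.allclose(a.pos, b.pos, atol=1e-3)
        assert detect_hbonds(back) and len(detect_hbonds(back)) == 4

    def test_no_atom_records_is_an_error(self):
        with pytest.raises(PDBParseError, match="no ATOM"):
            read_structure("HEADER only\nEND\n")

    def test_fixture_counts_from_file(self, tmp_path, variant_fixtures):
        p = tmp_path / "wt.pdb"
        write_pdb(variant_fixtures["wt_cin8"], str(p))
        s = read_structure(p.read_text())
        assert len(detect_hbonds(s)) == 4
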