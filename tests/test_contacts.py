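"""Geometric contact criteria: hydrogen bonds, van der Waals, salt bridges."""

import numpy as np
import pytest

from lipropen.contacts import (
    GeometryParams,
    VDW_RADII,
    classify_contacts,
    detect_hbonds,
    detect_salt_bridges,
    detect_vdw,
    find_contacts,
    hbond_geometry_ok,
    place_polar_hydrogens,
    residue_binding_flags,
)

from conftest import make_chain, make_lipid

P = GeometryParams()


def _aa_dir(angle_deg_val):
    a = np.radians(angle_deg_val)
    return np.array([np.cos(a), np.sin(a), 0.0])


class TestHbondGeometry:
    """Each criterion is individually necessary: starting from a passing
    arrangement, pushing any one quantity across its threshold flips the
    decision."""

    D = np.zeros(3)
    H = np.array([1.2, 0.0, 0.0])
    A = np.array([3.5, 0.0, 0.0])
    AA = A + 1.4 * _aa_dir(-20.0)  # D-A-AA = H-A-AA = 160 degrees

    def test_well_formed_bond_accepted(self):
        assert hbond_geometry_ok(self.D, self.H, self.A, [self.AA], P)

    def test_donor_acceptor_distance_criterion(self):
        a = np.array([3.95, 0.0, 0.0])
        h = np.array([1.5, 0.0, 0.0])  # keeps H-A at 2.45
        assert not hbond_geometry_ok(self.D, h, a, [a + 1.4 * _aa_dir(-20.0)], P)

    def test_hydrogen_acceptor_distance_criterion(self):
        h = np.array([0.8, 0.0, 0.0])  # H-A = 2.7 > 2.5, D-A unchanged
        assert not hbond_geometry_ok(self.D, h, self.A, [self.AA], P)

    def test_dha_angle_criterion(self):
        h = np.array([1.5, 1.8, 0.0])  # D-H-A about 80 degrees
        a = np.array([3.0, 0.0, 0.0])
        aa = a + 1.4 * _aa_dir(-20.0)
        assert not hbond_geometry_ok(self.D, h, a, [aa], P)

    def test_antecedent_angle_criterion(self):
        aa = self.A + 1.4 * _aa_dir(95.0)  # D-A-AA = 85 degrees
        assert not hbond_geometry_ok(self.D, self.H, self.A, [aa], P)

    def test_all_antecedents_must_pass(self):
        good = self.AA
        bad = self.A + 1.4 * _aa_dir(95.0)
        assert hbond_geometry_ok(self.D, self.H, self.A, [good], P)
        assert not hbond_geometry_ok(self.D, self.H, self.A, [good, bad], P)

    def test_aromatic_axis_criterion(self):
        # axis nearly along A->D passes; a 30-degree tilt fails
        ax_good = self.A + _aa_dir(175.0)
        ax_bad = self.A + _aa_dir(150.0)
        assert hbond_geometry_ok(self.D, self.H, self.A, [self.AA], P,
                                 aromatic_axis_point=ax_good)
        assert not hbond_geometry_ok(self.D, self.H, self.A, [self.AA], P,
                                     aromatic_axis_point=ax_bad)


class TestHydrogenPlacement:
    def test_backbone_amide_h_mid_chain(self):
        chain = make_chain([
            ("ALA", 1, [("N", "N", (0, 1.3, 0)), ("CA", "C", (0, 0, 0)),
                        ("C", "C", (1.3, -0.6, 0)), ("O", "O", (1.3, -1.8, 0))]),
            ("ALA", 2, [("N", "N", (2.4, 0.2, 0)), ("CA", "C", (3.6, -0.5, 0)),
                        ("C", "C", (4.9, 0.3, 0)), ("O", "O", (4.9, 1.5, 0))]),
        ])
        out = place_polar_hydrogens(chain)
        res2 = out.residues[1]
        hs = [a for a in res2.atoms if a.element == "H"]
        assert len(hs) == 1 and hs[0].parent_name == "N"
        n = res2.atom("N").xyz
        assert np.linalg.norm(hs[0].xyz - n) == pytest.approx(1.0, abs=1e-6)
        # sp2: H opposes the bisector of N->CA and N->C(prev)
        bis = (res2.atom("CA").xyz - n) / np.linalg.norm(res2.atom("CA").xyz - n)
        cprev = chain.residues[0].atom("C").xyz
        bis = bis + (cprev - n) / np.linalg.norm(cprev - n)
        cos = np.dot(hs[0].xyz - n, -bis) / (np.linalg.norm(bis))
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_first_residue_and_proline_get_no_backbone_h(self):
        chain = make_chain([
            ("ALA", 1, [("N", "N", (0, 1.3, 0)), ("CA", "C", (0, 0, 0)),
                        ("C", "C", (1.3, -0.6, 0)), ("O", "O", (1.3, -1.8, 0))]),
            ("PRO", 2, [("N", "N", (2.4, 0.2, 0)), ("CA", "C", (3.6, -0.5, 0)),
                        ("C", "C", (4.9, 0.3, 0)), ("O", "O", (4.9, 1.5, 0))]),
        ])
        out = place_polar_hydrogens(chain)
        assert all(a.element != "H" for r in out.residues for a in r.atoms)

    def test_arginine_guanidinium_has_five_donor_hydrogens(self):
        # idealized planar guanidinium built by hand
        cz = np.array([0.0, 0.0, 0.0])
        ne = np.array([-1.33, 0.0, 0.0])
        nh1 = 1.33 * _aa_dir(60.0)
        nh2 = 1.33 * _aa_dir(-60.0)
        cd = ne + 1.46 * _aa_dir(120.0)
        chain = make_chain([
            ("ARG", 1, [("N", "N", (-6, 0, 0)), ("CA", "C", (-5, 0, 0)),
                        ("C", "C", (-5, 1, 0)), ("O", "O", (-5, 2, 0)),
                        ("CD", "C", tuple(cd)), ("NE", "N", tuple(ne)),
                        ("CZ", "C", tuple(cz)), ("NH1", "N", tuple(nh1)),
                        ("NH2", "N", tuple(nh2))]),
        ])
        out = place_polar_hydrogens(chain)
        hs = [a for a in out.residues[0].atoms if a.element == "H"]
        assert len(hs) == 5  # NE x1, NH1 x2, NH2 x2 (no backbone H at chain start)
        parents = sorted(a.parent_name for a in hs)
        assert parents == ["NE", "NH1", "NH1", "NH2", "NH2"]

    def test_glycine_only_backbone_nh(self):
        chain = make_chain([
            ("ALA", 1, [("N", "N", (0, 1.3, 0)), ("CA", "C", (0, 0, 0)),
                        ("C", "C", (1.3, -0.6, 0)), ("O", "O", (1.3, -1.8, 0))]),
            ("GLY", 2, [("N", "N", (2.4, 0.2, 0)), ("CA", "C", (3.6, -0.5, 0)),
                        ("C", "C", (4.9, 0.3, 0)), ("O", "O", (4.9, 1.5, 0))]),
        ])
        out = place_polar_hydrogens(chain)
        hs = [a for r in out.residues for a in r.atoms if a.element == "H"]
        assert len(hs) == 1 and hs[0].parent_name == "N"


def _ser_chain(og_xyz=(2.2, 1.2, 0.0)):
    return make_chain([
        ("SER", 1, [("N", "N", (-1.2, 0.8, 0)), ("CA", "C", (0, 0, 0)),
                    ("C", "C", (0.5, -1.3, 0)), ("O", "O", (1.7, -1.5, 0)),
                    ("CB", "C", (1.5, 0, 0)), ("OG", "O", og_xyz)]),
    ])


def _acceptor_direction():
    """Unit vector at the tetrahedral angle from the CB->OG bond of
    _ser_chain, in the z=0 plane: a hydroxyl hydrogen can point straight
    at an acceptor placed along it."""
    u = np.array([1.5 - 2.2, -1.2, 0.0])
    u /= np.linalg.norm(u)
    c, s = np.cos(np.radians(109.47)), np.sin(np.radians(109.47))
    return np.array([u[0] * c - u[1] * s, u[0] * s + u[1] * c, 0.0])


def _phosphate_lipid(o_xyz, p_offset=None):
    o = np.asarray(o_xyz, dtype=float)
    p = o + (np.asarray(p_offset) if p_offset is not None else np.array([1.6, 0, 0]))
    return make_lipid(
        [("O3", "O", tuple(o)), ("P1", "P", tuple(p))],
        head={"O3", "P1"}, tail=set(),
        bonds=(("O3", "P1"),),
    )


class TestHbondDetection:
    def test_serine_donates_to_lipid_phosphate_oxygen(self):
        chain = _ser_chain()
        og = np.array([2.2, 1.2, 0.0])
        direction = _acceptor_direction()
        lip = _phosphate_lipid(og + 2.8 * direction, p_offset=1.6 * direction)
        chain_h = place_polar_hydrogens(chain, [lip])
        recs = detect_hbonds(chain_h, [lip], P)
        assert [(r.residue_atom, r.lipid_atom, r.contact_type) for r in recs] == [
            ("OG", "O3", "hbond")
        ]
        assert recs[0].distance == pytest.approx(2.8, abs=1e-6)

    def test_acceptor_beyond_da_max_not_detected(self):
        og = np.array([2.2, 1.2, 0.0])
        direction = _acceptor_direction()
        lip = _phosphate_lipid(og + 4.1 * direction, p_offset=1.6 * direction)
        chain_h = place_polar_hydrogens(_ser_chain(), [lip])
        assert detect_hbonds(chain_h, [lip], P) == []

    def test_acceptor_without_antecedent_skipped(self):
        og = np.array([2.2, 1.2, 0.0])
        o = og + 2.8 * _acceptor_direction()
        lip = make_lipid([("O3", "O", tuple(o))], head={"O3"}, tail=set(), bonds=())
        chain_h = place_polar_hydrogens(_ser_chain(), [lip])
        assert detect_hbonds(chain_h, [lip], P) == []


class TestVdw:
    def _ala(self, cb=(0.0, 0.0, 0.0)):
        return make_chain([
            ("ALA", 1, [("N", "N", (-20, 0, 0)), ("CA", "C", (-21, 0, 0)),
                        ("C", "C", (-22, 0, 0)), ("O", "O", (-23, 0, 0)),
                        ("CB", "C", cb)]),
        ])

    def test_carbon_pair_inside_radii_sum_plus_tolerance(self):
        lip = make_lipid([("C1", "C", (3.5, 0, 0))], head=set(), tail={"C1"})
        recs = detect_vdw(self._ala(), [lip], P)
        assert [(r.residue_atom, r.lipid_atom) for r in recs] == [("CB", "C1")]

    def test_carbon_pair_outside_cutoff(self):
        lip = make_lipid([("C1", "C", (4.0, 0, 0))], head=set(), tail={"C1"})
        assert detect_vdw(self._ala(), [lip], P) == []

    def test_hbonded_pair_excluded(self):
        lip = make_lipid([("C1", "C", (3.5, 0, 0))], head=set(), tail={"C1"})
        excl = {(("ALA", 1, "CB"), ("L_ZZL_1", "C1"))}
        assert detect_vdw(self._ala(), [lip], P, exclude_pairs=excl) == []

    def test_unknown_element_falls_back_to_default_radius(self):
        lip = make_lipid([("X1", "XX", (3.85, 0, 0))], head=set(), tail={"X1"})
        recs = detect_vdw(self._ala(), [lip], P)  # 1.7 + 1.7 + 0.5 = 3.9
        assert len(recs) == 1


class TestSaltBridges:
    def _lys(self, nz=(0.0, 0.0, 0.0)):
        return make_chain([
            ("LYS", 1, [("N", "N", (-20, 0, 0)), ("CA", "C", (-21, 0, 0)),
                        ("C", "C", (-22, 0, 0)), ("O", "O", (-23, 0, 0)),
                        ("NZ", "N", nz)]),
        ])

    def test_lysine_to_phosphate_oxygen_within_cutoff(self):
        lip = _phosphate_lipid((3.5, 0, 0))
        recs = detect_salt_bridges(self._lys(), [lip], P)
        assert [(r.residue_atom, r.lipid_atom, r.contact_type) for r in recs] == [
            ("NZ", "O3", "salt")
        ]

    def test_beyond_cutoff_not_detected(self):
        lip = _phosphate_lipid((4.5, 0, 0))
        assert detect_salt_bridges(self._lys(), [lip], P) == []

    def test_neutral_side_chain_never_salt(self):
        chain = make_chain([
            ("LEU", 1, [("N", "N", (-20, 0, 0)), ("CA", "C", (-21, 0, 0)),
                        ("C", "C", (-22, 0, 0)), ("O", "O", (-23, 0, 0)),
                        ("CD1", "C", (3.0, 0, 0))]),
        ])
        lip = _phosphate_lipid((0.0, 0, 0))
        assert detect_salt_bridges(chain, [lip], P) == []
        vdw = detect_vdw(chain, [lip], P)
        assert all(r.contact_type == "vdw" for r in vdw) and vdw

    def test_ester_oxygen_is_not_a_charge_centre(self):
        # oxygen bonded only to carbons carries no formal charge
        lip = make_lipid([("O1", "O", (3.0, 0, 0)), ("C1", "C", (4.4, 0, 0))],
                         head={"O1", "C1"}, tail=set(), bonds=(("O1", "C1"),))
        assert detect_salt_bridges(self._lys(), [lip], P) == []


class TestClassification:
    def test_flags_follow_contacted_groups(self):
        lip = make_lipid(
            [("O1", "O", (0, 0, 0)), ("C5", "C", (10, 0, 0))],
            head={"O1"}, tail={"C5"},
        )
        chain = make_chain([
            ("ALA", 1, [("CB", "C", (3.0, 0, 0))]),       # head only
            ("ALA", 2, [("CB", "C", (8.0, 0, 0))]),       # tail only
            ("ALA", 3, [("CB", "C", (50, 0, 0))]),        # no contact
        ])
        recs = classify_contacts(detect_vdw(chain, [lip], P),
                                 {lip.instance_id: lip.partition})
        flags = residue_binding_flags(recs)
        assert flags[("ALA", 1)] == {"head": True, "tail": False}
        assert flags[("ALA", 2)] == {"head": False, "tail": True}
        assert ("ALA", 3) not in flags

    def test_residue_contacting_both_groups_gets_both_flags(self):
        lip = make_lipid(
            [("O1", "O", (3.0, 0, 0)), ("C5", "C", (0, 3.0, 0))],
            head={"O1"}, tail={"C5"},
        )
        chain = make_chain([("ALA", 1, [("CB", "C", (0, 0, 0))])])
        recs = classify_contacts(detect_vdw(chain, [lip], P),
                                 {lip.instance_id: lip.partition})
        assert residue_binding_flags(recs)[("ALA", 1)] == {"head": True, "tail": True}

    def test_empty_contact_list_gives_no_flags(self):
        assert residue_binding_flags([]) == {}


def _random_scene(rng, n_res=40, n_lip_atoms=60):
    """Random coordinates for oracle comparisons (vdW + salt)."""
    res_names = rng.choice(["ALA", "LEU", "LYS", "ASP", "ARG"], size=n_res)
    residues = []
    for i, name in enumerate(res_names):
        atoms = [("CA", "C", tuple(rng.uniform(-15, 15, 3)))]
        if name == "LYS":
            atoms.append(("NZ", "N", tuple(rng.uniform(-15, 15, 3))))
        elif name == "ASP":
            atoms.append(("OD1", "O", tuple(rng.uniform(-15, 15, 3))))
        elif name == "ARG":
            atoms.append(("NH1", "N", tuple(rng.uniform(-15, 15, 3))))
        else:
            atoms.append(("CB", "C", tuple(rng.uniform(-15, 15, 3))))
        residues.append((name, i + 1, atoms))
    chain = make_chain(residues)

    lip_atoms, bonds = [], []
    names = []
    for j in range(n_lip_atoms):
        el = ["C", "O", "P"][j % 3]
        nm = f"{el}{j}"
        names.append(nm)
        lip_atoms.append((nm, el, tuple(rng.uniform(-15, 15, 3))))
    # bond every O to the following P so phosphate oxygens exist
    for j in range(0, n_lip_atoms - 1):
        if lip_atoms[j][1] == "O" and lip_atoms[j + 1][1] == "P":
            bonds.append((lip_atoms[j][0], lip_atoms[j + 1][0]))
    head = {nm for nm, el, _ in lip_atoms if el != "C"}
    tail = {nm for nm, el, _ in lip_atoms if el == "C"}
    lip = make_lipid(lip_atoms, head=head, tail=tail, bonds=tuple(bonds))
    return chain, lip


class TestOracleEquivalence:
    def test_vdw_matches_brute_force_all_pairs(self, rng):
        for _ in range(3):
            chain, lip = _random_scene(rng)
            got = {
                (r.residue_seq, r.residue_atom, r.lipid_atom)
                for r in detect_vdw(chain, [lip], P)
            }
            expected = set()
            for res in chain.residues:
                for a in res.atoms:
                    for la in lip.heavy_atoms():
                        r1 = VDW_RADII.get(a.element, 1.7)
                        r2 = VDW_RADII.get(la.element, 1.7)
                        d = float(np.linalg.norm(a.xyz - la.xyz))
                        if d <= r1 + r2 + P.vdw_tolerance:
                            expected.add((res.seq_id, a.name, la.name))
            assert got == expected

    def test_salt_matches_brute_force_all_pairs(self, rng):
        pos = {"LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"}}
        neg = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
        for _ in range(3):
            chain, lip = _random_scene(rng)
            phosphate_os = {
                a for a, b in lip.bonds
            }  # every bonded O here is an O-P pair by construction
            got = {
                (r.residue_seq, r.residue_atom, r.lipid_atom)
                for r in detect_salt_bridges(chain, [lip], P)
            }
            expected = set()
            for res in chain.residues:
                for a in res.atoms:
                    charge = (a.name in pos.get(res.name, ())) - (
                        a.name in neg.get(res.name, ())
                    )
                    if charge == 0:
                        continue
                    for la in lip.heavy_atoms():
                        lcharge = -1 if la.name in phosphate_os else 0
                        if lcharge == -charge and np.linalg.norm(
                            a.xyz - la.xyz
                        ) <= P.salt_bridge_max:
                            expected.add((res.seq_id, a.name, la.name))
            assert got == expected

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        chain, lip = _random_scene(rng, n_res=20, n_lip_atoms=30)
        rot = Rotation.random(random_state=7)
        shift = np.array([11.0, -4.0, 2.5])

        def move_chain(c):
            residues = []
            for res in c.residues:
                atoms = [
                    (a.name, a.element, tuple(rot.apply(a.xyz) + shift))
                    for a in res.atoms
                ]
                residues.append((res.name, res.seq_id, atoms))
            return make_chain(residues)

        def move_lipid(l):
            atoms = [
                (a.name, a.element, tuple(rot.apply(a.xyz) + shift))
                for a in l.atoms
            ]
            return make_lipid(atoms, head=set(l.partition.head_atoms),
                              tail=set(l.partition.tail_atoms), bonds=l.bonds)

        def signature(records):
            return sorted(
                (r.residue_seq, r.residue_atom, r.lipid_atom, r.contact_type,
                 round(r.distance, 6))
                for r in records
            )

        base = signature(find_contacts(chain, [lip], P))
        moved = signature(find_contacts(move_chain(chain), [move_lipid(lip)], P))
        assert base == moved
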