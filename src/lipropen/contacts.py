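"""Residue-lipid contact detection with HBPLUS-style geometric criteria.

Three contact classes are detected between protein residues and lipid
molecules:

* **hydrogen bonds** — polar hydrogens are first placed on the protein at
  idealized geometry; a bond D-H...A is accepted when the donor-acceptor
  distance is below ``da_max`` (3.9 Å), the hydrogen-acceptor distance is at
  most ``ha_max`` (2.5 Å), and the D-H-A, D-A-AA and H-A-AA angles (AA =
  acceptor antecedent) all exceed ``min_angle`` (90°).  For aromatic
  acceptors the D-A-AX and H-A-AX angles to the ring axis must additionally
  be below ``aromatic_axis_max`` (20°).
* **van der Waals** — heavy-atom pairs within the sum of the element radii
  plus ``vdw_tolerance`` (0.5 Å), excluding pairs already hydrogen bonded.
* **salt bridges** — oppositely charged heavy atoms (basic side-chain N vs.
  lipid phosphate O; acidic carboxylate O vs. lipid quaternary amine N)
  within ``salt_bridge_max`` (4.0 Å).

Lipid hydrogens are never placed: lipid atoms act as hydrogen-bond
acceptors and charge centres only, since acyl and choline hydrogen
positions are unreliable in deposited coordinates.  Each contact is tagged
head/tail according to the lipid's atom partition.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .lipid_model import LipidAtomPartition
from .structure_io import Atom, LipidInstance, ProteinChain, Residue

logger = logging.getLogger(__name__)

__all__ = [
    "GeometryParams",
    "ContactRecord",
    "place_polar_hydrogens",
    "detect_hbonds",
    "detect_vdw",
    "detect_salt_bridges",
    "classify_contacts",
    "find_contacts",
    "residue_binding_flags",
    "hbond_geometry_ok",
    "VDW_RADII",
]

# Per-element van der Waals radii (Å); a compact table standing in for the
# het-dictionary radii, overridable via load_radii().
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
FALLBACK_RADIUS = 1.70

N_H_BOND_LENGTH = 1.0
O_H_BOND_LENGTH = 1.0
TETRAHEDRAL = 109.47  # degrees


@dataclass(frozen=True)
class GeometryParams:
    """Geometric thresholds for contact detection (all distances in Å,
    angles in degrees)."""

    da_max: float = 3.9
    ha_max: float = 2.5
    min_angle: float = 90.0
    aromatic_axis_max: float = 20.0
    vdw_tolerance: float = 0.5
    salt_bridge_max: float = 4.0

    def __post_init__(self) -> None:
        for name in ("da_max", "ha_max", "vdw_tolerance", "salt_bridge_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("min_angle", "aromatic_axis_max"):
            if not 0 < getattr(self, name) < 180:
                raise ValueError(f"{name} must be in (0, 180) degrees")


@dataclass(frozen=True)
class ContactRecord:
    chain_id: str
    residue_name: str
    residue_seq: int
    residue_atom: str
    instance_id: str
    lipid_atom: str
    contact_type: str  # {"hbond", "vdw", "salt"}
    distance: float
    lipid_group: str | None = None  # {"head", "tail"}

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.residue_name, self.residue_seq)


def load_radii(path: str | Path) -> dict[str, float]:
    """Read a per-element radius table (TSV: ELEMENT, RADIUS)."""
    radii = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0].upper() == "ELEMENT":
                continue
            radii[row[0].upper()] = float(row[1])
    return radii


def _radius(element: str, radii: Mapping[str, float]) -> float:
    r = radii.get(element.upper())
    if r is None:
        logger.warning("no vdW radius for element %s; using %.2f", element, FALLBACK_RADIUS)
        return FALLBACK_RADIUS
    return r


# --------------------------------------------------------------------------
# geometry helpers

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle A-B-C at vertex B, in degrees."""
    u, v = _unit(a - b), _unit(c - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def _rotate(v: np.ndarray, axis: np.ndarray, degrees: float) -> np.ndarray:
    return Rotation.from_rotvec(np.radians(degrees) * _unit(axis)).apply(v)


def _perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(_unit(v), ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, ref))


# --------------------------------------------------------------------------
# hydrogen placement

# Side-chain donor geometry: atom -> (mode, support atoms).
#   sp2_1: one in-plane H opposing the bisector of two heavy neighbours
#   sp2_2: two planar H on an -NH2 (support = bonded C, plane reference)
#   rot_1 / rot_3: rotatable hydroxyl / sp3 amine, orientation optimized
_SIDECHAIN_DONORS: dict[str, list[tuple[str, str, tuple[str, ...]]]] = {
    "ARG": [
        ("NE", "sp2_1", ("CD", "CZ")),
        ("NH1", "sp2_2", ("CZ", "NE")),
        ("NH2", "sp2_2", ("CZ", "NE")),
    ],
    "LYS": [("NZ", "rot_3", ("CE",))],
    "HIS": [("ND1", "sp2_1", ("CG", "CE1")), ("NE2", "sp2_1", ("CD2", "CE1"))],
    "TRP": [("NE1", "sp2_1", ("CD1", "CE2"))],
    "ASN": [("ND2", "sp2_2", ("CG", "OD1"))],
    "GLN": [("NE2", "sp2_2", ("CD", "OE1"))],
    "SER": [("OG", "rot_1", ("CB",))],
    "THR": [("OG1", "rot_1", ("CB",))],
    "TYR": [("OH", "rot_1", ("CZ",))],
}


def _sp2_one(x: np.ndarray, n1: np.ndarray, n2: np.ndarray, length: float) -> list[np.ndarray]:
    direction = -( _unit(n1 - x) + _unit(n2 - x))
    return [x + length * _unit(direction)]


def _sp2_two(x: np.ndarray, c: np.ndarray, ref: np.ndarray, length: float) -> list[np.ndarray]:
    # planar amine: rotate the X->C direction by ±120° about the plane normal
    normal = np.cross(c - x, ref - c)
    if np.linalg.norm(normal) < 1e-9:
        normal = _perpendicular(c - x)
    to_c = _unit(c - x)
    return [x + length * _unit(_rotate(to_c, normal, s * 120.0)) for s in (+1, -1)]


def _rotatable(
    x: np.ndarray,
    anchor: np.ndarray,
    n_h: int,
    length: float,
    acceptor_coords: np.ndarray | None,
    step: float = 10.0,
) -> list[np.ndarray]:
    """Hydrogens on a rotatable donor (hydroxyl or sp3 amine), at the
    tetrahedral angle from the anchor bond; the torsion is scanned in
    ``step``-degree increments and the orientation minimizing the nearest
    hydrogen-acceptor distance is kept (deterministic torsion 0 when no
    acceptor is in range)."""
    a = _unit(anchor - x)
    p1 = _perpendicular(a)
    p2 = _unit(np.cross(a, p1))
    cos_t, sin_t = np.cos(np.radians(TETRAHEDRAL)), np.sin(np.radians(TETRAHEDRAL))

    def hydrogens(chi_deg: float) -> list[np.ndarray]:
        out = []
        for k in range(n_h):
            chi = np.radians(chi_deg + 360.0 * k / max(n_h, 1))
            d = cos_t * a + sin_t * (np.cos(chi) * p1 + np.sin(chi) * p2)
            out.append(x + length * _unit(d))
        return out

    if acceptor_coords is None or len(acceptor_coords) == 0:
        return hydrogens(0.0)
    best_chi, best_score = 0.0, np.inf
    for chi in np.arange(0.0, 360.0, step):
        hs = hydrogens(chi)
        score = min(
            float(np.min(np.linalg.norm(acceptor_coords - h, axis=1))) for h in hs
        )
        if score < best_score - 1e-9:
            best_chi, best_score = chi, score
    return hydrogens(best_chi)


def place_polar_hydrogens(
    chain: ProteinChain,
    lipids: Sequence[LipidInstance] = (),
    params: GeometryParams | None = None,
) -> ProteinChain:
    """Return a copy of the chain with polar hydrogens added.

    Backbone amide hydrogens are placed in the peptide plane (sp2, 1.0 Å);
    side-chain donors follow standard hybridization geometry.  Rotatable
    donors (SER/THR/TYR hydroxyls, LYS ammonium) are oriented toward the
    nearest lipid acceptor when one is within hydrogen-bonding range.
    Residues with missing support atoms are skipped with a warning.
    """
    params = params or GeometryParams()
    acceptor_coords = None
    if lipids:
        pts = [a.xyz for lip in lipids for a in lip.heavy_atoms() if a.element == "O"]
        if pts:
            acceptor_coords = np.asarray(pts)

    new_residues: list[Residue] = []
    prev: Residue | None = None
    for res in chain.residues:
        added: list[Atom] = []
        # backbone amide H (absent on PRO and on chain/gap starts)
        n_at, ca = res.atom("N"), res.atom("CA")
        if (
            res.name != "PRO"
            and n_at is not None
            and ca is not None
            and prev is not None
            and prev.seq_id == res.seq_id - 1
            and prev.atom("C") is not None
        ):
            (h,) = _sp2_one(n_at.xyz, ca.xyz, prev.atom("C").xyz, N_H_BOND_LENGTH)
            added.append(Atom("H", "H", tuple(h), parent_name="N"))

        local_acceptors = acceptor_coords
        if acceptor_coords is not None and ca is not None:
            near = np.linalg.norm(acceptor_coords - ca.xyz, axis=1) < 12.0
            local_acceptors = acceptor_coords[near] if near.any() else None

        for donor_name, mode, support in _SIDECHAIN_DONORS.get(res.name, []):
            donor = res.atom(donor_name)
            sup = [res.atom(s) for s in support]
            if donor is None or any(s is None for s in sup):
                if donor is not None:
                    logger.warning(
                        "%s%d: missing support atoms for donor %s; skipped",
                        res.name, res.seq_id, donor_name,
                    )
                continue
            length = O_H_BOND_LENGTH if donor.element == "O" else N_H_BOND_LENGTH
            if mode == "sp2_1":
                hs = _sp2_one(donor.xyz, sup[0].xyz, sup[1].xyz, length)
            elif mode == "sp2_2":
                hs = _sp2_two(donor.xyz, sup[0].xyz, sup[1].xyz, length)
            elif mode == "rot_1":
                hs = _rotatable(donor.xyz, sup[0].xyz, 1, length, local_acceptors)
            else:  # rot_3
                hs = _rotatable(donor.xyz, sup[0].xyz, 3, length, local_acceptors)
            for k, h in enumerate(hs, start=1):
                name = f"H{donor_name[1:]}{k if len(hs) > 1 else ''}"
                added.append(Atom(name, "H", tuple(h), parent_name=donor_name))

        new_residues.append(Residue(res.name, res.seq_id, res.atoms + tuple(added)))
        prev = res
    return replace(chain, residues=tuple(new_residues))


# --------------------------------------------------------------------------
# hydrogen-bond detection

def hbond_geometry_ok(
    d: np.ndarray,
    h: np.ndarray,
    a: np.ndarray,
    antecedents: Sequence[np.ndarray],
    params: GeometryParams | None = None,
    aromatic_axis_point: np.ndarray | None = None,
) -> bool:
    """Evaluate the five geometric hydrogen-bond criteria for one
    D-H...A(-AA) arrangement.  All antecedent angles must pass; the axis
    criterion applies only when ``aromatic_axis_point`` is given."""
    p = params or GeometryParams()
    if np.linalg.norm(a - d) >= p.da_max:
        return False
    if np.linalg.norm(a - h) > p.ha_max:
        return False
    if angle_deg(d, h, a) <= p.min_angle:
        return False
    for aa in antecedents:
        if angle_deg(d, a, aa) <= p.min_angle or angle_deg(h, a, aa) <= p.min_angle:
            return False
    if aromatic_axis_point is not None:
        if (
            angle_deg(d, a, aromatic_axis_point) >= p.aromatic_axis_max
            or angle_deg(h, a, aromatic_axis_point) >= p.aromatic_axis_max
        ):
            return False
    return True


def _lipid_acceptors(lipid: LipidInstance) -> list[tuple[Atom, list[Atom]]]:
    """Lipid acceptors and their heavy-atom antecedents: every oxygen, and
    nitrogens that are not quaternary amines."""
    heavy = {a.name: a for a in lipid.heavy_atoms()}
    out = []
    for a in heavy.values():
        nbs = [heavy[n] for n in lipid.neighbors(a.name) if n in heavy]
        if a.element == "O" or (a.element == "N" and len(nbs) <= 2):
            out.append((a, nbs))
    return out


def detect_hbonds(
    chain: ProteinChain,
    lipids: Sequence[LipidInstance],
    params: GeometryParams | None = None,
) -> list[ContactRecord]:
    """Protein-donor to lipid-acceptor hydrogen bonds.

    Requires polar hydrogens (see :func:`place_polar_hydrogens`); the
    recorded distance is donor-acceptor.
    """
    params = params or GeometryParams()
    acceptors: list[tuple[LipidInstance, Atom, list[Atom]]] = []
    for lip in lipids:
        for a, nbs in _lipid_acceptors(lip):
            if not nbs:
                logger.warning(
                    "acceptor %s of %s has no antecedent atom; skipped", a.name, lip.instance_id
                )
                continue
            acceptors.append((lip, a, nbs))
    if not acceptors:
        return []
    tree = cKDTree(np.asarray([a.xyz for _, a, _ in acceptors]))

    records = []
    for res in chain.residues:
        hydrogens: dict[str, list[Atom]] = {}
        for at in res.atoms:
            if at.element == "H" and at.parent_name:
                hydrogens.setdefault(at.parent_name, []).append(at)
        for donor_name, hs in hydrogens.items():
            donor = res.atom(donor_name)
            if donor is None:
                continue
            for idx in tree.query_ball_point(donor.xyz, params.da_max):
                lip, acc, nbs = acceptors[idx]
                if any(
                    hbond_geometry_ok(
                        donor.xyz, h.xyz, acc.xyz, [n.xyz for n in nbs], params
                    )
                    for h in hs
                ):
                    records.append(
                        ContactRecord(
                            chain.chain_id, res.name, res.seq_id, donor_name,
                            lip.instance_id, acc.name, "hbond",
                            float(np.linalg.norm(acc.xyz - donor.xyz)),
                        )
                    )
    return records


# --------------------------------------------------------------------------
# van der Waals and salt bridges

def _chain_heavy_atoms(chain: ProteinChain) -> list[tuple[Residue, Atom]]:
    return [(r, a) for r in chain.residues for a in r.atoms if a.element != "H"]


def detect_vdw(
    chain: ProteinChain,
    lipids: Sequence[LipidInstance],
    params: GeometryParams | None = None,
    radii: Mapping[str, float] | None = None,
    exclude_pairs: set[tuple[tuple[str, int, str], tuple[str, str]]] | None = None,
) -> list[ContactRecord]:
    """Heavy-atom van der Waals contacts: pair distance at most the sum of
    element radii plus the tolerance.  Pairs in ``exclude_pairs`` (already
    hydrogen bonded between the same atoms) are suppressed."""
    params = params or GeometryParams()
    radii = radii or VDW_RADII
    exclude_pairs = exclude_pairs or set()

    prot = _chain_heavy_atoms(chain)
    lip_atoms = [(lip, a) for lip in lipids for a in lip.heavy_atoms()]
    if not prot or not lip_atoms:
        return []
    max_r = max(radii.values())
    cutoff = 2 * max_r + params.vdw_tolerance
    tree = cKDTree(np.asarray([a.xyz for _, a in lip_atoms]))

    records = []
    for res, at in prot:
        r1 = _radius(at.element, radii)
        for idx in tree.query_ball_point(at.xyz, cutoff):
            lip, la = lip_atoms[idx]
            key = ((res.name, res.seq_id, at.name), (lip.instance_id, la.name))
            if key in exclude_pairs:
                continue
            d = float(np.linalg.norm(la.xyz - at.xyz))
            if d <= r1 + _radius(la.element, radii) + params.vdw_tolerance:
                records.append(
                    ContactRecord(
                        chain.chain_id, res.name, res.seq_id, at.name,
                        lip.instance_id, la.name, "vdw", d,
                    )
                )
    return records


_POSITIVE_PROTEIN = {"ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"}}
_NEGATIVE_PROTEIN = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}


def _lipid_charged_atoms(lipid: LipidInstance) -> list[tuple[Atom, int]]:
    """(atom, sign) for lipid charge centres: phosphate oxygens are
    negative, quaternary amine nitrogens positive."""
    heavy = {a.name: a for a in lipid.heavy_atoms()}
    out = []
    for a in heavy.values():
        nbs = [heavy[n] for n in lipid.neighbors(a.name) if n in heavy]
        if a.element == "O" and any(n.element == "P" for n in nbs):
            out.append((a, -1))
        elif a.element == "N" and len(nbs) >= 4:
            out.append((a, +1))
    return out


def detect_salt_bridges(
    chain: ProteinChain,
    lipids: Sequence[LipidInstance],
    params: GeometryParams | None = None,
) -> list[ContactRecord]:
    """Oppositely charged heavy-atom pairs within ``salt_bridge_max``."""
    params = params or GeometryParams()
    charged_lip = [
        (lip, a, sign) for lip in lipids for a, sign in _lipid_charged_atoms(lip)
    ]
    if not charged_lip:
        return []
    tree = cKDTree(np.asarray([a.xyz for _, a, _ in charged_lip]))

    records = []
    for res in chain.residues:
        for at in res.atoms:
            sign = 0
            if at.name in _POSITIVE_PROTEIN.get(res.name, ()):
                sign = +1
            elif at.name in _NEGATIVE_PROTEIN.get(res.name, ()):
                sign = -1
            if sign == 0:
                continue
            for idx in tree.query_ball_point(at.xyz, params.salt_bridge_max):
                lip, la, lsign = charged_lip[idx]
                if lsign == -sign:
                    records.append(
                        ContactRecord(
                            chain.chain_id, res.name, res.seq_id, at.name,
                            lip.instance_id, la.name, "salt",
                            float(np.linalg.norm(la.xyz - at.xyz)),
                        )
                    )
    return records


# --------------------------------------------------------------------------
# classification and orchestration

def classify_contacts(
    records: Iterable[ContactRecord],
    partitions: Mapping[str, LipidAtomPartition],
) -> list[ContactRecord]:
    """Tag each contact head/tail according to its lipid atom."""
    out = []
    for rec in records:
        group = partitions[rec.instance_id].group_of(rec.lipid_atom)
        out.append(replace(rec, lipid_group=group))
    return out


def residue_binding_flags(
    records: Iterable[ContactRecord],
) -> dict[tuple[str, int], dict[str, bool]]:
    """Collapse classified contacts to per-residue head_bound / tail_bound
    flags; a residue touching both groups carries both flags."""
    flags: dict[tuple[str, int], dict[str, bool]] = {}
    for rec in records:
        if rec.lipid_group is None:
            raise ValueError("contacts must be classified before summarizing")
        entry = flags.setdefault(rec.residue_key, {"head": False, "tail": False})
        entry[rec.lipid_group] = True
    return flags


def find_contacts(
    chain: ProteinChain,
    lipids: Sequence[LipidInstance],
    params: GeometryParams | None = None,
    radii: Mapping[str, float] | None = None,
) -> list[ContactRecord]:
    """Full contact detection for one chain: place hydrogens, detect all
    three contact classes, classify head/tail."""
    params = params or GeometryParams()
    chain_h = place_polar_hydrogens(chain, lipids, params)
    hbonds = detect_hbonds(chain_h, lipids, params)
    hb_pairs = {
        ((r.residue_name, r.residue_seq, r.residue_atom), (r.instance_id, r.lipid_atom))
        for r in hbonds
    }
    salt = detect_salt_bridges(chain_h, lipids, params)
    vdw = detect_vdw(chain_h, lipids, params, radii, exclude_pairs=hb_pairs)
    partitions = {lip.instance_id: lip.partition for lip in lipids}
    return classify_contacts(hbonds + salt + vdw, partitions)
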