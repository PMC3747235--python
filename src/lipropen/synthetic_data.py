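"""Self-contained synthetic inputs with known ground truth.

Three generators cover the pipeline's input types:

* :func:`make_complex` — an ideal α-helical chain with CB side-chain
  pseudo-atoms plus minimal synthetic lipids placed along the outward
  normal of designated residues, so that exactly those residues satisfy
  the heavy-atom contact criteria for the requested class.  The
  construction is the oracle: the designed binding flags are known before
  the contact engine ever runs.
* :func:`make_trajectory` — a multi-model PDB in which each designated
  residue's lipid is near in exactly ``round(q * n_frames)`` frames, so
  the realized occupancy equals the target exactly.
* :func:`make_count_tables` — multinomial residue compositions with
  binomial binding draws at prescribed per-type probabilities, for
  propensity parameter-recovery and chi-square calibration.

The synthetic lipid is registered under the reserved HET ID ``ZZL``: three
head atoms (a phosphorus and two oxygens) and an eight-carbon alkyl tail,
with the tail start declared by registry override since the molecule has
no ester carbonyl.  No physical realism is attempted: no sterics, no
bilayer, no force field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import gemmi
import numpy as np

from .lipid_model import LipidRegistry
from .propensity import AMINO_ACIDS, ChainContactCounts

__all__ = [
    "SyntheticSpec",
    "GenerationError",
    "synthetic_registry",
    "make_complex",
    "make_trajectory",
    "make_count_tables",
    "contact_frame_pattern",
]

SYNTHETIC_HET_ID = "ZZL"

# helix parameters: 100° twist and 1.5 Å rise per residue, CA radius 2.3 Å
_HELIX_TWIST = np.radians(100.0)
_HELIX_RISE = 1.5
_HELIX_RADIUS = 2.3

# contact-placement distances (Å): within the heavy-atom vdW criterion for
# the nearest designated atom, with everything else kept beyond 4.2 Å
_TAIL_CONTACT_DIST = 3.4  # C...C, cutoff 3.9
_HEAD_CONTACT_DIST = 3.2  # O...C, cutoff 3.72
_CLEARANCE = 4.2
_DISPLACEMENT = 18.0  # radial shift that breaks all contacts in a frame


class GenerationError(RuntimeError):
    """Requested geometry is infeasible (placements collide)."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic generators; the seed fully determines
    every output.

    ``designated_contacts`` maps residue sequence positions to the contact
    class each must exhibit ('head', 'tail' or 'both');
    ``occupancy_targets`` maps positions to trajectory contact fractions in
    [0, 1].  Counts mode draws ``n_chains`` chains of ``counts_chain_length``
    residues with per-type binding probabilities ``p_head`` / ``p_tail``
    (a scalar applies to all 20 types).
    """

    seed: int = 0
    structure_id: str = "synt"
    chain_length: int = 40
    resolution: float = 3.7
    sequence: tuple[str, ...] | None = None
    composition_weights: Mapping[str, float] | None = None
    designated_contacts: Mapping[int, str] = field(default_factory=dict)
    n_frames: int = 1000
    occupancy_targets: Mapping[int, float] = field(default_factory=dict)
    n_chains: int = 45
    counts_chain_length: int = 250
    p_head: float | Mapping[str, float] = 0.04
    p_tail: float | Mapping[str, float] = 0.05

    def __post_init__(self) -> None:
        for q in self.occupancy_targets.values():
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"occupancy target {q} outside [0, 1]")
        for cls in self.designated_contacts.values():
            if cls not in ("head", "tail", "both"):
                raise ValueError(f"unknown contact class {cls!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def probabilities(self, contact_class: str) -> dict[str, float]:
        p = self.p_head if contact_class == "head" else self.p_tail
        if isinstance(p, Mapping):
            out = {aa: float(p.get(aa, 0.0)) for aa in AMINO_ACIDS}
        else:
            out = {aa: float(p) for aa in AMINO_ACIDS}
        for aa, v in out.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"binding probability for {aa} outside [0, 1]")
        return out


def synthetic_registry() -> LipidRegistry:
    """The default registry extended with the ZZL test lipid (tail-start
    override C1; bonds are inferred from the generated coordinates)."""
    reg = LipidRegistry.default()
    reg.register(SYNTHETIC_HET_ID, tail_start_atoms=("C1",), notes="synthetic test lipid")
    return reg


# --------------------------------------------------------------------------
# helix and lipid geometry

def _helix_coordinates(n: int) -> dict[str, np.ndarray]:
    """Idealized backbone (N, CA, C, O) and CB positions for an n-residue
    α-helix along z.  Bond geometry is approximate but consistent enough
    for polar-hydrogen placement; contact fixtures needing exact hydrogen
    geometry are built atom-by-atom elsewhere."""
    i = np.arange(n)
    ca = np.stack(
        [
            _HELIX_RADIUS * np.cos(i * _HELIX_TWIST),
            _HELIX_RADIUS * np.sin(i * _HELIX_TWIST),
            i * _HELIX_RISE,
        ],
        axis=1,
    )
    # virtual neighbours for terminal extrapolation
    prev = np.vstack([2 * ca[0] - ca[1], ca[:-1]])
    nxt = np.vstack([ca[1:], 2 * ca[-1] - ca[-2]])
    n_at = ca + 0.33 * (prev - ca)
    c_at = ca + 0.33 * (nxt - ca)
    radial = ca.copy()
    radial[:, 2] = 0.0
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    o_at = c_at + 1.23 * radial
    cb = ca + 1.53 * radial
    return {"N": n_at, "CA": ca, "C": c_at, "O": o_at, "CB": cb, "radial": radial}


def _lipid_atoms(
    cb: np.ndarray, radial: np.ndarray, mode: str
) -> list[tuple[str, str, np.ndarray]]:
    """Place one ZZL lipid relative to a residue's CB so that the requested
    contact class (and only it) is realized.

    tail: the terminal methyl C8 sits nearest, the chain runs outward and
    the phosphate group caps the far end.  head: O1 sits nearest and the
    alkyl chain runs further outward.  both: the molecule lies tangentially
    so O1 and C1 are both within their criteria.
    """
    r = radial / np.linalg.norm(radial)
    t = np.cross([0.0, 0.0, 1.0], r)
    t /= np.linalg.norm(t)
    up = np.cross(r, t)
    atoms: list[tuple[str, str, np.ndarray]] = []
    if mode == "tail":
        # C8 ... C1 outward, then P1 with its two oxygens at the far end
        for k in range(8):  # C8 at cb + 3.4 r, C1 at cb + (3.4 + 7*1.5) r
            atoms.append((f"C{8 - k}", "C", cb + (_TAIL_CONTACT_DIST + 1.5 * k) * r))
        p1 = cb + (_TAIL_CONTACT_DIST + 8 * 1.5) * r
        atoms += [("P1", "P", p1), ("O1", "O", p1 + 1.5 * t), ("O2", "O", p1 + 1.5 * up)]
    elif mode == "head":
        o1 = cb + _HEAD_CONTACT_DIST * r
        p1 = o1 + 1.5 * r
        atoms += [("O1", "O", o1), ("P1", "P", p1), ("O2", "O", p1 + 1.5 * t)]
        for k in range(8):
            atoms.append((f"C{k + 1}", "C", p1 + 1.5 * (k + 1) * r))
    elif mode == "both":
        p1 = cb + 3.3 * r
        atoms += [("P1", "P", p1), ("O1", "O", p1 - 1.5 * t), ("O2", "O", p1 + 1.5 * up)]
        for k in range(8):
            atoms.append((f"C{k + 1}", "C", p1 + 1.5 * (k + 1) * t))
    else:  # pragma: no cover - guarded by SyntheticSpec
        raise ValueError(mode)
    return atoms


def _draw_sequence(spec: SyntheticSpec, n: int, rng: np.random.Generator) -> list[str]:
    if spec.sequence is not None:
        if len(spec.sequence) != n:
            raise ValueError("explicit sequence length differs from chain_length")
        return list(spec.sequence)
    weights = spec.composition_weights or {aa: 1.0 for aa in AMINO_ACIDS}
    p = np.asarray([weights.get(aa, 0.0) for aa in AMINO_ACIDS], dtype=float)
    p = p / p.sum()
    return [AMINO_ACIDS[k] for k in rng.choice(len(AMINO_ACIDS), size=n, p=p)]


def _build_structure(
    spec: SyntheticSpec,
    sequence: Sequence[str],
    helix: Mapping[str, np.ndarray],
    lipid_sets: Sequence[Sequence[tuple[str, str, np.ndarray]]],
) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = spec.structure_id
    st.info["_entry.id"] = spec.structure_id.upper()
    st.resolution = spec.resolution
    model = gemmi.Model(1)
    chain = gemmi.Chain("A")
    for i, aa in enumerate(sequence):
        res = gemmi.Residue()
        res.name = aa
        res.seqid = gemmi.SeqId(i + 1, " ")
        res.het_flag = "A"
        names = ["N", "CA", "C", "O"] + ([] if aa == "GLY" else ["CB"])
        for name in names:
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(name[0])
            at.pos = gemmi.Position(*helix[name][i])
            at.occ = 1.0
            res.add_atom(at)
        chain.add_residue(res)
    model.add_chain(chain)
    lip_chain = gemmi.Chain("L")
    for j, atoms in enumerate(lipid_sets):
        res = gemmi.Residue()
        res.name = SYNTHETIC_HET_ID
        res.seqid = gemmi.SeqId(j + 1, " ")
        res.het_flag = "H"
        for name, element, pos in atoms:
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(element)
            at.pos = gemmi.Position(*pos)
            at.occ = 1.0
            res.add_atom(at)
        lip_chain.add_residue(res)
    model.add_chain(lip_chain)
    st.add_model(model)
    st.setup_entities()
    return st


def _validate_clearance(
    sequence: Sequence[str],
    helix: Mapping[str, np.ndarray],
    lipid_sets: Sequence[Sequence[tuple[str, str, np.ndarray]]],
    designated: Mapping[int, str],
) -> None:
    """Geometric feasibility check: every lipid atom must stay clear of
    all residues other than the one it was placed for."""
    for j, atoms in enumerate(lipid_sets):
        owner = list(designated)[j]
        coords = np.asarray([pos for _, _, pos in atoms])
        for i, aa in enumerate(sequence):
            seq_id = i + 1
            if seq_id == owner:
                continue
            names = ["N", "CA", "C", "O"] + ([] if aa == "GLY" else ["CB"])
            res_xyz = np.asarray([helix[n][i] for n in names])
            d = np.linalg.norm(coords[:, None, :] - res_xyz[None, :, :], axis=2)
            if d.min() < _CLEARANCE:
                raise GenerationError(
                    f"lipid placed for residue {owner} collides with residue "
                    f"{seq_id} (min distance {d.min():.2f} Å)"
                )


def make_complex(spec: SyntheticSpec) -> str:
    """Generate a single-model PDB of one helical chain plus one synthetic
    lipid per designated residue; returns the PDB text."""
    rng = spec.rng()
    n = spec.chain_length
    sequence = _draw_sequence(spec, n, rng)
    helix = _helix_coordinates(n)
    designated = dict(sorted(spec.designated_contacts.items()))
    for seq_id in designated:
        if not 1 <= seq_id <= n:
            raise GenerationError(f"designated residue {seq_id} outside chain")
        if sequence[seq_id - 1] == "GLY":
            sequence[seq_id - 1] = "ALA"  # a CB anchor is required
    lipid_sets = [
        _lipid_atoms(helix["CB"][seq_id - 1], helix["radial"][seq_id - 1], mode)
        for seq_id, mode in designated.items()
    ]
    _validate_clearance(sequence, helix, lipid_sets, designated)
    st = _build_structure(spec, sequence, helix, lipid_sets)
    return st.make_pdb_string()


def contact_frame_pattern(q: float, n_frames: int) -> np.ndarray:
    """Boolean mask with exactly ``round(q * n_frames)`` True entries,
    spread evenly across the frames."""
    k = int(round(q * n_frames))
    t = np.arange(n_frames)
    return ((t + 1) * k) // n_frames > (t * k) // n_frames


def make_trajectory(spec: SyntheticSpec) -> str:
    """Generate a multi-model PDB trajectory; each residue listed in
    ``occupancy_targets`` realizes its target contact fraction exactly
    (the lipid is displaced 18 Å outward in non-contact frames)."""
    rng = spec.rng()
    n = spec.chain_length
    sequence = _draw_sequence(spec, n, rng)
    helix = _helix_coordinates(n)
    targets = dict(sorted(spec.occupancy_targets.items()))
    designated = {seq_id: "tail" for seq_id in targets}
    for seq_id in targets:
        if not 1 <= seq_id <= n:
            raise GenerationError(f"designated residue {seq_id} outside chain")
        if sequence[seq_id - 1] == "GLY":
            sequence[seq_id - 1] = "ALA"
    base_sets = [
        _lipid_atoms(helix["CB"][seq_id - 1], helix["radial"][seq_id - 1], "both")
        for seq_id in targets
    ]
    _validate_clearance(sequence, helix, base_sets, designated)
    patterns = {
        seq_id: contact_frame_pattern(q, spec.n_frames) for seq_id, q in targets.items()
    }

    st: gemmi.Structure | None = None
    frames = []
    for t in range(spec.n_frames):
        lipid_sets = []
        for j, seq_id in enumerate(targets):
            shift = (
                np.zeros(3)
                if patterns[seq_id][t]
                else _DISPLACEMENT * helix["radial"][seq_id - 1]
            )
            lipid_sets.append(
                [(nm, el, pos + shift) for nm, el, pos in base_sets[j]]
            )
        frame_st = _build_structure(spec, sequence, helix, lipid_sets)
        frames.append(frame_st[0])
    st = _build_structure(spec, sequence, helix, base_sets)
    while len(st) > 0:
        del st[0]
    for t, model in enumerate(frames):
        model.num = t + 1
        st.add_model(model)
    return st.make_pdb_string()


def make_count_tables(
    spec: SyntheticSpec, contact_class: str = "head"
) -> list[ChainContactCounts]:
    """Draw synthetic per-chain count tables: residue compositions are
    multinomial in the composition weights, binding draws are binomial at
    the per-type probabilities of the requested class."""
    rng = spec.rng()
    weights = spec.composition_weights or {aa: 1.0 for aa in AMINO_ACIDS}
    p_comp = np.asarray([weights.get(aa, 0.0) for aa in AMINO_ACIDS], dtype=float)
    p_comp = p_comp / p_comp.sum()
    p_bind = spec.probabilities(contact_class)

    out = []
    for c in range(spec.n_chains):
        comp = rng.multinomial(spec.counts_chain_length, p_comp)
        n_by_type = {aa: int(k) for aa, k in zip(AMINO_ACIDS, comp)}
        nb_by_type = {
            aa: float(rng.binomial(n_by_type[aa], p_bind[aa])) for aa in AMINO_ACIDS
        }
        out.append(
            ChainContactCounts(
                f"{spec.structure_id}_{c:03d}", contact_class, n_by_type, nb_by_type
            )
        )
    return out
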