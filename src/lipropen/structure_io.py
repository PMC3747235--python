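"""PDB/mmCIF reading and dataset screening.

Screening rules for crystal-structure mode: keep X-ray entries solved at
4.0 Å or better (entries without a resolution record, e.g. NMR, are
rejected); keep polymer chains of at least 30 standard residues, treating
selenomethionine (MSE) as MET and rejecting chains with any other
non-standard amino acid; collect every HETATM residue whose component ID is
in the phospholipid registry as a lipid instance.  The "no lipid contacts"
chain filter needs the contact engine and is applied downstream, before
cluster-representative selection.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import gemmi
import numpy as np

from .lipid_model import (
    LipidAtomPartition,
    LipidDefinition,
    LipidRegistry,
    bonds_from_distances,
    partition_lipid,
)

__all__ = [
    "Atom",
    "Residue",
    "ProteinChain",
    "LipidInstance",
    "FormatError",
    "screen_structure",
    "select_representatives",
    "read_chain_annotations",
]

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

MAX_RESOLUTION = 4.0
MIN_CHAIN_LENGTH = 30


class FormatError(ValueError):
    """Raised when the input cannot be parsed as PDB/mmCIF."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    pos: tuple[float, float, float]
    # donor heavy atom a placed hydrogen hangs off; None for real atoms
    parent_name: str | None = None

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.pos, dtype=float)


@dataclass(frozen=True)
class Residue:
    name: str
    seq_id: int
    atoms: tuple[Atom, ...]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[str, int]:
        return (self.name, self.seq_id)


@dataclass(frozen=True)
class ProteinChain:
    structure_id: str
    chain_id: str
    residues: tuple[Residue, ...]
    resolution: float
    tm_label: str = "unknown"  # {"TM", "non-TM", "unknown"}
    cluster_id: str | None = None

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def label(self) -> str:
        return f"{self.structure_id}_{self.chain_id}"


@dataclass(frozen=True)
class LipidInstance:
    het_id: str
    instance_id: str
    atoms: tuple[Atom, ...]
    partition: LipidAtomPartition
    bonds: tuple[tuple[str, str], ...] = ()

    def heavy_atoms(self) -> tuple[Atom, ...]:
        return tuple(a for a in self.atoms if a.element != "H")

    def neighbors(self, atom_name: str) -> list[str]:
        out = []
        for a, b in self.bonds:
            if a == atom_name:
                out.append(b)
            elif b == atom_name:
                out.append(a)
        return out

    def group_of(self, atom: Atom) -> str:
        name = atom.parent_name if atom.element == "H" and atom.parent_name else atom.name
        return self.partition.group_of(name)


def _read_structure(source: str | Path | TextIO) -> gemmi.Structure:
    try:
        if hasattr(source, "read"):
            return gemmi.read_pdb_string(source.read())
        text = str(source)
        if "\n" in text:
            return gemmi.read_pdb_string(text)
        path = Path(text)
        if path.suffix.lower() in {".cif", ".mmcif"}:
            return gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        return gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot parse structure input: {exc}") from exc


def _structure_id(st: gemmi.Structure) -> str:
    try:
        entry_id = st.info["_entry.id"]
    except KeyError:
        entry_id = ""
    name = entry_id or st.name or "unknown"
    if name == "string":  # gemmi's placeholder for in-memory input
        name = "unknown"
    return name.lower().removesuffix(".pdb")


def _pick_altloc(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties -> lowest
    altloc letter (so 'A' wins)."""
    best: dict[str, gemmi.Atom] = {}
    for at in residue:
        cur = best.get(at.name)
        if cur is None or (at.occ, -ord(at.altloc or "A")) > (cur.occ, -ord(cur.altloc or "A")):
            best[at.name] = at
    return [best[n] for n in best]


def _convert_atoms(residue: gemmi.Residue, rename_mse: bool = False) -> tuple[Atom, ...]:
    out = []
    for at in _pick_altloc(residue):
        name = at.name
        if rename_mse and name == "SE":
            name = "SD"  # selenomethionine read as MET
        out.append(Atom(name, at.element.name, (at.pos.x, at.pos.y, at.pos.z)))
    return tuple(out)


def _is_amino_acid(name: str) -> bool:
    if name in STANDARD_AA or name == "MSE":
        return True
    info = gemmi.find_tabulated_residue(name)
    return info is not None and info.is_amino_acid()


def screen_structure(
    source: str | Path | TextIO,
    registry: LipidRegistry | None = None,
    max_resolution: float = MAX_RESOLUTION,
    min_chain_length: int = MIN_CHAIN_LENGTH,
) -> tuple[list[ProteinChain], list[LipidInstance]]:
    """Parse one structure and apply the crystal-mode screening filters.

    Returns the protein chains that pass the resolution / length /
    composition filters, and every lipid instance whose HET ID is in the
    registry (with its head/tail partition computed from distance-inferred
    bonds).  An entry with no usable resolution record is rejected outright
    (empty chain and lipid lists).
    """
    registry = registry or LipidRegistry.default()
    st = _read_structure(source)
    st.setup_entities()
    structure_id = _structure_id(st)

    resolution = float(st.resolution)
    if not np.isfinite(resolution) or resolution <= 0 or resolution > max_resolution:
        return [], []

    chains: list[ProteinChain] = []
    lipids: list[LipidInstance] = []
    model = st[0]
    for ch in model:
        residues: list[Residue] = []
        reject_chain = False
        for res in ch:
            name = res.name
            if name == "HOH" or res.is_water():
                continue
            if name in registry:
                lipids.append(_make_lipid_instance(res, ch.name, registry))
                continue
            if not _is_amino_acid(name):
                continue  # other heteroatoms (cofactors, ions) are ignored
            if name == "MSE":
                residues.append(Residue("MET", res.seqid.num, _convert_atoms(res, True)))
            elif name in STANDARD_AA:
                residues.append(Residue(name, res.seqid.num, _convert_atoms(res)))
            else:
                reject_chain = True  # non-standard amino acid in the polymer
        if reject_chain or len(residues) < min_chain_length:
            continue
        chains.append(
            ProteinChain(structure_id, ch.name, tuple(residues), resolution)
        )
    return chains, lipids


def _make_lipid_instance(
    res: gemmi.Residue, chain_name: str, registry: LipidRegistry
) -> LipidInstance:
    entry = registry[res.name]
    atoms = _convert_atoms(res)
    if entry.definition is not None:
        defn = entry.definition
    else:
        triples = [(a.name, a.element, a.pos) for a in atoms]
        defn = LipidDefinition(
            res.name,
            tuple((a.name, a.element) for a in atoms),
            bonds_from_distances(triples),
        )
    partition = partition_lipid(defn, entry.tail_start_atoms)
    instance_id = f"{chain_name}_{res.name}_{res.seqid.num}"
    return LipidInstance(res.name, instance_id, atoms, partition, defn.bonds)


def read_chain_annotations(path: str | Path) -> dict[tuple[str, str], dict[str, str]]:
    """Read the sidecar TSV with cluster assignments and TM labels.

    Columns: structure_id, chain_id, cluster_id, tm_label.  Sequence
    clustering and membrane-topology annotation are inputs, not computed
    here.
    """
    out: dict[tuple[str, str], dict[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            key = (row["structure_id"].lower(), row["chain_id"])
            out[key] = {
                "cluster_id": row["cluster_id"],
                "tm_label": row.get("tm_label", "unknown"),
            }
    return out


def annotate_chains(
    chains: Iterable[ProteinChain],
    annotations: Mapping[tuple[str, str], Mapping[str, str]],
) -> list[ProteinChain]:
    out = []
    for c in chains:
        ann = annotations.get((c.structure_id, c.chain_id))
        if ann:
            c = replace(c, cluster_id=ann["cluster_id"], tm_label=ann.get("tm_label", c.tm_label))
        out.append(c)
    return out


def select_representatives(
    chains: Iterable[ProteinChain],
    contact_counts: Mapping[tuple[str, str], int],
    min_cluster_contacts: int = 5,
) -> list[ProteinChain]:
    """Pick one representative chain per sequence cluster.

    The representative is the chain with the most lipid-contacting residues;
    clusters in which every member has fewer than ``min_cluster_contacts``
    contacting residues are discarded.  Ties break lexicographically on
    (structure_id, chain_id) for determinism.
    """
    clusters: dict[str, list[ProteinChain]] = {}
    for c in chains:
        if c.cluster_id is None:
            raise ValueError(f"chain {c.label} has no cluster_id; annotate first")
        clusters.setdefault(c.cluster_id, []).append(c)

    reps = []
    for cid in sorted(clusters):
        members = clusters[cid]
        counts = {m.label: contact_counts[(m.structure_id, m.chain_id)] for m in members}
        if max(counts.values()) < min_cluster_contacts:
            continue
        reps.append(
            min(
                members,
                key=lambda m: (-counts[m.label], m.structure_id, m.chain_id),
            )
        )
    return reps
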