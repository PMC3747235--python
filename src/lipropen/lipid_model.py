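"""Phospholipid registry and head/tail atom partitioning.

A phosphoglyceride consists of one or two fatty-acid (acyl) chains linked
through a glycerol-phosphate moiety to at most one polar substituent.  For
contact statistics the molecule is split into a hydrophilic *head* group
(glycerol, phosphate, polar substituent, and the acyl carbonyl/ester atoms)
and hydrophobic *tail* groups (the acyl chain from the carbon adjacent to
the carbonyl carbon through the terminal methyl).

The registry maps PDB HET IDs to per-lipid metadata.  Mimetic lipids with
no ester carbonyl (ether-linked, phosphonate analogues) carry an explicit
``tail_start_atoms`` override naming the first tail carbon of each chain,
because "the corresponding carbon" of a mimetic cannot be inferred from the
molecular graph alone.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import networkx as nx

__all__ = [
    "LipidDefinition",
    "LipidAtomPartition",
    "LipidRegistry",
    "RegistryEntry",
    "RegistryMissError",
    "MalformedLipidError",
    "partition_lipid",
    "bonds_from_distances",
    "bonds_from_ccd",
]

# Heavy-atom covalent bond inference threshold (Å).
BOND_DISTANCE_CUTOFF = 1.9


class RegistryMissError(KeyError):
    """Raised when a HET ID is not present in the lipid registry."""


class MalformedLipidError(ValueError):
    """Raised when a lipid's bond graph is disconnected or chemically
    uninterpretable (no acyl chain and no tail-start override)."""


@dataclass(frozen=True)
class LipidDefinition:
    """A lipid chemical component: atoms and its molecular (bond) graph.

    Atom names are the PDB atom names; elements are capitalized symbols.
    Hydrogens may be present but are ignored by the partition (each hydrogen
    follows its parent heavy atom).
    """

    het_id: str
    atoms: tuple[tuple[str, str], ...]  # (atom name, element)
    bonds: tuple[tuple[str, str], ...]  # atom-name pairs

    def __post_init__(self) -> None:
        names = {n for n, _ in self.atoms}
        for a, b in self.bonds:
            if a not in names or b not in names:
                raise MalformedLipidError(
                    f"{self.het_id}: bond endpoint {a!r}/{b!r} names no listed atom"
                )

    def heavy_atom_names(self) -> set[str]:
        return {n for n, e in self.atoms if e.upper() != "H"}

    def graph(self) -> nx.Graph:
        """Bond graph restricted to heavy atoms."""
        g = nx.Graph()
        elements = dict(self.atoms)
        heavy = self.heavy_atom_names()
        g.add_nodes_from((n, {"element": elements[n].upper()}) for n in heavy)
        for a, b in self.bonds:
            if a in heavy and b in heavy:
                g.add_edge(a, b)
        return g


@dataclass(frozen=True)
class LipidAtomPartition:
    """Disjoint, exhaustive split of a lipid's heavy atoms into head and tail."""

    het_id: str
    head_atoms: frozenset[str]
    tail_atoms: frozenset[str]

    def group_of(self, atom_name: str) -> str:
        """Return ``"head"`` or ``"tail"``; hydrogens follow their parent
        heavy atom, which must be looked up by the caller."""
        if atom_name in self.head_atoms:
            return "head"
        if atom_name in self.tail_atoms:
            return "tail"
        raise KeyError(f"{atom_name!r} is not a heavy atom of {self.het_id}")


@dataclass
class RegistryEntry:
    het_id: str
    tail_start_atoms: tuple[str, ...] = ()
    notes: str = ""
    definition: LipidDefinition | None = None


@dataclass
class LipidRegistry:
    """User-extensible registry of phospholipid HET IDs.

    Ships with the curated set of 98 phosphoglyceride and mimetic component
    IDs found in lipid-bound PDB entries; additional components (e.g. the
    synthetic test lipid) can be registered at run time.
    """

    entries: dict[str, RegistryEntry] = field(default_factory=dict)

    def __contains__(self, het_id: str) -> bool:
        return het_id.upper() in self.entries

    def __getitem__(self, het_id: str) -> RegistryEntry:
        try:
            return self.entries[het_id.upper()]
        except KeyError:
            raise RegistryMissError(het_id) from None

    def register(
        self,
        het_id: str,
        tail_start_atoms: Iterable[str] = (),
        notes: str = "",
        definition: LipidDefinition | None = None,
    ) -> RegistryEntry:
        het_id = het_id.upper()
        if not (1 <= len(het_id) <= 3):
            raise ValueError(f"HET ID must be 1-3 characters, got {het_id!r}")
        entry = RegistryEntry(het_id, tuple(tail_start_atoms), notes, definition)
        self.entries[het_id] = entry
        return entry

    @classmethod
    def from_file(cls, path: str | Path) -> "LipidRegistry":
        """Load a tab-separated registry (columns HET_ID, TAIL_START_ATOMS,
        NOTES; '#' comment lines and the header row are skipped)."""
        reg = cls()
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#") or row[0] == "HET_ID":
                    continue
                het = row[0].strip().upper()
                tail_start = tuple(
                    a.strip() for a in (row[1] if len(row) > 1 else "").split(",") if a.strip()
                )
                notes = row[2].strip() if len(row) > 2 else ""
                reg.register(het, tail_start, notes)
        return reg

    @classmethod
    def default(cls) -> "LipidRegistry":
        """The bundled phosphoglyceride registry (98 HET IDs)."""
        with resources.as_file(
            resources.files("lipropen.data") / "phospholipid_het_ids.tsv"
        ) as p:
            return cls.from_file(p)


def bonds_from_distances(
    atoms: Iterable[tuple[str, str, "tuple[float, float, float]"]],
    cutoff: float = BOND_DISTANCE_CUTOFF,
) -> tuple[tuple[str, str], ...]:
    """Infer heavy-atom bonds from interatomic distances.

    Deposited lipid HETATMs frequently lack CONECT records; two heavy atoms
    closer than ``cutoff`` (default 1.9 Å) are taken as covalently bonded.
    ``atoms`` yields (name, element, xyz).
    """
    import numpy as np

    heavy = [(n, e, xyz) for n, e, xyz in atoms if e.upper() != "H"]
    if not heavy:
        return ()
    coords = np.asarray([xyz for _, _, xyz in heavy], dtype=float)
    bonds = []
    for i in range(len(heavy)):
        d = np.linalg.norm(coords[i + 1 :] - coords[i], axis=1)
        for j in (i + 1 + (d < cutoff).nonzero()[0]):
            bonds.append((heavy[i][0], heavy[j][0]))
    return tuple(bonds)


def bonds_from_ccd(path: str | Path, het_id: str) -> tuple[tuple[str, str], ...]:
    """Read a component's bonds from a chemical-component dictionary mmCIF."""
    import gemmi

    doc = gemmi.cif.read(str(path))
    block = doc.find_block(het_id) or doc.sole_block()
    pairs = block.find("_chem_comp_bond.", ["atom_id_1", "atom_id_2"])
    return tuple((row[0], row[1]) for row in pairs)


def _carbonyl_carbons(g: nx.Graph) -> list[str]:
    """Ester carbonyl carbons: a C bonded to a terminal O (the carbonyl
    oxygen), a bridging O (the ester oxygen), and at least one C (acyl C2)."""
    out = []
    for n, data in g.nodes(data=True):
        if data["element"] != "C":
            continue
        o_nb = [m for m in g[n] if g.nodes[m]["element"] == "O"]
        c_nb = [m for m in g[n] if g.nodes[m]["element"] == "C"]
        if not c_nb or len(o_nb) < 2:
            continue
        has_terminal_o = any(g.degree[m] == 1 for m in o_nb)
        has_bridging_o = any(g.degree[m] >= 2 for m in o_nb)
        if has_terminal_o and has_bridging_o:
            out.append(n)
    return out


def partition_lipid(
    defn: LipidDefinition, tail_start_atoms: Iterable[str] = ()
) -> LipidAtomPartition:
    """Split a lipid's heavy atoms into head and tail groups.

    The tail of each fatty-acid chain runs from the acyl C2 — the carbon
    bonded to the ester carbonyl carbon — to the terminal methyl; everything
    else (glycerol, phosphate, polar group, carbonyl and ester atoms) is
    head.  Concretely: take the carbon-only subgraph of the molecule, delete
    the carbonyl carbons, and call tail every component that contains an
    acyl C2 (or a registry-supplied ``tail_start_atoms`` carbon for mimetic
    lipids without a carbonyl).  Heteroatoms break the carbon graph, so
    glycerol and choline carbons never leak into the tail.
    """
    g = defn.graph()
    if g.number_of_nodes() == 0:
        raise MalformedLipidError(f"{defn.het_id}: no heavy atoms")
    if not nx.is_connected(g):
        raise MalformedLipidError(f"{defn.het_id}: disconnected bond graph")

    carbonyls = _carbonyl_carbons(g)
    starts: set[str] = set()
    for c in carbonyls:
        starts.update(m for m in g[c] if g.nodes[m]["element"] == "C")
    for name in tail_start_atoms:
        if name not in g:
            raise MalformedLipidError(
                f"{defn.het_id}: tail-start override {name!r} not a heavy atom"
            )
        starts.add(name)
    if not starts:
        raise MalformedLipidError(
            f"{defn.het_id}: no acyl carbonyl found and no tail-start override"
        )

    carbon_g = g.subgraph(
        n for n, d in g.nodes(data=True) if d["element"] == "C" and n not in carbonyls
    )
    tail: set[str] = set()
    for comp in nx.connected_components(carbon_g):
        if comp & starts:
            tail |= comp
    head = set(g.nodes) - tail

    # phosphorus can never be aliphatic tail; guaranteed because the
    # carbon-only subgraph excludes it, asserted for safety
    assert all(g.nodes[n]["element"] != "P" for n in tail)

    return LipidAtomPartition(defn.het_id, frozenset(head), frozenset(tail))
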