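"""Fractional lipid-binding counts from multi-frame trajectories.

Each snapshot yields a binary in-contact indicator per residue and contact
class; the per-residue binding count is the fraction of snapshots in which
the residue touches any lipid of the class,

    N_k^b = (sum_t I_k(t)) / n_frames,

a real number in [0, 1] that feeds directly into the crystal-structure
propensity formula.  The default per-snapshot criterion is a heavy-atom
distance cutoff (4.5 Å), the MD-community norm; the full crystal-style
hydrogen-bond/vdW/salt criteria are available at higher cost.

The portable trajectory format is a multi-model PDB sharing one topology;
the data contract is simply an ordered sequence of coordinate sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, TextIO

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .contacts import GeometryParams, find_contacts, residue_binding_flags
from .lipid_model import LipidRegistry
from .structure_io import (
    Atom,
    LipidInstance,
    ProteinChain,
    Residue,
    _convert_atoms,
    _is_amino_acid,
    _make_lipid_instance,
    STANDARD_AA,
)

DEFAULT_CUTOFF = 4.5

__all__ = [
    "DEFAULT_CUTOFF",
    "TrajectoryContactSeries",
    "read_trajectory",
    "frame_contacts",
    "occupancy",
    "trajectory_occupancy",
    "counts_from_occupancy",
]


@dataclass(frozen=True)
class TrajectoryContactSeries:
    """Per-residue contact occupancy over a trajectory for one class."""

    contact_class: str
    occupancies: Mapping[tuple[str, int], float]
    n_frames: int
    criterion: str
    cutoff: float

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        for key, q in self.occupancies.items():
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"occupancy of {key} outside [0, 1]: {q}")


def read_trajectory(
    source: str | Path | TextIO,
    registry: LipidRegistry | None = None,
    mask: Sequence[tuple[int, int]] = (),
) -> list[tuple[ProteinChain, list[LipidInstance]]]:
    """Read a multi-model PDB as an ordered frame sequence.

    Every model must present the same topology (same residues, same atom
    counts); frames that do not match the first model are rejected.
    ``mask`` lists inclusive residue-number ranges to exclude from the
    analysis (e.g. a large extra-membranous domain).
    """
    registry = registry or LipidRegistry.default()
    if hasattr(source, "read"):
        st = gemmi.read_pdb_string(source.read())
    else:
        text = str(source)
        st = gemmi.read_pdb_string(text) if "\n" in text else gemmi.read_structure(str(text))
    st.setup_entities()
    from .structure_io import _structure_id

    structure_id = _structure_id(st)

    def masked(seq_id: int) -> bool:
        return any(lo <= seq_id <= hi for lo, hi in mask)

    frames: list[tuple[ProteinChain, list[LipidInstance]]] = []
    signature = None
    for model in st:
        residues: list[Residue] = []
        lipids: list[LipidInstance] = []
        chain_id = ""
        for ch in model:
            for res in ch:
                if res.is_water():
                    continue
                if res.name in registry:
                    lipids.append(_make_lipid_instance(res, ch.name, registry))
                elif res.name in STANDARD_AA or res.name == "MSE" or _is_amino_acid(res.name):
                    if masked(res.seqid.num):
                        continue
                    name = "MET" if res.name == "MSE" else res.name
                    residues.append(
                        Residue(name, res.seqid.num, _convert_atoms(res, res.name == "MSE"))
                    )
                    chain_id = chain_id or ch.name
        sig = tuple((r.name, r.seq_id, len(r.atoms)) for r in residues)
        if signature is None:
            signature = sig
        elif sig != signature:
            raise ValueError(
                f"frame {len(frames)} does not match the topology of frame 0"
            )
        frames.append(
            (ProteinChain(structure_id, chain_id, tuple(residues), 0.0), lipids)
        )
    if not frames:
        raise ValueError("trajectory contains no frames")
    return frames


def frame_contacts(
    chain: ProteinChain,
    lipids: Sequence[LipidInstance],
    criterion: str = "distance",
    cutoff: float = DEFAULT_CUTOFF,
    params: GeometryParams | None = None,
) -> dict[tuple[str, int], dict[str, bool]]:
    """Binary head/tail contact indicators for one snapshot.

    ``criterion='distance'``: a residue is in contact with a class when any
    of its heavy atoms lies within ``cutoff`` of any lipid heavy atom of
    that class.  ``criterion='hbplus'`` runs the crystal-style contact
    engine instead.
    """
    if criterion == "hbplus":
        return residue_binding_flags(find_contacts(chain, lipids, params))
    if criterion != "distance":
        raise ValueError(f"unknown contact criterion {criterion!r}")

    group_points: dict[str, list[np.ndarray]] = {"head": [], "tail": []}
    for lip in lipids:
        for a in lip.heavy_atoms():
            group_points[lip.group_of(a)].append(a.xyz)
    trees = {
        g: cKDTree(np.asarray(pts)) for g, pts in group_points.items() if pts
    }
    flags: dict[tuple[str, int], dict[str, bool]] = {}
    for res in chain.residues:
        coords = np.asarray([a.xyz for a in res.atoms if a.element != "H"])
        entry = {"head": False, "tail": False}
        if len(coords):
            for g, tree in trees.items():
                d, _ = tree.query(coords, k=1)
                entry[g] = bool(np.min(d) <= cutoff)
        flags[res.key] = entry
    return flags


def occupancy(
    indicator_frames: Sequence[Mapping[tuple[str, int], Mapping[str, bool]]],
    contact_class: str,
    criterion: str = "distance",
    cutoff: float = DEFAULT_CUTOFF,
) -> TrajectoryContactSeries:
    """Average per-frame indicators into occupancy fractions.

    A residue seen in contact in k of n frames gets occupancy k/n exactly;
    the result is invariant under frame reordering.
    """
    if not indicator_frames:
        raise ValueError("need at least one frame")
    totals: dict[tuple[str, int], int] = {}
    for frame in indicator_frames:
        for key, entry in frame.items():
            totals[key] = totals.get(key, 0) + (1 if entry.get(contact_class) else 0)
    n = len(indicator_frames)
    return TrajectoryContactSeries(
        contact_class,
        {key: count / n for key, count in totals.items()},
        n,
        criterion,
        cutoff,
    )


def trajectory_occupancy(
    source: str | Path | TextIO,
    registry: LipidRegistry | None = None,
    criterion: str = "distance",
    cutoff: float = DEFAULT_CUTOFF,
    params: GeometryParams | None = None,
    mask: Sequence[tuple[int, int]] = (),
) -> dict[str, TrajectoryContactSeries]:
    """Full pipeline: trajectory in, head and tail occupancy series out."""
    frames = read_trajectory(source, registry, mask)
    indicators = [
        frame_contacts(chain, lipids, criterion, cutoff, params)
        for chain, lipids in frames
    ]
    return {
        cls: occupancy(indicators, cls, criterion, cutoff)
        for cls in ("head", "tail")
    }


def counts_from_occupancy(
    chain: ProteinChain, series: TrajectoryContactSeries
):
    """Sum occupancy fractions into per-type fractional binding counts for
    the propensity formula."""
    from .propensity import ChainContactCounts

    n_by_type: dict[str, int] = {}
    nb_by_type: dict[str, float] = {}
    for res in chain.residues:
        n_by_type[res.name] = n_by_type.get(res.name, 0) + 1
        nb_by_type[res.name] = nb_by_type.get(res.name, 0.0) + series.occupancies.get(
            res.key, 0.0
        )
    return ChainContactCounts(chain.label, series.contact_class, n_by_type, nb_by_type)


def occupancy_table(series_by_class: Mapping[str, TrajectoryContactSeries]) -> pd.DataFrame:
    """Tidy per-residue occupancy table (one row per residue)."""
    keys = sorted(
        {k for s in series_by_class.values() for k in s.occupancies},
        key=lambda k: k[1],
    )
    data = {
        "residue": [k[0] for k in keys],
        "seq_id": [k[1] for k in keys],
    }
    for cls, s in series_by_class.items():
        data[f"{cls}_occupancy"] = [s.occupancies.get(k, 0.0) for k in keys]
    return pd.DataFrame(data)
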