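"""Per-chain amino acid lipid-contact propensities and their averages.

The propensity of residue type *i* in one chain is

    P_i = (N_i^b / N_i) / (N^b / N)

where N_i^b is the number of lipid-binding residues of type *i*, N_i the
total number of residues of type *i*, N^b the total number of binding
residues and N the chain length.  P_i = 1 means no preference; a type
absent from the chain has an undefined propensity and is excluded from
averaging.  Binding counts may be real-valued (trajectory occupancies), so
the same machinery serves crystal structures and MD snapshots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .structure_io import ProteinChain

AMINO_ACIDS: tuple[str, ...] = (
    "TRP", "PHE", "TYR", "LEU", "ILE", "CYS", "MET", "GLY", "VAL", "SER",
    "THR", "ALA", "HIS", "ASN", "PRO", "GLN", "ARG", "LYS", "ASP", "GLU",
)

__all__ = [
    "AMINO_ACIDS",
    "ChainContactCounts",
    "counts_from_flags",
    "chain_propensity",
    "average_propensities",
]


@dataclass(frozen=True)
class ChainContactCounts:
    """Residue and binding-residue counts of one chain for one contact
    class.  Binding counts are floats so trajectory occupancy fractions can
    be summed into them."""

    chain_label: str
    contact_class: str  # {"head", "tail"}
    n_by_type: Mapping[str, int]
    nb_by_type: Mapping[str, float]

    def __post_init__(self) -> None:
        for aa, nb in self.nb_by_type.items():
            n = self.n_by_type.get(aa, 0)
            if not -1e-9 <= nb <= n + 1e-9:
                raise ValueError(
                    f"{self.chain_label}/{aa}: binding count {nb} outside [0, {n}]"
                )

    @property
    def n_total(self) -> int:
        return sum(self.n_by_type.values())

    @property
    def nb_total(self) -> float:
        return sum(self.nb_by_type.values())


def counts_from_flags(
    chain: ProteinChain,
    flags: Mapping[tuple[str, int], Mapping[str, bool]],
    contact_class: str,
) -> ChainContactCounts:
    """Build counts from per-residue binding flags (see
    :func:`lipropen.contacts.residue_binding_flags`)."""
    n_by_type: dict[str, int] = {}
    nb_by_type: dict[str, float] = {}
    for res in chain.residues:
        n_by_type[res.name] = n_by_type.get(res.name, 0) + 1
        bound = flags.get(res.key, {}).get(contact_class, False)
        nb_by_type[res.name] = nb_by_type.get(res.name, 0.0) + (1.0 if bound else 0.0)
    return ChainContactCounts(chain.label, contact_class, n_by_type, nb_by_type)


def chain_propensity(counts: ChainContactCounts) -> dict[str, float] | None:
    """Propensities for one chain: type -> value, NaN where the type is
    absent (undefined).  Returns None when the chain has no binding
    residues at all (the chain contributes nothing to the average)."""
    n, nb = counts.n_total, counts.nb_total
    if n == 0 or nb <= 0:
        return None
    overall = nb / n
    out: dict[str, float] = {}
    for aa in AMINO_ACIDS:
        n_i = counts.n_by_type.get(aa, 0)
        if n_i == 0:
            out[aa] = math.nan
        else:
            out[aa] = (counts.nb_by_type.get(aa, 0.0) / n_i) / overall
    return out


def average_propensities(
    per_chain: Sequence[Mapping[str, float]],
    contact_class: str = "",
    source: str = "",
) -> pd.DataFrame:
    """Average per-chain propensities over a protein set.

    Undefined (NaN) entries are excluded type by type; the standard error
    of the mean is s/sqrt(n) with the n-1 sample standard deviation, over
    the n chains where the type was defined (NaN when n < 2).  Returns a
    DataFrame indexed by amino acid with columns mean, sem, n_chains.
    """
    if not per_chain:
        raise ValueError("no chains to average")
    mat = pd.DataFrame(list(per_chain), columns=list(AMINO_ACIDS), dtype=float)
    n_chains = mat.notna().sum()
    mean = mat.mean(skipna=True)
    sem = mat.std(ddof=1, skipna=True) / np.sqrt(n_chains)
    sem[n_chains < 2] = np.nan
    out = pd.DataFrame({"mean": mean, "sem": sem, "n_chains": n_chains})
    out.index.name = "amino_acid"
    out.attrs["contact_class"] = contact_class
    out.attrs["source"] = source
    return out
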