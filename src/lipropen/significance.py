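"""Pooled over/under-representation tests for lipid-binding residues.

Counts are pooled over a dataset (chains with fewer than six binding
residues of the given contact class are excluded), the expected binding
count per type is E_i = N_i * N^b / N, and each type is scored with the
one-cell goodness-of-fit statistic chi2_i = (O_i - E_i)^2 / E_i carrying
the sign of (O_i - E_i); p-values come from the 1-d.f. chi-square upper
tail of the unsigned statistic.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .propensity import AMINO_ACIDS, ChainContactCounts

MIN_BINDING_RESIDUES = 6

__all__ = [
    "MIN_BINDING_RESIDUES",
    "EmptyPoolError",
    "pool_counts",
    "signed_chi_square",
    "signed_chi2_value",
]


class EmptyPoolError(ValueError):
    """No chain passed the minimum-binding-residue filter."""


def pool_counts(
    chains: Sequence[ChainContactCounts],
    min_binding_residues: int = MIN_BINDING_RESIDUES,
    dataset_label: str = "",
) -> pd.DataFrame:
    """Pool per-chain counts into a dataset-level observed/expected table.

    Only chains with at least ``min_binding_residues`` binding residues of
    the given contact class contribute (applied per class, so a chain can
    qualify for tail contacts but not head).  Returns a DataFrame indexed
    by amino acid with columns obs, exp, n; the expected counts conserve
    the pooled binding total exactly.
    """
    # small tolerance so fractional (occupancy-summed) counts at the
    # boundary are not lost to float rounding
    kept = [c for c in chains if c.nb_total >= min_binding_residues - 1e-9]
    if not kept:
        raise EmptyPoolError(
            f"no chain has >= {min_binding_residues} binding residues"
        )
    n_i = {aa: 0 for aa in AMINO_ACIDS}
    o_i = {aa: 0.0 for aa in AMINO_ACIDS}
    for c in kept:
        for aa in AMINO_ACIDS:
            n_i[aa] += c.n_by_type.get(aa, 0)
            o_i[aa] += c.nb_by_type.get(aa, 0.0)
    n = sum(n_i.values())
    nb = sum(o_i.values())
    out = pd.DataFrame(
        {
            "obs": [o_i[aa] for aa in AMINO_ACIDS],
            "exp": [n_i[aa] * nb / n for aa in AMINO_ACIDS],
            "n": [n_i[aa] for aa in AMINO_ACIDS],
        },
        index=list(AMINO_ACIDS),
    )
    out.index.name = "amino_acid"
    out.attrs["dataset"] = dataset_label
    out.attrs["n_chains"] = len(kept)
    contact_classes = {c.contact_class for c in kept}
    if len(contact_classes) == 1:
        out.attrs["contact_class"] = contact_classes.pop()
    return out


def signed_chi2_value(obs: float, exp: float) -> float:
    """The signed one-cell statistic for a single type."""
    if exp <= 0:
        raise ValueError("expected count must be positive")
    stat = (obs - exp) ** 2 / exp
    return float(np.sign(obs - exp) * stat)


def signed_chi_square(summary: pd.DataFrame, bonferroni: bool = True) -> pd.DataFrame:
    """Signed chi-square and 1-d.f. p-value per amino acid type.

    Input is the obs/exp/n table from :func:`pool_counts`.  Types with
    zero expected count are skipped.  The raw p-values follow the printed
    convention (no multiple-testing correction); a Bonferroni column is
    appended as a clearly-labelled convenience.
    """
    rows = {}
    for aa, row in summary.iterrows():
        if row["exp"] <= 0:
            continue
        s = signed_chi2_value(row["obs"], row["exp"])
        p = float(chi2_dist.sf(abs(s), df=1))
        rows[aa] = {"obs": row["obs"], "exp": row["exp"], "n": row["n"],
                    "signed_chi2": s, "p_value": p}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "amino_acid"
    if bonferroni:
        out["p_bonferroni"] = np.minimum(out["p_value"] * len(out), 1.0)
    out.attrs.update(summary.attrs)
    return out
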