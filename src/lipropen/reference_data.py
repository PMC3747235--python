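"""Bundled reference tables.

Two kinds of fixed inputs ship with the package:

* The Wimley-White experimental lipophilicity scales: free energies
  (kcal/mol) of transferring amino acid side chains from water to the
  POPC bilayer interface and to bulk octanol, with ARG/LYS positive,
  ASP/GLU negative and HIS neutral.  Negative values mean favourable
  transfer into the lipid phase.
* Published reference propensity and enrichment tables from an
  atomic-resolution survey of lipid-bound membrane-protein structures
  (45 TM / 27 non-TM representative chains) and three 100-ns bilayer MD
  simulations.  These serve as comparison vectors for newly computed
  propensities and as regression anchors: reproducing the full tables
  requires the external PDB corpus and trajectories, but the downstream
  statistics (correlations, signed chi-square) recompute exactly from
  these printed values.
"""

from __future__ import annotations

import pandas as pd

from .propensity import AMINO_ACIDS

__all__ = [
    "lipophilicity_scales",
    "reference_propensities",
    "reference_enrichment",
]

# columns: crystal head mean, crystal head SEM, crystal tail mean,
# crystal tail SEM, MD head, MD tail, POPC scale, octanol scale
_REFERENCE = {
    "TRP": (2.41, 1.04, 3.25, 0.63, 5.44, 4.38, -1.85, -2.09),
    "PHE": (1.55, 0.50, 1.96, 0.43, 0.97, 1.97, -1.13, -1.71),
    "TYR": (2.17, 0.57, 1.15, 0.26, 2.12, 1.45, -0.94, -0.71),
    "LEU": (0.75, 0.17, 1.60, 0.23, 0.80, 1.70, -0.56, -1.25),
    "ILE": (0.47, 0.09, 1.46, 0.27, 0.48, 1.41, -0.31, -1.12),
    "CYS": (0.47, 0.32, 1.16, 0.93, 0.06, 1.68, -0.24, -0.02),
    "MET": (0.96, 0.25, 1.47, 0.38, 1.01, 1.56, -0.23, -0.67),
    "GLY": (0.53, 0.20, 0.43, 0.13, 0.42, 0.42, 0.01, 1.15),
    "VAL": (0.60, 0.18, 1.24, 0.41, 0.40, 1.23, 0.07, -0.46),
    "SER": (0.68, 0.20, 0.89, 0.25, 0.73, 0.44, 0.13, 0.46),
    "THR": (0.82, 0.25, 0.76, 0.15, 0.43, 0.35, 0.14, 0.25),
    "ALA": (0.54, 0.15, 0.92, 0.19, 0.22, 0.66, 0.17, 0.50),
    "HIS": (1.99, 0.39, 0.53, 0.09, 1.35, 0.88, 0.17, 0.11),
    "ASN": (1.92, 0.47, 0.43, 0.13, 1.57, 0.31, 0.42, 0.85),
    "PRO": (0.56, 0.37, 0.35, 0.12, 0.77, 0.65, 0.45, 0.14),
    "GLN": (1.69, 0.98, 0.51, 0.26, 1.26, 0.25, 0.58, 0.77),
    "ARG": (2.42, 0.65, 0.27, 0.21, 3.85, 0.43, 0.81, 1.81),
    "LYS": (1.64, 0.58, 0.23, 0.09, 3.26, 0.55, 0.99, 2.80),
    "ASP": (0.51, 0.32, 0.06, 0.04, 0.61, 0.00, 1.23, 3.64),
    "GLU": (0.56, 0.57, 0.30, 0.13, 0.93, 0.12, 2.02, 3.63),
}

# Pooled enrichment counts per (contact class, dataset): amino acid ->
# (observed binding residues, expected binding residues, total residues).
# Expected counts are reproduced at their printed precision (2 d.p. for the
# head tables, 1 d.p. for the tail tables).
_ENRICHMENT = {
    ("head", "TM"): {
        "TRP": (22, 9.12, 290), "PHE": (35, 22.65, 720), "TYR": (28, 12.90, 410),
        "LEU": (28, 37.40, 1189), "ILE": (11, 23.18, 737), "CYS": (2, 4.25, 135),
        "MET": (11, 11.51, 366), "GLY": (15, 28.06, 892), "VAL": (16, 26.70, 849),
        "SER": (14, 20.57, 654), "THR": (16, 19.53, 621), "ALA": (16, 29.85, 949),
        "HIS": (16, 8.05, 256), "ASN": (22, 11.45, 364), "PRO": (9, 15.98, 508),
        "GLN": (14, 8.30, 264), "ARG": (32, 13.24, 421), "LYS": (20, 12.20, 388),
        "ASP": (6, 11.73, 373), "GLU": (8, 14.34, 456),
    },
    ("head", "non-TM"): {
        "TRP": (3, 2.23, 84), "PHE": (13, 9.06, 341), "TYR": (21, 7.25, 273),
        "LEU": (20, 21.85, 823), "ILE": (9, 11.58, 436), "CYS": (2, 4.51, 170),
        "MET": (1, 4.22, 159), "GLY": (15, 13.54, 510), "VAL": (14, 15.11, 569),
        "SER": (13, 15.61, 588), "THR": (5, 10.62, 400), "ALA": (12, 17.55, 661),
        "HIS": (7, 5.47, 206), "ASN": (11, 9.00, 339), "PRO": (6, 10.36, 390),
        "GLN": (12, 9.77, 368), "ARG": (20, 10.41, 392), "LYS": (20, 13.01, 490),
        "ASP": (5, 11.79, 444), "GLU": (7, 13.04, 491),
    },
    ("tail", "TM"): {
        "TRP": (42, 12.9, 290), "PHE": (63, 32.1, 720), "TYR": (21, 18.3, 410),
        "LEU": (85, 53.0, 1189), "ILE": (48, 32.8, 737), "CYS": (7, 6.0, 135),
        "MET": (24, 16.3, 366), "GLY": (17, 39.7, 892), "VAL": (47, 37.8, 849),
        "SER": (26, 29.1, 654), "THR": (21, 27.7, 621), "ALA": (39, 42.3, 949),
        "HIS": (6, 11.4, 256), "ASN": (7, 16.2, 364), "PRO": (8, 22.6, 508),
        "GLN": (6, 11.8, 264), "ARG": (5, 18.8, 421), "LYS": (4, 17.3, 388),
        "ASP": (1, 16.6, 373), "GLU": (6, 20.3, 456),
    },
    ("tail", "non-TM"): {
        "TRP": (9, 3.07, 84), "PHE": (35, 12.45, 341), "TYR": (20, 9.97, 273),
        "LEU": (68, 30.05, 823), "ILE": (33, 15.92, 436), "CYS": (5, 6.21, 170),
        "MET": (13, 5.81, 159), "GLY": (4, 18.62, 510), "VAL": (34, 20.78, 569),
        "SER": (8, 21.47, 588), "THR": (7, 14.61, 400), "ALA": (24, 24.14, 661),
        "HIS": (3, 7.52, 206), "ASN": (3, 12.38, 339), "PRO": (9, 14.24, 390),
        "GLN": (2, 13.44, 368), "ARG": (7, 14.31, 392), "LYS": (8, 17.89, 490),
        "ASP": (2, 16.21, 444), "GLU": (3, 17.93, 491),
    },
}


def reference_propensities() -> pd.DataFrame:
    """Reference propensity columns and scales, indexed by amino acid.

    Columns: crystal_head, crystal_head_sem, crystal_tail, crystal_tail_sem,
    md_head, md_tail, popc, octanol.
    """
    cols = [
        "crystal_head", "crystal_head_sem", "crystal_tail", "crystal_tail_sem",
        "md_head", "md_tail", "popc", "octanol",
    ]
    df = pd.DataFrame.from_dict(_REFERENCE, orient="index", columns=cols)
    df = df.loc[list(AMINO_ACIDS)]
    df.index.name = "amino_acid"
    return df


def lipophilicity_scales() -> pd.DataFrame:
    """Water-to-POPC-interface and water-to-octanol transfer free energies
    (kcal/mol) per amino acid."""
    return reference_propensities()[["popc", "octanol"]].copy()


def reference_enrichment(contact_class: str, dataset: str) -> pd.DataFrame:
    """Pooled observed/expected binding-residue counts for one contact
    class ('head'/'tail') and dataset ('TM'/'non-TM'), as printed."""
    table = _ENRICHMENT[(contact_class, dataset)]
    df = pd.DataFrame.from_dict(table, orient="index", columns=["obs", "exp", "n"])
    df = df.loc[list(AMINO_ACIDS)]
    df.index.name = "amino_acid"
    df.attrs["contact_class"] = contact_class
    df.attrs["dataset"] = dataset
    return df
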