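# lipropen

Amino acid propensities for contacting phospholipid **head** and **tail**
groups, from crystal structures and MD-style trajectories.

Membrane proteins sit in a shell of annular and tightly-bound lipids, and
the chemistry of that interface — which residues reach for the phosphate
and polar head groups, which pack against the acyl tails — shapes both
stability and function. `lipropen` measures this at atomic resolution:

* **Contact detection.** Polar hydrogens are placed on the protein at
  idealized geometry, then residue–lipid contacts are classified as
  hydrogen bonds (donor–acceptor < 3.9 Å, H–acceptor ≤ 2.5 Å, and the
  D–H–A, D–A–AA and H–A–AA angles all > 90°, HBPLUS-style), van der Waals
  contacts (heavy-atom distance ≤ radii sum + 0.5 Å) or salt bridges
  (opposite formal charges ≤ 4.0 Å).
* **Head/tail partition.** Each lipid's heavy atoms are split on its
  molecular graph: the tail of each acyl chain runs from the carbon next
  to the ester carbonyl through the terminal methyl; glycerol, phosphate,
  polar substituent and the carbonyl/ester atoms are head. A registry of
  98 phosphoglyceride HET IDs ships with the package; mimetic lipids
  without a carbonyl carry explicit tail-start overrides.
* **Propensity scores.** For residue type *i* in one chain,

  *P*<sub>i</sub> = (*N*<sub>i</sub><sup>b</sup>/*N*<sub>i</sub>) / (*N*<sup>b</sup>/*N*),

  the fraction of type-*i* residues bound to lipid normalized by the
  chain's overall bound fraction (1 = neutral). Scores are averaged over a
  protein set with s/√n standard errors. Trajectories contribute
  *fractional* binding counts — the fraction of snapshots in which a
  residue touches lipid — through the same formula.
* **Enrichment tests.** Pooled counts per dataset are scored with a signed
  one-cell chi-square, χ²<sub>i</sub> = (O<sub>i</sub>−E<sub>i</sub>)²/E<sub>i</sub>
  with the sign of O<sub>i</sub>−E<sub>i</sub> and 1-d.f. p-values.
* **Vector comparison.** Propensity vectors are compared with each other
  and with the Wimley–White water→POPC-interface and water→octanol
  transfer free-energy scales via Pearson's r with leave-one-type-out
  jackknife standard errors.

## Worked example

The synthetic generator builds a helical chain with lipids placed so that
designated residues — and only they — satisfy the contact criteria:

```python
from lipropen import (screen_structure, find_contacts, residue_binding_flags,
                      counts_from_flags, chain_propensity)
from lipropen.synthetic_data import SyntheticSpec, make_complex, synthetic_registry

spec = SyntheticSpec(seed=7, designated_contacts={5: "tail", 9: "head", 12: "both"})
registry = synthetic_registry()
chains, lipids = screen_structure(make_complex(spec), registry)
chain = chains[0]
flags = residue_binding_flags(find_contacts(chain, lipids))
for (name, seq), f in sorted(flags.items(), key=lambda kv: kv[0][1]):
    print(f"{name}{seq}: head_bound={f['head']} tail_bound={f['tail']}")
p = chain_propensity(counts_from_flags(chain, flags, "tail"))
print({aa: round(v, 2) for aa, v in p.items() if v and v > 0 and v == v})
```

prints

```
MET5: head_bound=False tail_bound=True
GLN9: head_bound=True tail_bound=False
CYS12: head_bound=True tail_bound=True
{'CYS': 10.0, 'MET': 10.0}
```

Exactly the three designated residues carry their designed flags. The
chain has 40 residues of which 2 are tail-bound (overall rate 0.05); MET
and CYS each have one of one (or one of few) residues bound, hence tail
propensities well above 1 — a 1-in-1 bound type in a 5%-bound chain scores
(1/1)/(2/40) = 10.

The `lipropen` command exposes the same machinery from the shell
(`screen`, `contacts`, `md`, `synth`, `compare`); try
`lipropen compare` for the full 6×6 correlation matrix of the bundled
propensity vectors and lipophilicity scales, e.g. crystal vs. MD head
propensities correlate at 0.81 (jackknife SE 0.06) and crystal tail
propensities anti-correlate with the POPC interface scale at −0.87 (0.07).

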