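# Methods

## Scope and data model

The package quantifies how the twenty amino acid types contact the head
(hydrophilic) and tail (acyl) portions of phosphoglycerides, in two data
regimes: single crystal-style structures, where a residue either does or
does not contact lipid, and multi-frame trajectories, where contact is a
per-snapshot indicator averaged into an occupancy fraction. Both regimes
feed the same propensity statistic, so crystal and trajectory results are
directly comparable.

Inputs are PDB-format coordinates (single-model for structures,
multi-model for trajectories), a registry of phospholipid HET IDs, and a
sidecar TSV carrying sequence-cluster assignments and TM/non-TM labels.
Sequence clustering and membrane-topology annotation are deliberately
*inputs*: they come from external tools and databases, and recomputing
them is out of scope.

## Lipid head/tail partition

A lipid's heavy atoms are split on its molecular graph. Ester carbonyl
carbons are recognized as carbons bonded to one terminal and one bridging
oxygen plus a carbon; the tail of each chain is the connected carbon-only
component containing the acyl C2 (the carbon bonded to the carbonyl
carbon) after the carbonyl carbons are deleted. Because heteroatoms break
the carbon graph, glycerol and choline carbons can never leak into a tail.
The carbonyl carbon and both ester oxygens are head atoms: the partition
boundary is the carbon *next to* the carbonyl, which keeps the
hydrophobic/hydrophilic split clean. Mimetic lipids with no carbonyl
(ether-linked, phosphonate analogues) carry a per-HET `tail_start_atoms`
override in the registry file, because "the corresponding carbon" of a
mimetic is a curation decision, not a graph property. The bundled registry
lists the 98 phosphoglyceride component IDs; none carries an override out
of the box, so mimetics among them must be curated before use on real
deposited structures (a known limitation).

Bond graphs come from a chemical-component-dictionary mmCIF when one is
supplied, otherwise from a heavy-atom distance cutoff of 1.9 Å — deposited
lipids frequently lack CONECT records. Lipid hydrogens, when present,
follow their parent heavy atom's group.

## Structure screening

Crystal mode keeps entries with a recorded resolution of at most 4.0 Å
(entries without one — NMR and similar — are rejected), chains of at least
30 standard residues with selenomethionine read as MET and any other
non-standard amino acid disqualifying the chain, and all registry lipids.
Alternate conformations keep the highest-occupancy conformer, ties
resolved toward altloc `A`. Chains with no lipid contacts are removed
downstream, where the contact engine is available, before
cluster-representative selection: one chain per cluster, the one with the
most lipid-contacting residues, clusters discarded when every member has
fewer than five; ties break lexicographically on (structure id, chain id)
for determinism.

## Contact criteria

Hydrogen bonds follow the HBPLUS geometric definition. Polar hydrogens
are placed on the protein only, at 1.0 Å with standard hybridization:
backbone amides and side-chain sp2 donors (ARG, ASN, GLN, TRP, HIS) are
fully determined by their heavy-atom frames; rotatable donors (SER, THR,
TYR hydroxyls; LYS ammonium) scan their torsion in 10° steps and keep the
orientation whose hydrogen comes nearest a lipid acceptor, falling back
to torsion zero when none is in range. Neutral HIS is given hydrogens on
both ring nitrogens, so either tautomer's donation is detected. A bond
D–H⋯A(–AA) is accepted when D–A < 3.9 Å, H–A ≤ 2.5 Å, and D–H–A, D–A–AA,
H–A–AA all exceed 90° for every antecedent; aromatic acceptors would
additionally require the D–A–AX and H–A–AX axis angles below 20°, though
no lipid acceptor in practice is aromatic. The H–A criterion is read as a
maximum (≤ 2.5 Å); a point equality is physically meaningless.

Lipid atoms act as acceptors (all oxygens, plus nitrogens that are not
quaternary) and as charge centres only; lipid hydrogens are never placed,
since acyl and choline hydrogen positions in deposited coordinates are
unreliable. This drops only lipid-donated bonds, a conservative choice.

Van der Waals contacts use a compact per-element radius table (C 1.70,
N 1.55, O 1.52, S 1.80, P 1.80, Se 1.90 Å; unknown elements fall back to
1.70 with a logged warning, and a user table can override the defaults)
with a 0.5 Å tolerance on the radii sum; pairs already hydrogen-bonded
between the same two atoms are not double-counted as vdW. Salt bridges —
basic side-chain nitrogens (ARG NE/NH1/NH2, LYS NZ, HIS ND1/NE2) against
phosphate oxygens, and ASP/GLU carboxylate oxygens against quaternary
amine nitrogens — use a 4.0 Å heavy-atom cutoff; no geometric criterion
beyond distance is standard for this class, so the cutoff is configurable.
Salt-bridge records may coexist with hydrogen bonds for the same atom
pair; downstream statistics consume binary per-residue flags, where the
distinction is immaterial. Waters and non-registry heteroatoms are
ignored. Neighbour search uses a k-d tree; the test suite holds it equal
to brute-force all-pairs scans.

A residue is *head-bound* if any of its contacts targets a head atom and
*tail-bound* if any targets a tail atom; both flags can be set, because
classification is per contact, not per residue.

## Propensity and enrichment statistics

Per chain, P_i = (N_i^b/N_i)/(N^b/N). Types absent from a chain are
undefined (excluded from averages); present-but-unbound types score 0; a
chain with no binding residues contributes nothing. Averages over a
protein set use only defined values, with SEM = s/√n, s the n−1 sample
standard deviation and n the number of chains where the type is defined;
a single-chain SEM is reported as missing rather than zero. Head and tail
propensities share the same denominators N_i and N, with per-class N^b.
Counts always cover the entire chain, loops included — no TM-segment
masking. The exact identity Σ_i (N_i/N)·P_i = 1 holds per chain and is
asserted in tests.

For enrichment, counts are pooled over a dataset, keeping only chains
with at least six binding residues of the class under test (applied per
class, so a chain can qualify for tail but not head). With
E_i = N_i·N^b/N over the pooled totals, each type is scored with
χ²_i = (O_i−E_i)²/E_i signed by O_i−E_i, and a 1-d.f. upper-tail p-value
of the unsigned statistic; the sign conveys the direction, matching the
published convention of pairing a signed statistic with a raw p-value. No
multiple-testing correction is applied to the headline numbers; a
clearly-labelled Bonferroni column is emitted as a convenience.

## Trajectories

The per-snapshot contact criterion defaults to a heavy-atom distance
cutoff of 4.5 Å per lipid group — the MD-community norm, and far cheaper
than placing hydrogens in every frame — with the full crystal-style
criteria available via `criterion="hbplus"`. Which convention the original
trajectory analyses used is not documented; both are provided and the
default is stated in every output. Occupancies are exact ratios
(frames-in-contact / frames), invariant under frame reordering and
self-concatenation, and reduce to the crystal computation when all values
are 0 or 1. All provided frames are used by default; subsampling is a
property of the input. Large extra-membranous domains can be excluded with
a residue-range mask.

## Vector comparison

Pearson's r is computed over the intersection of defined types (≥ 3
required, undefined entries shrink the intersection). The jackknife
standard error uses σ² = ((N+1)/N)·Σ(C₍₋ᵢ₎−⟨C⟩)², with N the intersection
size. The (N+1)/N prefactor is the convention of the published tables this
package reproduces — the textbook jackknife uses (N−1)/N, and both are
available (`factor="conventional"`), with outputs labelling which was
used. Correlations use raw values, never ranks or rounded intermediates;
outlier-removal variants record the excluded types. The bundled reference
vectors (crystal and MD propensity columns, printed at 2 d.p.) reproduce
the published correlations at two-decimal precision; the bundled
lipophilicity scales fix ARG/LYS positive, ASP/GLU negative and HIS
neutral.

## Synthetic data

The generator produces the three input kinds with known ground truth and
no physical realism (no sterics, no bilayer, no force field):

* **Complexes** — an ideal α-helix (2.3 Å CA radius, 100° twist, 1.5 Å
  rise) with N/CA/C/O backbone and CB side-chain pseudo-atoms, plus one
  minimal lipid (`ZZL`: P1/O1/O2 head, C1–C8 tail, tail start declared by
  registry override) per designated residue, placed along the residue's
  outward normal so its nearest atom sits inside the vdW criterion
  (3.4 Å for a tail carbon, 3.2 Å for a head oxygen, a tangential layout
  for both-group contacts) while every other lipid atom stays beyond
  4.2 Å of every other residue; infeasible requests raise a generation
  error. The backbone bond geometry is approximate; fixtures that need
  exact hydrogen-bond geometry are built atom-by-atom in the tests
  instead.
* **Trajectories** — multi-model PDBs in which each designated residue's
  lipid is displaced 18 Å outward in non-contact frames; the contact
  frames number exactly round(q·n_frames), spread evenly, so realized
  occupancies equal their targets exactly. The default frame count is
  1000, matching the snapshot count of the trajectory analyses the
  package emulates.
* **Count tables** — multinomial residue compositions with binomial
  binding draws. Defaults mirror the crystal dataset scale: 45 chains of
  250 residues with mean binding probabilities of 0.04 (head) and 0.05
  (tail), the pooled bound fractions seen in structure surveys; the
  composition is uniform over the twenty types for simplicity, which
  overweights rare residues (TRP, CYS) relative to real proteomes.

What passing tests on these fixtures show is that the machinery — parsing,
partitioning, geometry, counting, statistics — is correct; they do not
show that real membrane proteins behave any particular way, since the
synthetic complexes have pseudo-side-chains, no packing, and designed
rather than physical contacts.

## Numerical choices and problem sizes

The ≥ 6 binding-residue filter admits fractional totals within 1e-9 of
the threshold so occupancy-summed counts are not lost to float rounding.
Chi-square p-values come from `scipy.stats.chi2.sf`. The type-I-error
calibration in the acceptance tests uses 2000 null replicates of a
4000-residue pool at binding probability 0.05 (expected counts ≈ 10 per
type, comfortably in the asymptotic regime); the one-cell statistic with
E estimated from the same pool is mildly conservative — the binomial
variance factor (1−p) deflates it — so the empirical rate sits slightly
below the nominal 0.05, within the 0.05 ± 0.02 acceptance band. Parameter
recovery runs 200–300 chains of 250 residues, enough for ratio-estimator
noise of a 3-fold-enriched type to fall well inside the stated
tolerances. Trajectory checks use 36-residue chains; the worked-example
occupancy target runs at the full 1000 frames.

## Known limitations

* Tail-start overrides for the mimetic members of the 98-lipid registry
  are not curated; real-data use requires filling them in.
* Hydrogen placement optimizes each rotatable donor independently against
  lipid acceptors only; no global network optimization, no protein-protein
  bonds (which the statistics never consume).
* Aromatic-acceptor axis checks are implemented but unused by the lipid
  chemistry covered here.
* The distance-based trajectory criterion treats head/tail by nearest
  heavy atom and ignores hydrogen-bond directionality.
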