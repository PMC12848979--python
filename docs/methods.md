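# Methods

## Scope and model

`aipmap` converts the 3D structure of a protonated protein–ligand
complex into an absolute binding free energy in water by summing the
contributions of paired atomic surface site interaction points (AIPs).
Each AIP stands for roughly 9 Å² of van der Waals surface — the footprint
of one H-bonding interaction — and carries a signed polarity ε (donors
and positive sites > 0, acceptors and negative sites < 0) and a
fractional weight f (0.5 for π-electron-density sites, which cover a
smaller patch; 1.0 otherwise).  The package assumes AIP values are
*transferable*: a functional group footprinted once on a small molecule
keeps its AIPs in any macromolecular context, which is reasonable for
proteins because the sp³ α-carbon breaks electronic communication between
residues' functional groups.  Conformation-dependent effects (e.g. an
intramolecular H-bond eliminating the participating sites) are taken as
already reflected in the input ligand description and are not recomputed.

Out of scope by design: computing AIPs from electronic structure
(footprinting) — ligand AIPs are consumed as CML input; charged ligands
and metal-containing sites; docking/pose generation; protonation-state
assignment; conformational entropy, explicit-water packing in tight
pockets, and H-bond cooperativity.

## Protein AIP assignment

Fragments are complete small molecules stored with fitted virtual-site
AIP templates.  A site's position is expressed relative to anchor atom 1
(the atom nearest the site) and anchors 2 and 3 (the two atoms fewest
bonds from atom 1):

    r_AIP = r1 + w12 (r2−r1) + w13 (r3−r1) + w_x (r2−r1)×(r3−r1)

The weights solve a 3×3 linear system in this basis; collinear anchors
are rejected (with the next candidate anchor pair tried first, chosen by
bond distance, then element priority C<N<O<S, then atom id).
Reconstruction is exact to numerical precision and rigid-motion
equivariant, so a template fitted on the fragment geometry can be
evaluated on the matched atoms of any target.

Matching uses subgraph *monomorphism* on the molecular graph: heavy atoms
must agree in element and hybridization (aromatic flags included), and a
fragment hydrogen bonded to carbon may additionally match a target carbon
that is sp³ or bonded to an sp³ carbon.  These truncation hydrogens stand
in for the bonds continuing into the macromolecule; monomorphism (rather
than induced isomorphism) is required because two truncation hydrogens
may land on target carbons that are themselves bonded.  Carbons matched
by a hydrogen receive no AIPs.

Coverage is greedy and iterative: the largest fragment with a match that
contributes at least one new AIP is applied, with the candidate list
restricted to fragments no larger than the number of atoms still lacking
an AIP description.  AIPs are never added to an atom that already has
them, and matched atoms stay visible to later rounds — adjacent fragments
necessarily overlap at the linking α-carbons.  The shipped library covers
the amide unit at two truncation levels (N-methylacetamide, and
N-methylformamide whose formyl hydrogen is a pure truncation marker);
with the acetamide form alone, consecutive amide units cannot be tiled,
because the methyl standing in for a mid-chain α-carbon always has one
hydrogen facing the preceding backbone nitrogen, which the
hydrogen-to-carbon rule cannot match.  Ties between equal-sized fragments
follow library order, and among matches of one fragment the
lexicographically smallest set of target atom ids wins, making the
build deterministic and independent of atom input order.

The shipped `protein_aip_ff_synthetic.xml` is a synthetic, toy-scale
stand-in for a full footprinted protein library (the published one is
external supplementary data): same format, structurally faithful
fragments, hand-placed AIPs with ε values in the range reported for the
corresponding site types.

## Contact identification

All thresholds are package constants, overridable per run:

| parameter | default | meaning |
|---|---|---|
| probe radius | 0.35 Å | SASA probe for per-AIP exposure |
| SASA cutoff | 9.8 Å² | sites with larger patches stay solvated |
| H-bond heavy cutoff | 3.0 Å | donor–acceptor heavy-atom distance |
| H-bond AIP cutoff | 2.2 Å | paired AIP distance for H-bonds |
| contact cutoff | 1.7 Å | AIP distance for all other contacts |
| E_vdW | −5.6 kJ/mol | nonpolar surface-contact energy |
| T | 298 K | temperature (not stated by the source method; standard-state convention for K_d/K_i data) |
| R | 8.314×10⁻³ kJ/(mol·K) | gas constant |

Per-AIP SASA uses deterministic Shrake–Rupley-style sampling (golden
spiral, 960 points/sphere by default; per-AIP values change by ≤ 2 % on
doubling, which the suite checks).  Every accessible point of an atom is
attributed to that atom's nearest AIP, the natural discretisation of the
~9 Å² site footprint; atoms without AIPs contribute no AIP area.  Van der
Waals radii are the Bondi set.  AIPs with SASA strictly greater than the
cutoff are eliminated before any pairing, so their desolvation never
enters the sum.

H-bonds are found first: polar-H sites versus lone-pair sites across the
interface, subject to both distance criteria, accepted greedily by
ascending AIP distance with deterministic ties (ligand atom id, then
protein atom id), each AIP used at most once.  Remaining cross-interface
AIP pairs closer than 1.7 Å form a bipartite graph; the pairing maximises
cardinality and, among maximum matchings, minimises total AIP distance.
This lexicographic objective is solved as a min-cost assignment with
candidate-edge cost (distance − M), M = 10⁶ ≫ n·1.7 Å, which makes
cardinality strictly dominant; the test suite checks optimality against
exhaustive enumeration.

## Free energies

Contact association constants follow the Boltzmann form above with the
repulsive clamp.  The bound-state free energy of either partner is the
two-term expression with K_tot = K_ij + K_vdW; its first term is
solute-independent and cancels from every ΔΔG.

Solvation is a single-solute-site reduction of the ensemble treatment of
the liquid.  The solvent is an ensemble of site types (ε_k, x_k) at total
density θ whose free fractions solve

    φ_k = 1 / (1 + θ Σ_l x_l φ_l (K_kl + K_vdW))

by damped fixed-point iteration (tolerance 10⁻¹⁴; the map is a
contraction for the water-like parameter range used here).  A solute site
i is then solvated against the *available* solvent surface:

    ΔG_S(i) = RT ln[(√(1+8θ)−1)/(4θ)] + RT ln[1 / (1 + θ Σ_k x_k φ_k (K_ik + K_vdW))]

The competition term matters: water is strongly self-associated, so its
free-site fractions are small, weakly polar solute sites are poorly
solvated, and nonpolar contacts become net attractive (the hydrophobic
effect).  A naive ensemble average without the φ factors cannot produce
attractive nonpolar contacts at all, because K_ij ≥ K_vdW always makes
the solvated state at least as favourable as the clamped bound state;
this is why the speciation form was chosen.

Both ΔG_B and ΔG_S share the solute-independent confinement term, raise
an explicit error on any non-positive or non-finite logarithm argument
(which signals an invalid θ or ε input), and reduce to zero as θ → 0.

## Water parameterization

The published water AIP ensemble and θ are external supplementary data.
The shipped `water_aip.solvent` is a two-site model (one donor, one
acceptor type at equal fractions) whose three parameters were calibrated
once, by least squares, against a published table of 22 per-contact free
energies for a protein–ligand complex (the same table shipped as
`aip_contacts_2w4x.tsv`):

    θ = 0.5777,  ε_donor = +2.316,  ε_acceptor = −5.987

The calibrated model reproduces the qualitative structure of that table —
nonpolar contacts at −1 to −3 kJ/mol, strong H-bonds down to −4, weaker
H-bonds near zero because desolvation cancels the bound term — with an
rms per-row deviation of 0.45 kJ/mol and a worst row of 1.1 kJ/mol; its
total over the table is −31.9 kJ/mol against the published −30.2.
Exact per-row agreement would require the original solvation
parameterization, so no test asserts per-row equality; the suite asserts
the model's monotonicity, symmetry and limit properties instead, and the
acceptance script reports the rms deviation as a measured number.  The
solvent file is swappable data, never hard-coded in logic.

## Synthetic test systems

`aipmap.fixtures` generates complete toy complexes as pure functions of a
seed: an engineered ideal H-bond inside a shielding pocket collar; rows
of CH-like sites whose optimal pairing is made provably unique (verified
against exhaustive enumeration at generation time, regenerating with a
derived sub-seed until uniqueness holds); a donor–donor clash that the
lint check must flag; and a buried-versus-protruding pair for the
exposure filter.  The collar/wall atoms exist because a bare toy
molecule's whole accessible sphere is attributed to its single AIP, which
would exceed the 9.8 Å² cutoff — real binding sites are buried, and the
fixtures emulate that burial explicitly.  What passing these tests shows:
the geometric rules, the optimisation and the bookkeeping are correct.
What they do not show: predictive accuracy on real complexes, which
depends on footprinted AIP values, crystal-structure protonation and the
full water parameterization, none of which the toys emulate.  The
published 94-complex benchmark (Pearson and Spearman 0.76, RMSE
11 kJ/mol) requires downloading those structures and their supplementary
AIP data plus manual hydrogen corrections; it is an optional external
validation, not part of the test suite.

Problem sizes used throughout (chosen to keep every check exhaustive or
near-exact): bipartite oracle instances up to 8×8 sites, subgraph oracle
graphs up to 12 atoms, 200 pairing instances and 1000 virtual-site
geometries in the acceptance script, batches of 5 synthetic complexes.

## Known limitations

* The hybridization/aromaticity perception for PDB input is
  connectivity-based (neighbour counts, planar 5/6-rings) and intended
  for well-formed protonated structures; exotic chemistry should arrive
  via CML, which carries explicit labels.
* The H→C matching rule is taken literally (carbons only); fragments must
  be designed so every truncation hydrogen faces a carbon, as the two
  shipped amide forms illustrate.  Whether the rule should extend to
  aromatic target carbons in practice is untested here beyond the stated
  "bonded to an sp³ carbon" condition.
* Solvation ignores cross-talk between neighbouring solute sites
  (each site is solvated independently at infinite dilution).
* Scoring uses the input geometry verbatim; no minimisation, no
  alternative binding modes.
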