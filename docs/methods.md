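# Methods

## The model

`hamartini` implements a Martini 3 coarse-grained (CG) representation of
hyaluronic acid (HA), the linear glycosaminoglycan built from repeating
GlcNAc–GlcA disaccharides joined by β(1→3) and β(1→4) glycosidic linkages.
Each disaccharide is represented by 9 beads; a free GlcNAc carries 5 beads
and a free GlcA 4. Beads come in three Martini sizes — tiny (T, 2 heavy
atoms, 36 u), small (S, 3 heavy atoms, 54 u) and regular (R, 4 heavy atoms,
72 u) — and are typed P3r/P2r/N4r/N5ar/Q5n according to the polarity of the
mapped chemical group. The carboxylate bead S6 carries the single −1 charge
per dimer, so an HA chain of n monosaccharides has net charge −n/2.

The bonded interactions use five functional forms in their GROMACS
dialects:

| form | GROMACS funct | potential |
|---|---|---|
| bond stretch | bonds 1 | ½ k_b (b − b₀)² |
| angle bend (G96) | angles 2 | ½ k_θ (cos θ − cos θ₀)² |
| restricted bend | angles 10 | ½ k_θ (cos θ − cos θ₀)² / sin² θ |
| improper dihedral | dihedrals 2 | ½ k_ξ (ξ − ξ₀)², Δξ wrapped and in radians |
| proper dihedral | dihedrals 1 | k_φ (1 + cos(m φ − φ₀)) |

The restricted-bending form is used for the one backbone angle whose
equilibrium value (146°) approaches linearity (B6–B9–B8); its divergence at
θ = 180° is the point of the functional form, and the evaluator reproduces
it up to a configurable cap (default 10⁶ kJ/mol) to keep scans finite.

Glycosidic-linkage conformation is held near the exo-syn minimum mainly by
two proper dihedrals per dimer: B1–B3–B8–B6 (the 1→4 linkage, k = −32
kJ/mol) and B8–B7–B12–B11 (the 1→3 linkage across the dimer junction,
k = −60 kJ/mol), both with multiplicity 1. Several bonds between
non-adjacent beads exist purely to stabilize near-linear triplets; they are
real bonds, so their endpoint pairs are also excluded from nonbonded
interactions under `nrexcl = 1`.

### Units and conventions

Distances are nm, energies kJ/mol, angles degrees in all user-facing data.
Improper force constants are printed in the parameter tables with a
deg⁻² unit header, but GROMACS dihedral type 2 interprets the constant per
rad²; the package stores and serializes the printed values verbatim (so a
GROMACS run with the emitted ITP behaves exactly like the original files)
and the energy evaluator converts the angular deviation to radians before
squaring, i.e. it follows the GROMACS semantics. Providing an alternative
"literal deg⁻²" evaluator was deliberately rejected to avoid silent unit
misuse.

Beads are 1-based everywhere a user sees them (terms, ITP records,
reports); coordinate arrays are 0-based NumPy rows, row i holding bead
i + 1.

## Parameter storage

All numeric parameters live in one JSON data file inside the package,
protected by a SHA-256 checksum over its canonical serialization and
validated on first load. No force-field literal appears in code. The
monomer tables (GlcNAc: 6 bonds, 3 angles, 2 impropers; GlcA: 4 bonds,
2 angles, 1 improper) and the dimer template (12 intra bonds, 8 intra
angles, 5 intra impropers, 1 intra dihedral; 4 junction bonds, 3 junction
angles, 2 junction impropers, 1 junction dihedral) are stored once —
periodic images are never duplicated.

## Chain expansion and end groups

A chain of n monosaccharides (n even; odd counts are rejected because the
parameter scheme has no GlcNAc reducing end) is expanded by the
periodicity rule: the template's terms, whose indices refer to beads 1–9
(junction terms reaching into 10–18), are re-emitted with offset 9r for
the r-th dimer, junction terms only while a following dimer exists. Term
counts are therefore linear in the dimer count n: 12n + 4(n−1) bonds,
8n + 3(n−1) angles, 5n + 2(n−1) impropers, n + (n−1) dihedrals.

End-group logic: the reducing-end GlcA anomeric bead gains the anomeric
hydroxyl and grows T7 → S7; bead 2 stays T2 throughout a chain because the
non-reducing terminus is GlcNAc, whose anomeric carbon is engaged in no
linkage-direction change. Free monomers grow their anomeric bead (S2 /
S7). Bonded terms are identical for end and internal residues: the
parameter set defines no end-specific rows, and the package follows that.

Recommended integration time steps are 0.01 ps for chains and 0.03 ps for
free monosaccharides — the values at which the model is stable in MD — and
are emitted into the MDP template together with the validated run
settings (reaction-field electrostatics with ε_r = 15, 1.1 nm cutoffs,
V-rescale at 298 K, Parrinello–Rahman at 1 bar).

## Starting coordinates

`build_initial_coordinates` tiles a frozen 9-bead dimer template along a
fixed pitch vector (~0.95 nm per dimer). The template and pitch were
obtained once by least-squares relaxation of the model's own bonded terms
for a tetramer under the constraint that consecutive dimers are rigid
translates, then frozen as constants; generation at run time is pure
arithmetic and therefore bit-reproducible. The structures are primitive
starting points (all bonds well within 3×b₀, no steric clashes at 0.23 nm
minimum separation), not equilibrium conformations.

## Atomistic-to-CG mapping

Mapping uses the center of geometry (COG): each bead sits at the
unweighted mean of its group's heavy atoms plus carbon-bound hydrogens.
O–H and N–H hydrogens belong to no group, so their presence or absence
never moves a bead. The default naming dialect is the CHARMM36
carbohydrate scheme; other dialects can be added as data without code
changes.

Oxygen ownership is residue-local: O3 of GlcNAc belongs to the
ethanolamine bead R3 and O4 of GlcA to the oxyethyl bead S9, whether the
oxygen is a free hydroxyl or engaged in a glycosidic bond. This choice
(over assigning bridging oxygens to the partner anomeric bead) keeps every
bead's heavy-atom count equal to its size class — T = 2, S = 3, R = 4 —
for internal, reducing-end and free variants alike, and makes the per-
residue atom partition exact. It is a documented convention; the
published mapping figure does not resolve the question either way.

## Persistence length

Backbone bond vectors are defined between consecutive R3/S9 beads
(indices 3 + 9r and 9 + 9s), giving 2n − 1 vectors for n dimers. The
autocorrelation C(n) is the average over frames and index pairs of the
dot product of *unit* vectors n bonds apart (normalization by unit
vectors, recorded in the fit metadata, since raw-dot-product
normalization is an equally defensible reading). l_p comes from a direct
nonlinear least-squares fit of C(n) = exp(−n·d/l_p), with d the mean
backbone bond length over all selected vectors and frames; a log-space
linear fit is available as a cross-check. The default fit range is
n ∈ [1, n_max] with n_max the largest n where C(n) exceeds the 0.05 noise
floor, capped at half the series length. A series that does not decay
(all points above 0.95 over the range) is reported as "exceeds resolvable
range" with l_p = None rather than a number.

## Synthetic ensembles

The WLC sampler realizes the Kratky–Porod correlation structure with a
freely rotating chain: a fixed bend angle with cos θ = exp(−d/l_p) and an
independent uniform azimuth per step, so E[C(n)] = exp(−n·d/l_p) holds
exactly and the estimator can be validated against a closed form. This
emulates the decay of orientational correlations of real HA chains but
none of their excluded volume, electrostatics, or torsional structure —
estimator tests on it validate the statistics pipeline, not the force
field. Sampling uses NumPy's PCG64 generator; seeds are recorded in the
output metadata and all generators are pure functions of (spec, seed).

Validation scale: the persistence-length recovery checks use 99-bond
chains (the backbone-vector count of a 100-mer) at 10⁴ frames with
l_p/d ∈ {5, 10, 20}, where the estimator recovers l_p within a few
percent; the tolerance asserted is 10%.

## SASA and aggregation

SASA uses Shrake–Rupley point sampling (via biotite) with per-size bead
radii 0.191 / 0.230 / 0.264 nm (T/S/R) and a default probe radius of
0.14 nm, all configurable; areas converge to well under 0.5% on doubling
the point count at the default 1000 points. The published analysis used
the double-cubic-lattice method — a different algorithm for the same
quantity; agreement is at the level of the convergence tolerance.
Aggregates are quantified by single-linkage clustering of molecules
linked when any inter-bead distance falls below a cutoff (default 0.6 nm,
a contact-distance convention for R beads, not a published value).

## Known limitations

- Nonbonded pair parameters are not shipped: topologies reference Martini
  3 bead type names and defer the C6/C12 pair matrix to the user's
  Martini 3 distribution files. No nonbonded energies are evaluated.
- No forces/gradients; the energy evaluator is a validation surface, not
  an MD engine. Observables that require equilibrium sampling (transfer
  free energies, the long-chain persistence length in salt solution)
  need an external MD engine; this package emits the complete run inputs
  for those simulations.
- Starting structures are primitive; equilibration is the MD engine's
  job.
- The mapper handles single residues and linked chains with CHARMM36
  names; back-mapping (CG→AA) is out of scope.
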