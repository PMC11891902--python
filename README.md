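# hamartini

Martini 3 coarse-grained modelling tools for hyaluronic acid (HA):
topology generation, atomistic-to-CG mapping, bonded-energy evaluation,
and chain-scale analysis.

HA is the linear glycosaminoglycan of repeating GlcNAc–GlcA disaccharides
joined by β(1→3) and β(1→4) glycosidic bonds. In the Martini 3
representation implemented here, each disaccharide maps to 9 beads (free
GlcNAc: 5, free GlcA: 4) placed at the center of geometry of their atom
groups, with one −1 carboxylate charge per dimer. The bonded model uses
harmonic bonds (V = ½k_b(b−b₀)²), G96 cosine angles
(V = ½k_θ(cos θ − cos θ₀)²), a restricted-bending angle for the
near-linear backbone triplet (the same form divided by sin²θ), harmonic
improper dihedrals, and two periodic torsions per dimer
(V = k_φ(1 + cos(mφ − φ₀))) that hold the 1→4 and 1→3 linkages in the
exo-syn conformation. Chains of arbitrary (even) length are expanded from
a single dimer parameter template by the bead-index periodicity rule
(offset 9r for the r-th dimer), so no force-field file ever needs hand
editing.

The package is aimed at researchers running GROMACS Martini 3 simulations
of glycosaminoglycans who need reproducible topologies, validation of
geometries/energies, and standard polymer observables (persistence length
from bond-vector autocorrelation, radius of gyration, end-to-end
distance, SASA with Martini bead radii, aggregate clustering).

## Worked example

Build an HA octamer with a starting structure and run settings:

```sh
$ hamartini build --units 8 --out-itp ha8.itp --out-gro ha8.gro --mdp ha8.mdp
HA8: 36 beads, net charge -4, recommended dt 0.01 ps
```

36 beads is 9 per disaccharide × 4 dimers; the net charge −4 is one
carboxylate (Q5n bead) per dimer, which tells you how many counter-ions
to add. The recommended 0.01 ps time step is the value at which the
chain model is stable in MD (free monosaccharides tolerate 0.03 ps).
The ITP contains `[ bonds ]` funct 1, `[ angles ]` funct 2 and funct 10
(the restricted-bending backbone angle), and two `[ dihedrals ]`
sections (funct 2 impropers, funct 1 propers); pair (LJ) parameters are
resolved by bead type names against your Martini 3 distribution files.

Evaluate the bonded energy of the generated structure:

```sh
$ hamartini energy --itp ha8.itp --gro ha8.gro
frame 0: total=-414.516 bonds=29.312 angles=17.076 impropers=14.988 dihedrals=-475.892
```

The harmonic classes (bonds/angles/impropers) are small and positive —
the primitive starting structure sits near the reference geometry — and
the proper-dihedral class is negative because both linkage torsions have
negative force constants (k = −32 and −60 kJ/mol), making their minima
negative.

From Python, the same objects are a few calls away:

```python
import hamartini as hm
from hamartini import analysis, synthetic

top = hm.build_chain_topology(100)        # 450 beads, charge -50
coords = hm.build_initial_coordinates(top)

# persistence length from a worm-like-chain ensemble with known stiffness
spec = synthetic.WLCSpec(n_bonds=99, d=0.5, l_p=5.0, n_frames=10_000, seed=1)
fit = analysis.persistence_length(synthetic.sample_wlc(spec).vectors)
print(fit.l_p)          # ~5.0 nm, recovered within a few percent
```

Map an atomistic structure (CHARMM36 names) onto beads:

```sh
hamartini map --in fragment.pdb --out fragment_cg.gro
```

## Layout

- `hamartini.params` — typed, checksummed force-field tables (single
  source of truth)
- `hamartini.topology` — monomer/chain builders, starting coordinates
- `hamartini.gmxio` — ITP writer/parser, GRO/PDB/MDP output, trajectory
  reading (MDAnalysis)
- `hamartini.mapper` — COG mapping from CHARMM36-named structures
- `hamartini.energy` — internal-coordinate measurement and the five
  bonded-energy forms
- `hamartini.analysis` — persistence length, Rg/e2e, SASA, aggregation
  clusters
- `hamartini.synthetic` — WLC sampler, perturbed geometries, toy
  atomistic fragments
- `hamartini.cli` — the `hamartini` command

See `docs/methods.md` for the model, conventions and limitations.
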