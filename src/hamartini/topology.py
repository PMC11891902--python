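"""Topology construction for HA monosaccharides and chains.

Expands the monomer tables and the dimer template into complete bonded
topologies for hyaluronic-acid chains of arbitrary (even) monosaccharide
count, applying the dimer periodicity rule: the terms of the template,
whose indices refer to beads 1-9 of the first dimer (junction terms reach
into 10-18), are re-emitted with an offset of 9*r for the r-th dimer.

Index convention: beads are 1-based everywhere a user sees them (topology
terms, ITP output, reports).  Coordinate arrays are plain (n, 3) NumPy
arrays in nm, row ``i`` holding bead ``i+1``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import params as ffp
from .params import (
    AngleTerm,
    BondTerm,
    DihedralTerm,
    ImproperTerm,
)

__all__ = [
    "Bead",
    "Topology",
    "build_monomer_topology",
    "build_chain_topology",
    "build_initial_coordinates",
]


@dataclass(frozen=True)
class Bead:
    """A bead instance inside a concrete molecule (global 1-based index)."""

    index: int
    label: str
    martini_type: str
    size_class: str
    charge: int
    mass: float
    residue_name: str
    residue_number: int


@dataclass
class Topology:
    molecule_name: str
    beads: list[Bead]
    bonds: list[BondTerm]
    angles: list[AngleTerm]
    impropers: list[ImproperTerm]
    dihedrals: list[DihedralTerm]
    nrexcl: int = 1

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def net_charge(self) -> int:
        return sum(b.charge for b in self.beads)

    @property
    def n_residues(self) -> int:
        return len({b.residue_number for b in self.beads})

    @property
    def exclusions(self) -> list[tuple[int, int]]:
        """Nonbonded exclusion pairs: every directly bonded pair (nrexcl 1).

        The stabilizing bonds between non-adjacent beads are bonds, so their
        endpoints are excluded too, matching GROMACS semantics.
        """
        return sorted({tuple(sorted((t.i, t.j))) for t in self.bonds})

    @property
    def recommended_timestep(self) -> float:
        """Stable MD time step in ps (0.01 for chains, 0.03 for monomers)."""
        kind = "chain" if self.n_residues >= 2 else "monomer"
        return ffp.recommended_timestep(kind)

    def validate(self) -> None:
        n = self.n_beads
        if [b.index for b in self.beads] != list(range(1, n + 1)):
            raise ValueError("bead indices must be 1..n in order")
        for group in (self.bonds, self.angles, self.impropers, self.dihedrals):
            for t in group:
                if not all(1 <= x <= n for x in t.indices):
                    raise ValueError(f"term {t} references a bead outside 1..{n}")
        if n > 1:
            ij = np.array([(t.i - 1, t.j - 1) for t in self.bonds])
            adj = coo_matrix(
                (np.ones(len(ij)), (ij[:, 0], ij[:, 1])), shape=(n, n)
            )
            n_comp, _ = connected_components(adj, directed=False)
            if n_comp != 1:
                raise ValueError(
                    f"bond graph is not connected ({n_comp} components)"
                )


def _shift(term, offset: int):
    if isinstance(term, BondTerm):
        return replace(term, i=term.i + offset, j=term.j + offset)
    if isinstance(term, AngleTerm):
        return replace(term, i=term.i + offset, j=term.j + offset, k=term.k + offset)
    return replace(
        term,
        i=term.i + offset,
        j=term.j + offset,
        k=term.k + offset,
        l=term.l + offset,
    )


def _bead_instance(
    d: ffp.BeadDefinition, global_index: int, residue_number: int
) -> Bead:
    return Bead(
        index=global_index,
        label=d.label,
        martini_type=d.martini_type,
        size_class=d.size_class,
        charge=d.charge,
        mass=d.mass,
        residue_name=ffp.residue_of_bead(d.index_in_dimer).upper(),
        residue_number=residue_number,
    )


def build_monomer_topology(residue: str) -> Topology:
    """Topology of a free GlcNAc (5 beads) or GlcA (4 beads) monosaccharide.

    The anomeric bead carries the free anomeric hydroxyl and is therefore
    size S (S2 for GlcNAc, S7 for GlcA).  Net charge is -1 for GlcA (the
    carboxylate S6) and 0 for GlcNAc.
    """
    defs = ffp.bead_catalog("free_monomer", residue)
    offset = defs[0].index_in_dimer - 1  # GlcA beads 6-9 -> global 1-4
    beads = [
        _bead_instance(d, d.index_in_dimer - offset, 1) for d in defs
    ]
    pset = ffp.monomer_parameter_set(residue)
    top = Topology(
        molecule_name=_normalized_name(residue),
        beads=beads,
        bonds=[_shift(t, -offset) for t in pset.bonds],
        angles=[_shift(t, -offset) for t in pset.angles],
        impropers=[_shift(t, -offset) for t in pset.impropers],
        dihedrals=[_shift(t, -offset) for t in pset.dihedrals],
    )
    top.validate()
    return top


def _normalized_name(residue: str) -> str:
    return {"GlcNAc": "GLCNAC", "GlcA": "GLCA"}[
        ffp._normalize_residue(residue)
    ]


def build_chain_topology(n_units: int, molecule_name: str | None = None) -> Topology:
    """Topology of an HA chain of ``n_units`` monosaccharides.

    The chain starts with GlcNAc at the non-reducing end and must end with
    GlcA at the reducing end, so ``n_units`` must be even and positive; each
    GlcNAc-GlcA dimer contributes 9 beads.  The reducing-end GlcA anomeric
    bead is grown to S7; every other bead keeps its internal size.  Junction
    terms are emitted between consecutive dimers only.
    """
    if n_units < 2 or n_units % 2 != 0:
        raise ValueError(
            f"n_units must be an even count >= 2 (got {n_units}): HA is a strict "
            "GlcNAc-GlcA repeat and no parameters exist for a GlcNAc reducing end"
        )
    n_dimers = n_units // 2
    template = ffp.chain_parameter_template()

    beads: list[Bead] = []
    for r in range(n_dimers):
        variant = "reducing_end" if r == n_dimers - 1 else "internal"
        for d in ffp.bead_catalog(variant):
            res_no = 2 * r + (1 if d.index_in_dimer <= 5 else 2)
            beads.append(_bead_instance(d, 9 * r + d.index_in_dimer, res_no))

    top = Topology(
        molecule_name=molecule_name or f"HA{n_units}",
        beads=beads,
        bonds=[],
        angles=[],
        impropers=[],
        dihedrals=[],
    )
    for r in range(n_dimers):
        off = 9 * r
        top.bonds += [_shift(t, off) for t in template.intra.bonds]
        top.angles += [_shift(t, off) for t in template.intra.angles]
        top.impropers += [_shift(t, off) for t in template.intra.impropers]
        top.dihedrals += [_shift(t, off) for t in template.intra.dihedrals]
        if r < n_dimers - 1:
            top.bonds += [_shift(t, off) for t in template.junction.bonds]
            top.angles += [_shift(t, off) for t in template.junction.angles]
            top.impropers += [_shift(t, off) for t in template.junction.impropers]
            top.dihedrals += [_shift(t, off) for t in template.junction.dihedrals]
    top.validate()
    return top


# ---------------------------------------------------------------------------
# Canonical starting geometries (nm).
#
# The 9-bead dimer template and its periodic pitch vector were obtained once
# by minimizing the model's own bonded energy for an HA tetramer under the
# constraint that dimer r+1 is dimer r rigidly translated by the pitch; the
# monomer templates were minimized against the monomer tables.  Frozen here
# so that coordinate generation is deterministic arithmetic.
# ---------------------------------------------------------------------------

_GLCNAC_XYZ = np.array([
    [-0.380522, -0.009221, 0.064424],
    [-0.043848, 0.051774, -0.168560],
    [0.132262, -0.006506, 0.047311],
    [-0.131982, -0.002185, 0.169769],
    [0.424091, -0.033862, -0.112944],
])
_GLCA_XYZ = np.array([
    [-0.064877, 0.203202, -0.169821],
    [0.129404, -0.159907, -0.076962],
    [-0.008232, -0.154300, 0.184335],
    [-0.056295, 0.111005, 0.062448],
])
_CHAIN_DIMER_XYZ = np.array([
    [-0.359934, 0.135668, -0.234908],
    [-0.092522, 0.064464, -0.005100],
    [-0.164833, -0.071914, 0.168805],
    [-0.377702, 0.056705, 0.026377],
    [0.025130, -0.272235, 0.349952],
    [0.180183, 0.242809, 0.038980],
    [0.396852, 0.008539, -0.125625],
    [0.232292, -0.182292, -0.198532],
    [0.160533, 0.018254, -0.019950],
])
_CHAIN_PITCH = np.array([0.834060, 0.048519, -0.458355])


def build_initial_coordinates(
    topology: Topology, template: np.ndarray | None = None
) -> np.ndarray:
    """Deterministic, clash-free starting coordinates (nm) for a topology.

    Chains are built by tiling the canonical dimer template along its pitch
    vector; free monomers use their own minimized templates.  A custom
    ``template`` may be supplied for chains: an array of 9 bead positions
    used per dimer (the default pitch still applies).
    """
    if topology.n_residues == 1:
        base = _GLCNAC_XYZ if topology.molecule_name == "GLCNAC" else _GLCA_XYZ
        if topology.n_beads != len(base):
            raise ValueError("monomer topology does not match template size")
        return base.copy()
    n_dimers = topology.n_beads // 9
    tile = _CHAIN_DIMER_XYZ if template is None else np.asarray(template, float)
    if tile.shape != (9, 3):
        raise ValueError("chain spacing template must have shape (9, 3)")
    out = np.concatenate(
        [tile + r * _CHAIN_PITCH for r in range(n_dimers)], axis=0
    )
    return out
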