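"""Force-field parameter tables for the Martini 3 hyaluronic-acid model.

All bonded parameters of the model — the GlcNAc and GlcA monosaccharide
tables and the disaccharide (dimer) template with its inter-dimer junction
terms — are shipped as a single checksummed JSON data file and exposed here
as typed, queryable objects.  Every other module treats this one as the
single source of truth; no numeric force-field literal appears anywhere
else in the package.

Bead indexing follows the HA dimer convention: beads 1–5 belong to GlcNAc
(non-reducing side), beads 6–9 to GlcA.  Junction terms of the dimer
template reference beads 10–18, i.e. beads 1–9 of the *next* dimer.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Literal

__all__ = [
    "BeadDefinition",
    "BondTerm",
    "AngleTerm",
    "ImproperTerm",
    "DihedralTerm",
    "ParameterSet",
    "DimerTemplate",
    "NonbondedConfig",
    "RESIDUES",
    "monomer_parameter_set",
    "chain_parameter_template",
    "bead_catalog",
    "nonbonded_config",
    "bead_mass",
    "sasa_radius",
    "recommended_timestep",
]

RESIDUES = ("GlcNAc", "GlcA")

Variant = Literal["internal", "reducing_end", "free_monomer"]
AngleForm = Literal["g96", "restricted"]

_DATA_FILE = "ha_martini3.json"


class UnknownResidueError(KeyError):
    """Raised for residue identifiers outside the supported set."""

    def __init__(self, residue: str):
        super().__init__(residue)
        self.residue = residue

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"unknown residue {self.residue!r}; supported residues are "
            + ", ".join(RESIDUES)
        )


def _normalize_residue(residue: str) -> str:
    for name in RESIDUES:
        if residue.lower() == name.lower():
            return name
    raise UnknownResidueError(residue)


@dataclass(frozen=True)
class BeadDefinition:
    """One coarse-grained interaction center of the HA model."""

    index_in_dimer: int
    label: str
    martini_type: str
    size_class: str  # T (2 heavy atoms), S (3) or R (4)
    charge: int  # elementary charges
    mapped_group: str
    variant: Variant = "internal"

    @property
    def mass(self) -> float:
        """Martini 3 convention: 72 u (R), 54 u (S), 36 u (T)."""
        return bead_mass(self.size_class)


@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    k_b: float  # kJ mol^-1 nm^-2
    b0: float  # nm

    @property
    def indices(self) -> tuple[int, ...]:
        return (self.i, self.j)


@dataclass(frozen=True)
class AngleTerm:
    i: int
    j: int
    k: int
    k_theta: float  # kJ mol^-1
    theta0: float  # degrees
    form: AngleForm = "g96"  # GROMACS funct 2 (g96 cosine) or 10 (restricted)

    @property
    def indices(self) -> tuple[int, ...]:
        return (self.i, self.j, self.k)


@dataclass(frozen=True)
class ImproperTerm:
    """Harmonic improper dihedral (GROMACS dihedral funct 2).

    ``k_xi`` is stored and serialized verbatim as printed in the parameter
    tables; the energy evaluator applies the GROMACS convention (the angular
    deviation is converted to radians).
    """

    i: int
    j: int
    k: int
    l: int
    k_xi: float
    xi0: float  # degrees

    @property
    def indices(self) -> tuple[int, ...]:
        return (self.i, self.j, self.k, self.l)


@dataclass(frozen=True)
class DihedralTerm:
    """Periodic proper dihedral (GROMACS dihedral funct 1)."""

    i: int
    j: int
    k: int
    l: int
    k_phi: float  # kJ mol^-1, may be negative
    phi0: float  # degrees (phase)
    m: int  # multiplicity

    @property
    def indices(self) -> tuple[int, ...]:
        return (self.i, self.j, self.k, self.l)


@dataclass(frozen=True)
class NonbondedConfig:
    """Nonbonded treatment of the model.

    Only the configuration is held here — bead types, the single S6 charge,
    first-neighbour exclusions, reaction-field settings.  The Lennard-Jones
    C6/C12 pair matrix is defined by the Martini 3 distribution files and is
    deliberately not duplicated: topologies reference bead type names only.
    """

    exclusion_depth: int
    eps_r: float
    cutoff: float  # nm
    pair_table_source: str


class ParameterSet:
    """Bonded terms of one residue table (or one term group) with lookup."""

    def __init__(
        self,
        bonds: Iterable[BondTerm] = (),
        angles: Iterable[AngleTerm] = (),
        impropers: Iterable[ImproperTerm] = (),
        dihedrals: Iterable[DihedralTerm] = (),
    ):
        self.bonds = list(bonds)
        self.angles = list(angles)
        self.impropers = list(impropers)
        self.dihedrals = list(dihedrals)

    def bond(self, i: int, j: int) -> BondTerm:
        for t in self.bonds:
            if {t.i, t.j} == {i, j}:
                return t
        raise KeyError(f"no bond between beads {i} and {j}")

    def angle(self, i: int, j: int, k: int) -> AngleTerm:
        for t in self.angles:
            if (t.i, t.j, t.k) in ((i, j, k), (k, j, i)):
                return t
        raise KeyError(f"no angle {i}-{j}-{k}")

    def improper(self, i: int, j: int, k: int, l: int) -> ImproperTerm:
        for t in self.impropers:
            if t.indices in ((i, j, k, l), (l, k, j, i)):
                return t
        raise KeyError(f"no improper dihedral {i}-{j}-{k}-{l}")

    def dihedral(self, i: int, j: int, k: int, l: int) -> DihedralTerm:
        for t in self.dihedrals:
            if t.indices in ((i, j, k, l), (l, k, j, i)):
                return t
        raise KeyError(f"no proper dihedral {i}-{j}-{k}-{l}")

    def __len__(self) -> int:
        return (
            len(self.bonds) + len(self.angles) + len(self.impropers) + len(self.dihedrals)
        )


class DimerTemplate(ParameterSet):
    """The full HA dimer parameter block plus its junction terms.

    ``intra`` terms act among beads 1–9 of one dimer; ``junction`` terms span
    two consecutive dimers and reference beads 10–18 (= beads 1–9 of the next
    dimer).  Periodic images are *not* stored: expansion to a chain applies
    the Bn periodicity rule (offset 9·r for the r-th dimer).
    """

    def __init__(self, intra: ParameterSet, junction: ParameterSet):
        super().__init__(
            intra.bonds + junction.bonds,
            intra.angles + junction.angles,
            intra.impropers + junction.impropers,
            intra.dihedrals + junction.dihedrals,
        )
        self.intra = intra
        self.junction = junction


class _ForceField:
    """Lazy, validated singleton view over the packaged data file."""

    def __init__(self) -> None:
        raw = json.loads(
            resources.files("hamartini.data").joinpath(_DATA_FILE).read_text()
        )
        blob = json.dumps(
            raw["payload"], sort_keys=True, separators=(",", ":")
        ).encode()
        digest = hashlib.sha256(blob).hexdigest()
        if digest != raw["sha256"]:
            raise RuntimeError(
                f"parameter data file {_DATA_FILE} is corrupted: checksum mismatch"
            )
        self.version: str = raw["version"]
        self.payload: dict = raw["payload"]

    def beads(self) -> list[BeadDefinition]:
        return [
            BeadDefinition(idx, label, mtype, size, charge, group)
            for idx, label, mtype, size, charge, group in self.payload["beads"]
        ]


_FF: _ForceField | None = None


def _ff() -> _ForceField:
    global _FF
    if _FF is None:
        _FF = _ForceField()
    return _FF


def _parse_set(block: dict) -> ParameterSet:
    return ParameterSet(
        bonds=[BondTerm(*row) for row in block["bonds"]],
        angles=[AngleTerm(*row) for row in block["angles"]],
        impropers=[ImproperTerm(*row) for row in block["impropers"]],
        dihedrals=[DihedralTerm(*row) for row in block["dihedrals"]],
    )


def monomer_parameter_set(residue: str) -> ParameterSet:
    """Bonded parameters of a free monosaccharide (GlcNAc or GlcA).

    GlcNAc carries 6 bonds, 3 angles and 2 impropers; GlcA carries 4 bonds,
    2 angles and 1 improper.  Bead indices follow the dimer numbering
    (GlcNAc: 1–5, GlcA: 6–9).
    """
    residue = _normalize_residue(residue)
    return _parse_set(_ff().payload["monomers"][residue])


def chain_parameter_template() -> DimerTemplate:
    """The dimer parameter template used to expand HA chains of any length."""
    block = _ff().payload["dimer_template"]
    return DimerTemplate(_parse_set(block["intra"]), _parse_set(block["junction"]))


def bead_catalog(
    variant: Variant = "internal", residue: str | None = None
) -> list[BeadDefinition]:
    """Bead definitions for the HA dimer, or for one free monosaccharide.

    With ``variant="free_monomer"`` a ``residue`` must be given and only that
    residue's beads are returned (5 for GlcNAc, 4 for GlcA), with the
    anomeric bead grown to size S (it gains the anomeric hydroxyl).  With
    ``variant="reducing_end"`` all 9 dimer beads are returned with bead 7
    (GlcA anomeric) grown to S7; ``"internal"`` returns the plain 9 beads.
    """
    ff = _ff()
    beads = ff.beads()

    def grow(bead: BeadDefinition) -> BeadDefinition:
        # T -> S: the anomeric bead absorbs the free anomeric hydroxyl
        return replace(
            bead,
            size_class="S",
            label="S" + bead.label[1:],
            variant=variant,
        )

    if variant == "free_monomer":
        if residue is None:
            raise ValueError("free_monomer variant requires a residue id")
        residue = _normalize_residue(residue)
        keep = set(ff.payload["residue_beads"][residue])
        grown = ff.payload["reducing_end_grows"][residue]
        out = []
        for b in beads:
            if b.index_in_dimer not in keep:
                continue
            out.append(grow(b) if b.index_in_dimer == grown else replace(b, variant=variant))
        return out

    if variant == "reducing_end":
        grown = ff.payload["reducing_end_grows"]["GlcA"]
        return [
            grow(b) if b.index_in_dimer == grown else replace(b, variant=variant)
            for b in beads
        ]

    if variant == "internal":
        return beads

    raise ValueError(f"unknown variant {variant!r}")


def nonbonded_config() -> NonbondedConfig:
    return NonbondedConfig(**_ff().payload["nonbonded"])


def bead_mass(size_class: str) -> float:
    return _ff().payload["masses"][size_class]


def sasa_radius(size_class: str) -> float:
    """Per-size-class bead radius (nm) used for SASA calculations."""
    return _ff().payload["sasa_radii"][size_class]


def recommended_timestep(kind: Literal["chain", "monomer"]) -> float:
    """Integration time step (ps) at which the model is stable in MD."""
    return _ff().payload["recommended_timestep"][kind]


def residue_of_bead(index_in_dimer: int) -> str:
    """Residue owning a dimer bead index (1–5 GlcNAc, 6–9 GlcA)."""
    if 1 <= index_in_dimer <= 5:
        return "GlcNAc"
    if 6 <= index_in_dimer <= 9:
        return "GlcA"
    raise ValueError(f"bead index {index_in_dimer} outside the dimer range 1-9")


def data_version() -> str:
    return _ff().version
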