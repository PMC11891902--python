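"""Atomistic-to-coarse-grained mapping by center of geometry.

Each CG bead is placed at the unweighted mean position (COG) of its mapped
atom group: the heavy atoms of the chemical fragment plus hydrogens bonded
to carbon ("aliphatic" hydrogens).  Hydroxyl and amide hydrogens are not
part of any group and never move a bead.

Ownership of oxygens is residue-local: the glycosidic/hydroxyl oxygen O3 of
GlcNAc belongs to the ethanolamine bead R3 and O4 of GlcA to the oxyethyl
bead S9, so that every bead's heavy-atom count equals its size class
(T = 2, S = 3, R = 4) whether the oxygen is free or engaged in a linkage.
The anomeric bead (T2 of GlcNAc, T7 of GlcA) holds the ring oxygen and the
anomeric carbon, and additionally the anomeric hydroxyl O1 when the residue
terminates a chain at the reducing end or is a free sugar (growing T to S).

The default atom-naming dialect is the CHARMM36 carbohydrate force field
(the naming scheme of CHARMM-GUI-generated structures).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .params import UnknownResidueError

__all__ = [
    "AtomisticStructure",
    "MappingTable",
    "default_mapping_tables",
    "map_aa_to_cg",
]

# resname aliases accepted on input structures
_RESNAME_ALIASES = {
    "GLCNAC": "GlcNAc",
    "GLCNA": "GlcNAc",  # GRO 5-char truncation
    "GLCN": "GlcNAc",  # PDB 4-char truncation
    "BGLCNA": "GlcNAc",
    "AGLCNA": "GlcNAc",
    "NAG": "GlcNAc",
    "GLCA": "GlcA",
    "BGLCA": "GlcA",
    "AGLCA": "GlcA",
    "GCU": "GlcA",
    "BDP": "GlcA",
}

# CHARMM36 carbohydrate dialect.  "atoms": always part of the group;
# "optional": present only at a reducing end / free sugar (anomeric OH).
_CHARMM36 = {
    "GlcNAc": {
        1: {"atoms": ("C6", "O6", "H61", "H62"), "optional": ()},
        2: {"atoms": ("C1", "O5", "H1"), "optional": ("O1",)},
        3: {"atoms": ("C2", "N", "C3", "O3", "H2", "H3"), "optional": ()},
        4: {"atoms": ("C4", "C5", "O4", "H4", "H5"), "optional": ()},
        5: {"atoms": ("C", "O", "CT", "HT1", "HT2", "HT3"), "optional": ()},
    },
    "GlcA": {
        6: {"atoms": ("C6", "O61", "O62"), "optional": ()},
        7: {"atoms": ("C1", "O5", "H1"), "optional": ("O1",)},
        8: {"atoms": ("C2", "O2", "C3", "O3", "H2", "H3"), "optional": ()},
        9: {"atoms": ("C4", "O4", "C5", "H4", "H5"), "optional": ()},
    },
}

_DIALECTS = {"charmm36": _CHARMM36}


def _is_hydrogen(name: str) -> bool:
    return name.lstrip("0123456789").upper().startswith("H")


@dataclass
class AtomisticStructure:
    """A minimal atomistic structure: parallel arrays, positions in nm."""

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        self.names = np.asarray(self.names, dtype=object)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @classmethod
    def from_file(cls, path: str) -> "AtomisticStructure":
        """Load a PDB or GRO file (via MDAnalysis); positions converted to nm."""
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(path)
        return cls(
            names=u.atoms.names,
            resnames=u.atoms.resnames,
            resids=u.atoms.resids,
            positions=u.atoms.positions / 10.0,
        )

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "AtomisticStructure":
        pos = self.positions
        if rotation is not None:
            pos = pos @ np.asarray(rotation).T
        if translation is not None:
            pos = pos + np.asarray(translation)
        return AtomisticStructure(self.names, self.resnames, self.resids, pos)


@dataclass(frozen=True)
class MappingTable:
    """Per-residue, per-bead atom groups for one atomistic naming dialect."""

    naming_dialect: str
    groups: dict  # residue -> {bead_index -> {"atoms": (...), "optional": (...)}}

    def residue_groups(self, residue: str) -> dict:
        if residue not in self.groups:
            raise UnknownResidueError(residue)
        return self.groups[residue]

    def heavy_atoms(self, residue: str, include_optional: bool = True) -> set:
        out = set()
        for g in self.residue_groups(residue).values():
            names = g["atoms"] + (g["optional"] if include_optional else ())
            out |= {a for a in names if not _is_hydrogen(a)}
        return out


def default_mapping_tables(dialect: str = "charmm36") -> MappingTable:
    """The built-in mapping table for a supported atomistic naming dialect."""
    try:
        groups = _DIALECTS[dialect.lower()]
    except KeyError:
        raise ValueError(
            f"unknown naming dialect {dialect!r}; supported: "
            + ", ".join(sorted(_DIALECTS))
        ) from None
    return MappingTable(naming_dialect=dialect.lower(), groups=groups)


def _canonical_residue(resname: str) -> str:
    try:
        return _RESNAME_ALIASES[resname.upper()]
    except KeyError:
        raise UnknownResidueError(resname) from None


def map_aa_to_cg(
    structure: AtomisticStructure, table: MappingTable | None = None
) -> np.ndarray:
    """Map an atomistic HA structure to CG bead coordinates.

    Residues are processed in ``resid`` order; within each residue beads are
    emitted in their dimer-index order, matching the bead order of the
    corresponding topology.  Each bead position is the unweighted mean of
    the member atoms found.  A missing heavy atom (other than an optional
    anomeric O1) is an error; missing hydrogens produce a warning only.

    Returns an (n_beads, 3) array in nm.
    """
    if table is None:
        table = default_mapping_tables()

    positions: list[np.ndarray] = []
    for resid in sorted(set(structure.resids.tolist())):
        mask = structure.resids == resid
        resname = structure.resnames[mask][0]
        residue = _canonical_residue(str(resname))
        names = {str(n): i for i, n in zip(np.where(mask)[0], structure.names[mask])}
        for bead_index in sorted(table.residue_groups(residue)):
            group = table.residue_groups(residue)[bead_index]
            members = []
            for atom in group["atoms"]:
                if atom in names:
                    members.append(names[atom])
                elif _is_hydrogen(atom):
                    warnings.warn(
                        f"residue {residue} {resid}: hydrogen {atom} missing; "
                        "mapping without it",
                        stacklevel=2,
                    )
                else:
                    raise ValueError(
                        f"residue {residue} {resid}: heavy atom {atom} required "
                        f"by bead {bead_index} not found in structure"
                    )
            for atom in group["optional"]:
                if atom in names:
                    members.append(names[atom])
            positions.append(structure.positions[members].mean(axis=0))
    if not positions:
        raise ValueError("structure contains no mappable residues")
    return np.array(positions)
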