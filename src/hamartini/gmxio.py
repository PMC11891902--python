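"""GROMACS file I/O: ITP topologies, GRO/PDB coordinates, MDP templates.

The ITP dialect written here uses the interaction types of the model:
bonds funct 1, angles funct 2 (G96 cosine) or 10 (restricted bending),
impropers as dihedrals funct 2, propers as dihedrals funct 1, and
``nrexcl 1`` (first covalent neighbours excluded).  ``parse_itp`` reads the
same dialect back (tolerant of comments and blank lines) so that
write -> parse -> write is byte-identical.

Coordinate files are read through MDAnalysis (GRO/PDB/XTC/TRR) and written
through its writers; this package works in nm internally and converts at
the boundary (MDAnalysis uses Angstrom).
"""

from __future__ import annotations

import io
from typing import Iterable, TextIO

import numpy as np

from . import params as ffp
from .params import AngleTerm, BondTerm, DihedralTerm, ImproperTerm
from .topology import Bead, Topology

__all__ = [
    "write_itp",
    "parse_itp",
    "write_top",
    "write_gro",
    "write_pdb",
    "load_coordinates",
    "load_trajectory",
    "mdp_template",
]

_ANGLE_FUNCT = {"g96": 2, "restricted": 10}
_ANGLE_FORM = {v: k for k, v in _ANGLE_FUNCT.items()}


def _fmt(x: float) -> str:
    """Integers print bare; other values keep their shortest decimal form."""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def write_itp(topology: Topology, stream: TextIO | None = None) -> str:
    """Serialize a topology to GROMACS ITP text; returns the text."""
    out = io.StringIO()
    w = out.write
    w("; Martini 3 hyaluronic acid model - generated by hamartini\n")
    w("; bead pair (LJ) parameters are defined by the Martini 3 "
      "distribution files\n\n")
    w("[ moleculetype ]\n; name  nrexcl\n")
    w(f"{topology.molecule_name}  {topology.nrexcl}\n\n")

    w("[ atoms ]\n;  nr  type  resnr  residue  atom  cgnr  charge  mass\n")
    for b in topology.beads:
        w(
            f"{b.index:>5} {b.martini_type:>5} {b.residue_number:>6} "
            f"{b.residue_name:>8} {b.label:>5} {b.index:>5} "
            f"{_fmt(b.charge):>7} {_fmt(b.mass):>7}\n"
        )

    if topology.bonds:
        w("\n[ bonds ]\n;   i    j  funct      b0      k_b\n")
        for t in topology.bonds:
            w(f"{t.i:>5}{t.j:>5}{1:>7} {t.b0:>7.3f} {_fmt(t.k_b):>8}\n")

    if topology.angles:
        w("\n[ angles ]\n;   i    j    k  funct  theta0  k_theta\n")
        for t in topology.angles:
            w(
                f"{t.i:>5}{t.j:>5}{t.k:>5}{_ANGLE_FUNCT[t.form]:>7} "
                f"{_fmt(t.theta0):>7} {_fmt(t.k_theta):>8}\n"
            )

    if topology.impropers:
        w("\n[ dihedrals ]\n; improper dihedrals\n")
        w(";   i    j    k    l  funct     xi0     k_xi\n")
        for t in topology.impropers:
            w(
                f"{t.i:>5}{t.j:>5}{t.k:>5}{t.l:>5}{2:>7} "
                f"{_fmt(t.xi0):>7} {_fmt(t.k_xi):>8}\n"
            )

    if topology.dihedrals:
        w("\n[ dihedrals ]\n; proper dihedrals\n")
        w(";   i    j    k    l  funct    phi0    k_phi   m\n")
        for t in topology.dihedrals:
            w(
                f"{t.i:>5}{t.j:>5}{t.k:>5}{t.l:>5}{1:>7} "
                f"{_fmt(t.phi0):>7} {_fmt(t.k_phi):>8} {t.m:>3}\n"
            )

    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def _tokenize(text: str) -> Iterable[tuple[str, list[str]]]:
    """Yield (current_section, fields) for every data line."""
    section = None
    for raw in text.splitlines():
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            if not line.endswith("]"):
                raise ValueError(f"malformed section header: {raw!r}")
            section = line[1:-1].strip().lower()
            continue
        if section is None:
            raise ValueError(f"data line outside any section: {raw!r}")
        yield section, line.split()


def _num(s: str) -> float:
    v = float(s)
    return int(v) if v == int(v) else v


def parse_itp(text: str) -> Topology:
    """Parse ITP text in the dialect produced by :func:`write_itp`."""
    name = None
    nrexcl = None
    beads: list[Bead] = []
    bonds: list[BondTerm] = []
    angles: list[AngleTerm] = []
    impropers: list[ImproperTerm] = []
    dihedrals: list[DihedralTerm] = []

    for section, f in _tokenize(text):
        try:
            if section == "moleculetype":
                name, nrexcl = f[0], int(f[1])
            elif section == "atoms":
                beads.append(
                    Bead(
                        index=int(f[0]),
                        martini_type=f[1],
                        residue_number=int(f[2]),
                        residue_name=f[3],
                        label=f[4],
                        charge=int(float(f[6])),
                        mass=float(f[7]),
                        size_class=f[4][0],
                    )
                )
            elif section == "bonds":
                funct = int(f[2])
                if funct != 1:
                    raise ValueError(f"unsupported bond funct {funct}")
                bonds.append(BondTerm(int(f[0]), int(f[1]), _num(f[4]), float(f[3])))
            elif section == "angles":
                funct = int(f[3])
                if funct not in _ANGLE_FORM:
                    raise ValueError(f"unsupported angle funct {funct}")
                angles.append(
                    AngleTerm(
                        int(f[0]), int(f[1]), int(f[2]),
                        _num(f[5]), _num(f[4]), _ANGLE_FORM[funct],
                    )
                )
            elif section == "dihedrals":
                funct = int(f[4])
                ijkl = tuple(int(x) for x in f[:4])
                if funct == 2:
                    impropers.append(ImproperTerm(*ijkl, _num(f[6]), _num(f[5])))
                elif funct == 1:
                    dihedrals.append(
                        DihedralTerm(*ijkl, _num(f[6]), _num(f[5]), int(f[7]))
                    )
                else:
                    raise ValueError(f"unsupported dihedral funct {funct}")
            else:
                raise ValueError(f"unknown section [ {section} ]")
        except (IndexError, ValueError) as err:
            if isinstance(err, ValueError) and "unsupported" in str(err):
                raise
            if isinstance(err, ValueError) and "unknown section" in str(err):
                raise
            raise ValueError(f"malformed record in [ {section} ]: {f}") from err

    if name is None or not beads:
        raise ValueError("ITP lacks a [ moleculetype ] or [ atoms ] section")
    top = Topology(
        molecule_name=name,
        beads=beads,
        bonds=bonds,
        angles=angles,
        impropers=impropers,
        dihedrals=dihedrals,
        nrexcl=nrexcl,
    )
    top.validate()
    return top


def write_top(topology: Topology, itp_filename: str, n_molecules: int = 1) -> str:
    """Minimal GROMACS .top wrapper referencing the Martini 3 master files."""
    return (
        '#include "martini_v3.0.0.itp"\n'
        '#include "martini_v3.0.0_solvents_v1.itp"\n'
        '#include "martini_v3.0.0_ions_v1.itp"\n'
        f'#include "{itp_filename}"\n\n'
        "[ system ]\n"
        f"{topology.molecule_name} in water\n\n"
        "[ molecules ]\n"
        f"{topology.molecule_name}  {n_molecules}\n"
    )


def _universe(topology: Topology, coords_nm: np.ndarray):
    import MDAnalysis as mda

    coords = np.asarray(coords_nm, float)
    resids = [b.residue_number for b in topology.beads]
    unique_res = sorted(set(resids))
    res_index = [unique_res.index(r) for r in resids]
    u = mda.Universe.empty(
        n_atoms=topology.n_beads,
        n_residues=len(unique_res),
        atom_resindex=res_index,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [b.label for b in topology.beads])
    u.add_TopologyAttr(
        "resnames",
        [
            next(b.residue_name for b in topology.beads if b.residue_number == r)
            for r in unique_res
        ],
    )
    u.add_TopologyAttr("resids", unique_res)
    u.atoms.positions = coords * 10.0  # nm -> Angstrom
    span = coords.max(axis=0) - coords.min(axis=0) + 4.0
    u.dimensions = [span[0] * 10, span[1] * 10, span[2] * 10, 90, 90, 90]
    return u


def write_gro(topology: Topology, coords_nm: np.ndarray, path: str) -> None:
    """Write bead coordinates (nm) as a GRO file."""
    _universe(topology, coords_nm).atoms.write(path)


def write_pdb(topology: Topology, coords_nm: np.ndarray, path: str) -> None:
    """Write bead coordinates as PDB (Angstrom, converted from nm)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _universe(topology, coords_nm).atoms.write(path)


def load_coordinates(path: str) -> np.ndarray:
    """Read a single-frame coordinate file (GRO/PDB); returns (n, 3) in nm."""
    import MDAnalysis as mda

    u = mda.Universe(path)
    return u.atoms.positions / 10.0


def load_trajectory(structure: str, trajectory: str | None = None) -> np.ndarray:
    """Read a trajectory (XTC/TRR/multiframe) as (n_frames, n, 3) in nm."""
    import MDAnalysis as mda

    u = mda.Universe(structure) if trajectory is None else mda.Universe(
        structure, trajectory
    )
    return np.array([u.atoms.positions / 10.0 for _ in u.trajectory])


def mdp_template(topology: Topology, nsteps: int = 500000) -> str:
    """MD parameter template matching the model's validated run settings.

    Reaction-field electrostatics (cutoff 1.1 nm, eps_r 15), 1.1 nm LJ
    cutoff, V-rescale thermostat at 298 K, Parrinello-Rahman barostat at
    1 bar, and the time step the model is stable at (0.01 ps for chains,
    0.03 ps for free monosaccharides).  A convenience template, not a
    validated production protocol.
    """
    nb = ffp.nonbonded_config()
    dt = topology.recommended_timestep
    return "\n".join(
        [
            "integrator               = md",
            f"dt                       = {dt}",
            f"nsteps                   = {nsteps}",
            "nstxout-compressed       = 1000",
            "cutoff-scheme            = Verlet",
            f"rvdw                     = {nb.cutoff}",
            "coulombtype              = reaction-field",
            f"rcoulomb                 = {nb.cutoff}",
            f"epsilon-r                = {nb.eps_r}",
            "vdw-modifier             = Potential-shift-verlet",
            "tcoupl                   = v-rescale",
            "tc-grps                  = System",
            "tau-t                    = 1.0",
            "ref-t                    = 298",
            "pcoupl                   = parrinello-rahman",
            "pcoupltype               = isotropic",
            "tau-p                    = 40.0",
            "ref-p                    = 1.0",
            "compressibility          = 3e-4",
            "",
        ]
    )
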