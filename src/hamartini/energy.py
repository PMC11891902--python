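"""Internal-coordinate measurement and bonded-energy evaluation.

Implements the five bonded interaction forms of the model in their GROMACS
dialects:

* bond stretching, funct 1:      V = 1/2 k_b (b - b0)^2
* angle bending, funct 2 (G96):  V = 1/2 k_th (cos th - cos th0)^2
* restricted bending, funct 10:  V = 1/2 k_th (cos th - cos th0)^2 / sin^2 th
* improper dihedral, funct 2:    V = 1/2 k_xi (xi - xi0)^2, deviation in rad
* proper dihedral, funct 1:      V = k_phi (1 + cos(m phi - phi0))

Angles are reported in degrees, distances in nm, energies in kJ/mol.
Dihedrals and impropers follow the IUPAC sign convention and are wrapped to
[-180, 180).  The improper force constant is stored as printed in the
parameter tables but the deviation is converted to radians before squaring
(GROMACS dihedral-type-2 semantics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .params import AngleTerm, BondTerm, DihedralTerm, ImproperTerm

__all__ = [
    "GeometryMeasurement",
    "EnergyBreakdown",
    "bond_length",
    "bond_angle",
    "dihedral_angle",
    "measure",
    "term_energy",
    "total_bonded_energy",
]

_DEGENERATE_NORM = 1e-9  # nm; shorter vectors are geometrically meaningless
_SIN_GUARD = 1e-6  # sin(theta) below this triggers the divergence guard
DEFAULT_RESTRICTED_CAP = 1e6  # kJ/mol cap for the restricted-bending divergence


class DegenerateGeometryError(ValueError):
    pass


@dataclass(frozen=True)
class GeometryMeasurement:
    kind: str  # bond | angle | improper | dihedral
    indices: tuple[int, ...]
    value: float  # nm for bonds, degrees otherwise
    frame: int = 0


@dataclass
class EnergyBreakdown:
    """Per-term bonded energies plus per-class and grand totals (kJ/mol)."""

    per_term: dict[str, list[float]] = field(default_factory=dict)

    @property
    def class_totals(self) -> dict[str, float]:
        return {k: float(sum(v)) for k, v in self.per_term.items()}

    @property
    def total(self) -> float:
        return float(sum(self.class_totals.values()))


def _vec(coords: np.ndarray, a: int, b: int) -> np.ndarray:
    return np.asarray(coords[b], float) - np.asarray(coords[a], float)


def _checked_norm(v: np.ndarray) -> float:
    n = float(np.linalg.norm(v))
    if n < _DEGENERATE_NORM:
        raise DegenerateGeometryError(
            f"degenerate geometry: vector norm {n:g} nm below {_DEGENERATE_NORM:g}"
        )
    return n


def bond_length(coords: np.ndarray, i: int, j: int) -> float:
    """Distance (nm) between beads ``i`` and ``j`` (0-based indices)."""
    return float(np.linalg.norm(_vec(coords, i, j)))


def bond_angle(coords: np.ndarray, i: int, j: int, k: int) -> float:
    """Angle (degrees) at vertex ``j`` of the triplet ``i-j-k``."""
    u = _vec(coords, j, i)
    v = _vec(coords, j, k)
    nu, nv = _checked_norm(u), _checked_norm(v)
    c = float(np.dot(u, v) / (nu * nv))
    cross = float(np.linalg.norm(np.cross(u, v)) / (nu * nv))
    if cross == 0.0 and c > 0:
        raise DegenerateGeometryError("exactly parallel vectors: angle undefined")
    if cross < _SIN_GUARD:
        warnings.warn("near-collinear triplet in angle measurement", stacklevel=2)
    return float(np.degrees(np.arctan2(cross, c)))


def _wrap_deg(x: float) -> float:
    """Wrap an angle in degrees to [-180, 180)."""
    return float((x + 180.0) % 360.0 - 180.0)


def dihedral_angle(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Signed dihedral (degrees, IUPAC convention) of the quadruplet i-j-k-l.

    Wrapped to [-180, 180); a trans-planar quadruplet reports -180.
    """
    b1 = _vec(coords, i, j)
    b2 = _vec(coords, j, k)
    b3 = _vec(coords, k, l)
    _checked_norm(b1), _checked_norm(b2), _checked_norm(b3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return _wrap_deg(np.degrees(np.arctan2(y, x)))


def measure(coords: np.ndarray, term_or_indices, frame: int = 0) -> GeometryMeasurement:
    """Measure the internal coordinate of a term or a raw index tuple.

    Accepts a parameter/topology term (Bond/Angle/Improper/Dihedral) with
    1-based indices, or a plain tuple of 0-based indices whose length
    selects the kind (2: bond, 3: angle, 4: dihedral).
    """
    if isinstance(term_or_indices, BondTerm):
        idx, kind = term_or_indices.indices, "bond"
    elif isinstance(term_or_indices, AngleTerm):
        idx, kind = term_or_indices.indices, "angle"
    elif isinstance(term_or_indices, ImproperTerm):
        idx, kind = term_or_indices.indices, "improper"
    elif isinstance(term_or_indices, DihedralTerm):
        idx, kind = term_or_indices.indices, "dihedral"
    else:
        raw = tuple(term_or_indices)
        kind = {2: "bond", 3: "angle", 4: "dihedral"}[len(raw)]
        value = _measure_raw(coords, raw, kind)
        return GeometryMeasurement(kind, raw, value, frame)
    zero_based = tuple(x - 1 for x in idx)
    value = _measure_raw(coords, zero_based, "dihedral" if kind == "improper" else kind)
    return GeometryMeasurement(kind, idx, value, frame)


def _measure_raw(coords: np.ndarray, idx: tuple[int, ...], kind: str) -> float:
    if kind == "bond":
        return bond_length(coords, *idx)
    if kind == "angle":
        return bond_angle(coords, *idx)
    return dihedral_angle(coords, *idx)


def term_energy(
    term,
    coords: np.ndarray,
    restricted_cap: float = DEFAULT_RESTRICTED_CAP,
) -> float:
    """Energy (kJ/mol) of a single bonded term at the given coordinates.

    Term indices are 1-based (topology convention); ``coords`` is an
    (n_beads, 3) array in nm.
    """
    idx = tuple(x - 1 for x in term.indices)
    if isinstance(term, BondTerm):
        b = bond_length(coords, *idx)
        return 0.5 * term.k_b * (b - term.b0) ** 2
    if isinstance(term, AngleTerm):
        theta = np.radians(bond_angle(coords, *idx))
        dcos = np.cos(theta) - np.cos(np.radians(term.theta0))
        e = 0.5 * term.k_theta * dcos**2
        if term.form == "restricted":
            s2 = np.sin(theta) ** 2
            if s2 < _SIN_GUARD**2:
                warnings.warn(
                    "restricted-bending angle at linearity: energy capped",
                    stacklevel=2,
                )
                return float(restricted_cap)
            e = min(e / s2, restricted_cap)
        return float(e)
    if isinstance(term, ImproperTerm):
        xi = dihedral_angle(coords, *idx)
        dxi = np.radians(_wrap_deg(xi - term.xi0))
        return float(0.5 * term.k_xi * dxi**2)
    if isinstance(term, DihedralTerm):
        phi = dihedral_angle(coords, *idx)
        return float(
            term.k_phi * (1.0 + np.cos(np.radians(term.m * phi - term.phi0)))
        )
    raise TypeError(f"unsupported term type {type(term).__name__}")


def total_bonded_energy(
    topology,
    coords: np.ndarray,
    restricted_cap: float = DEFAULT_RESTRICTED_CAP,
) -> EnergyBreakdown:
    """Evaluate all bonded terms of a topology at one configuration."""
    coords = np.asarray(coords, float)
    if coords.shape != (len(topology.beads), 3):
        raise ValueError(
            f"coordinate shape {coords.shape} does not match bead count "
            f"{len(topology.beads)}"
        )
    out = EnergyBreakdown()
    for name, terms in (
        ("bonds", topology.bonds),
        ("angles", topology.angles),
        ("impropers", topology.impropers),
        ("dihedrals", topology.dihedrals),
    ):
        out.per_term[name] = [term_energy(t, coords, restricted_cap) for t in terms]
    return out
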