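"""Synthetic inputs for testing: WLC ensembles, perturbed geometries, toy
atomistic fragments.

The worm-like-chain sampler realizes the target correlation structure of
the Kratky-Porod model with a freely rotating chain: every consecutive pair
of bond vectors encloses the fixed angle theta with cos(theta) =
exp(-d/l_p) and an independent uniform azimuth, so that exactly

    E[u_i . u_{i+n}] = exp(-n d / l_p).

This gives a closed-form expectation for the bond-vector autocorrelation
C(n) against which the persistence-length estimator can be validated.  All
generators are pure functions of their arguments including the seed
(NumPy PCG64).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mapper import AtomisticStructure, default_mapping_tables, _is_hydrogen
from .params import _normalize_residue
from .topology import Topology, build_initial_coordinates, build_monomer_topology

__all__ = [
    "WLCSpec",
    "WLCSample",
    "sample_wlc",
    "perturbed_geometry",
    "toy_aa_fragment",
]


@dataclass(frozen=True)
class WLCSpec:
    """Specification of a worm-like-chain ensemble."""

    n_bonds: int
    d: float  # bond length, nm
    l_p: float  # persistence length, nm (may be float("inf"))
    n_frames: int
    seed: int

    def __post_init__(self):
        if self.n_bonds < 1 or self.n_frames < 1 or self.d <= 0 or self.l_p <= 0:
            raise ValueError("all WLC spec fields must be positive")


@dataclass
class WLCSample:
    """Sampled ensemble: unit bond vectors per frame, plus its provenance."""

    spec: WLCSpec
    vectors: np.ndarray  # (n_frames, n_bonds, 3), each of length d
    metadata: dict = field(default_factory=dict)

    @property
    def positions(self) -> np.ndarray:
        """Bead positions (n_frames, n_bonds + 1, 3) implied by the vectors."""
        return np.concatenate(
            [np.zeros((len(self.vectors), 1, 3)), np.cumsum(self.vectors, axis=1)],
            axis=1,
        )


def sample_wlc(spec: WLCSpec) -> WLCSample:
    """Draw a WLC bond-vector ensemble with exact per-step <cos theta>."""
    rng = np.random.default_rng(spec.seed)
    F, B = spec.n_frames, spec.n_bonds
    cos_t = np.exp(-spec.d / spec.l_p) if np.isfinite(spec.l_p) else 1.0
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t**2))

    u = np.zeros((F, B, 3))
    # random initial direction per frame (isotropic)
    v = rng.normal(size=(F, 3))
    u[:, 0] = v / np.linalg.norm(v, axis=1, keepdims=True)
    for b in range(1, B):
        prev = u[:, b - 1]
        # orthonormal frame perpendicular to prev
        helper = np.where(
            np.abs(prev[:, [0]]) < 0.9, [[1.0, 0, 0]], [[0, 1.0, 0]]
        )
        e1 = np.cross(prev, helper)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(prev, e1)
        phi = rng.uniform(0, 2 * np.pi, size=(F, 1))
        u[:, b] = cos_t * prev + sin_t * (np.cos(phi) * e1 + np.sin(phi) * e2)
    return WLCSample(
        spec=spec,
        vectors=spec.d * u,
        metadata={"seed": spec.seed, "cos_theta": cos_t, "generator": "PCG64"},
    )


def perturbed_geometry(
    coords: np.ndarray, sigma: float, seed: int
) -> np.ndarray:
    """Gaussian-displace every bead coordinate (sd ``sigma`` nm per axis)."""
    coords = np.asarray(coords, float)
    if sigma == 0:
        return coords.copy()
    rng = np.random.default_rng(seed)
    return coords + rng.normal(0.0, sigma, size=coords.shape)


def toy_aa_fragment(residue: str, seed: int = 0) -> AtomisticStructure:
    """A synthetic atomistic monosaccharide fragment for mapper tests.

    Not a chemically meaningful conformation: atoms carry the CHARMM36
    dialect names and are placed around the canonical CG bead positions so
    that each mapped group's center of geometry lies exactly on its bead.
    Non-aliphatic hydrogens (HO*, HN) are added off-group so that their
    presence or absence cannot move any bead.
    """
    residue = _normalize_residue(residue)
    table = default_mapping_tables()
    top = build_monomer_topology(residue)
    centers = build_initial_coordinates(top)
    groups = table.residue_groups(residue)

    rng = np.random.default_rng(seed)
    names: list[str] = []
    positions: list[np.ndarray] = []
    for row, bead_index in enumerate(sorted(groups)):
        g = groups[bead_index]
        members = list(g["atoms"]) + list(g["optional"])
        offsets = rng.normal(0.0, 0.05, size=(len(members), 3))
        offsets -= offsets.mean(axis=0)  # COG lands exactly on the bead
        for atom, off in zip(members, offsets):
            names.append(atom)
            positions.append(centers[row] + off)
            if atom in ("O1", "O2", "O3", "O4", "O6"):
                # decorate hydroxyls with their (unmapped) hydrogen
                names.append("H" + atom)
                positions.append(centers[row] + off + [0.03, 0.0, 0.0])
    if residue == "GlcNAc":
        names.append("HN")
        positions.append(centers[2] + [0.0, 0.08, 0.0])
    return AtomisticStructure(
        names=np.array(names, dtype=object),
        resnames=np.array([residue.upper()] * len(names), dtype=object),
        resids=np.ones(len(names), dtype=int),
        positions=np.array(positions),
    )
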