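"""Chain-scale observables: persistence length, Rg/end-to-end, SASA,
aggregation clusters.

Persistence length follows the bond-vector autocorrelation route: backbone
bond vectors are defined between consecutive R3/S9 beads (dimer indices
3 + 9r and 9 + 9s), the autocorrelation

    C(n) = < u_i . u_{i+n} >            (unit vectors; frames and pairs)

is averaged over the trajectory, and l_p is obtained from a least-squares
fit of C(n) = exp(-n d / l_p), where d is the mean backbone bond length
over all selected vectors and frames.  Unit-vector normalization of C(n)
is a documented convention and recorded in the fit metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from . import params as ffp
from .topology import Topology

__all__ = [
    "PersistenceFit",
    "backbone_indices",
    "backbone_vectors",
    "autocorrelation",
    "fit_persistence_length",
    "persistence_length",
    "gyration_and_e2e",
    "sasa",
    "cluster_aggregates",
]

NOISE_FLOOR = 0.05  # C(n) below this is considered noise and excluded from fits
_NONDECAY = 0.95  # series staying above this over the fit range cannot be fit


def backbone_indices(topology: Topology) -> list[int]:
    """1-based indices of the backbone beads: R3 and S9 of every dimer."""
    idx = [b.index for b in topology.beads if b.label in ("R3", "S9")]
    if not idx or topology.n_beads % 9 != 0:
        raise ValueError("topology is not an HA chain with the R3/S9 pattern")
    return sorted(idx)


def backbone_vectors(coords: np.ndarray, topology: Topology) -> np.ndarray:
    """Backbone bond vectors of one frame: differences of consecutive
    selected beads (2 per dimer, hence 2*n_dimers - 1 vectors)."""
    sel = np.array(backbone_indices(topology)) - 1
    pts = np.asarray(coords, float)[sel]
    return np.diff(pts, axis=0)


def autocorrelation(vectors: np.ndarray) -> np.ndarray:
    """Bond-vector autocorrelation C(n), n = 0..n_bonds-1.

    ``vectors``: (n_frames, n_bonds, 3) or (n_bonds, 3).  Vectors are
    normalized to unit length; C(n) averages u_i . u_{i+n} over all frames
    and all valid pairs.  C(0) is exactly 1.
    """
    v = np.asarray(vectors, float)
    if v.ndim == 2:
        v = v[None]
    if v.shape[0] == 0 or v.shape[1] < 2:
        raise ValueError("need at least one frame with at least 2 vectors")
    u = v / np.linalg.norm(v, axis=2, keepdims=True)
    B = u.shape[1]
    C = np.empty(B)
    C[0] = 1.0
    for n in range(1, B):
        C[n] = float(np.mean(np.sum(u[:, :-n] * u[:, n:], axis=2)))
    return C


@dataclass
class PersistenceFit:
    """Result of the exponential fit C(n) = exp(-n d / l_p)."""

    C: np.ndarray
    d: float  # mean backbone bond length, nm
    l_p: float | None  # nm; None if the series does not decay
    fit_range: tuple[int, int]
    fit_residual: float
    status: str  # "ok" | "exceeds_resolvable_range"
    metadata: dict = field(default_factory=dict)


def fit_persistence_length(
    C: np.ndarray,
    d: float,
    fit_range: tuple[int, int] | None = None,
    log_space: bool = False,
) -> PersistenceFit:
    """Fit l_p from a C(n) series and the mean bond length d (nm).

    Default fit range: n in [1, n_max] with n_max the largest n where
    C(n) > 0.05 (noise floor), capped at half the series length.  A series
    that does not decay over the range (all points above 0.95) is reported
    with status ``exceeds_resolvable_range`` and ``l_p = None`` instead of
    a number.
    """
    C = np.asarray(C, float)
    if fit_range is None:
        above = np.nonzero(C > NOISE_FLOOR)[0]
        n_max = min(int(above.max()) if len(above) else 1, max(len(C) // 2, 2))
        fit_range = (1, max(n_max, 1))
    lo, hi = fit_range
    n = np.arange(lo, hi + 1)
    n = n[n < len(C)]
    y = C[n]
    meta = {"normalization": "unit_vectors", "log_space": log_space}

    if len(n) < 3 or np.all(y > _NONDECAY):
        return PersistenceFit(
            C, d, None, (int(n[0]), int(n[-1])) if len(n) else fit_range,
            float("nan"), "exceeds_resolvable_range", meta,
        )

    if log_space:
        pos = y > 0
        slope = np.polyfit(n[pos], np.log(y[pos]), 1)[0]
        l_p = -d / slope
        yhat = np.exp(slope * n)
    else:
        slope_guess = (np.log(max(y[-1], 1e-6)) - np.log(y[0])) / (n[-1] - n[0])
        p0 = max(-d / slope_guess, 1e-3 * d) if slope_guess < 0 else 10 * d
        (l_p,), _ = curve_fit(
            lambda x, lp: np.exp(-x * d / lp), n, y, p0=[p0], maxfev=10000
        )
        yhat = np.exp(-n * d / l_p)
    resid = float(np.sqrt(np.mean((y - yhat) ** 2)))
    if l_p <= 0:
        return PersistenceFit(
            C, d, None, (int(n[0]), int(n[-1])), resid,
            "exceeds_resolvable_range", meta,
        )
    return PersistenceFit(
        C, d, float(l_p), (int(n[0]), int(n[-1])), resid, "ok", meta
    )


def persistence_length(
    trajectory: np.ndarray,
    topology: Topology | None = None,
    fit_range: tuple[int, int] | None = None,
    log_space: bool = False,
) -> PersistenceFit:
    """Full pipeline from a coordinate trajectory (or bond-vector ensemble).

    ``trajectory`` is (n_frames, n_beads, 3) with a chain ``topology`` (the
    R3/S9 backbone selection is applied per frame), or a raw bond-vector
    ensemble (n_frames, n_bonds, 3) when ``topology`` is None.
    """
    traj = np.asarray(trajectory, float)
    if traj.ndim == 2:
        traj = traj[None]
    if topology is not None:
        vectors = np.stack([backbone_vectors(f, topology) for f in traj])
    else:
        vectors = traj
    C = autocorrelation(vectors)
    d = float(np.mean(np.linalg.norm(vectors, axis=2)))
    return fit_persistence_length(C, d, fit_range=fit_range, log_space=log_space)


@dataclass
class ChainShape:
    rg: np.ndarray  # per frame, nm
    e2e: np.ndarray  # per frame, nm

    @property
    def summary(self) -> dict:
        return {
            "rg_mean": float(self.rg.mean()),
            "rg_sd": float(self.rg.std(ddof=1)) if len(self.rg) > 1 else 0.0,
            "e2e_mean": float(self.e2e.mean()),
            "e2e_sd": float(self.e2e.std(ddof=1)) if len(self.e2e) > 1 else 0.0,
        }


def gyration_and_e2e(trajectory: np.ndarray) -> ChainShape:
    """Per-frame radius of gyration (equal bead weights) and first-to-last
    bead distance, in nm."""
    traj = np.asarray(trajectory, float)
    if traj.ndim == 2:
        traj = traj[None]
    centered = traj - traj.mean(axis=1, keepdims=True)
    rg = np.sqrt(np.mean(np.sum(centered**2, axis=2), axis=1))
    e2e = np.linalg.norm(traj[:, -1] - traj[:, 0], axis=1)
    return ChainShape(rg=rg, e2e=e2e)


def sasa(
    coords: np.ndarray,
    topology: Topology,
    probe_radius: float = 0.14,
    point_number: int = 1000,
) -> float:
    """Solvent-accessible surface area (nm^2) of one configuration.

    Shrake-Rupley point sampling (via biotite) with the model's per-size
    bead radii: 0.191 nm (T), 0.230 nm (S), 0.264 nm (R).  ``probe_radius``
    in nm; ``point_number`` controls the surface-point resolution.
    """
    import biotite.structure as struc

    coords = np.asarray(coords, float)
    n = len(coords)
    if n != topology.n_beads:
        raise ValueError("coordinate/bead count mismatch")
    radii_nm = np.array([ffp.sasa_radius(b.size_class) for b in topology.beads])
    arr = struc.AtomArray(n)
    arr.coord = coords * 10.0  # nm -> Angstrom
    arr.set_annotation("element", np.array(["C"] * n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        areas = struc.sasa(
            arr,
            probe_radius=probe_radius * 10.0,
            vdw_radii=radii_nm * 10.0,
            point_number=point_number,
        )
    return float(np.nansum(areas)) / 100.0  # Angstrom^2 -> nm^2


def cluster_aggregates(
    coords: np.ndarray,
    molecule_ids: np.ndarray,
    cutoff: float = 0.6,
) -> list[int]:
    """Single-linkage clustering of molecules by inter-bead contact.

    Two molecules are linked when any bead-bead distance is below
    ``cutoff`` (nm); cluster sizes are returned sorted descending.  The
    default cutoff, 0.6 nm, is a contact-distance convention for R beads.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = np.asarray(coords, float)
    mol = np.asarray(molecule_ids)
    unique, inverse = np.unique(mol, return_inverse=True)
    m = len(unique)
    pairs = cKDTree(coords).query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        mi, mj = inverse[pairs[:, 0]], inverse[pairs[:, 1]]
        mask = mi != mj
        adj = coo_matrix(
            (np.ones(mask.sum()), (mi[mask], mj[mask])), shape=(m, m)
        )
    else:
        adj = coo_matrix((m, m))
    _, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels)
    return sorted((int(s) for s in sizes), reverse=True)
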