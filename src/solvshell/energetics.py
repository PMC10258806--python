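"""Solute–solvent energetics and conformational flexibility.

Potential of mean force w(r) = −RT ln g(r) from a pair distribution, a
Shrake–Rupley solvent-accessible surface area with hydrophobic/hydrophilic
decomposition, per-atom root-mean-square fluctuations after rigid-body
alignment, and dihedral/improper torsional distributions of the macrocycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import GAS_CONSTANT
from .structure import RadialDistribution, ShellPartition
from .trajectory_io import SOLUTE_ROLES, Topology, Trajectory


@dataclass
class PMFProfile:
    """w(r) in kJ/mol on the RDF grid; bins with g = 0 are masked (NaN)."""

    r: np.ndarray
    w: np.ndarray           # NaN where undefined
    temperature: float
    gas_constant: float = GAS_CONSTANT

    def well(self, r_lo, r_hi):
        """(position, depth) of the minimum of w within [r_lo, r_hi)."""
        mask = (self.r >= r_lo) & (self.r < r_hi) & ~np.isnan(self.w)
        if not mask.any():
            return None
        i = np.argmin(np.where(mask, self.w, np.inf))
        return float(self.r[i]), float(self.w[i])

    def wells(self, partition: ShellPartition):
        lows = [0.0] + list(partition.boundaries[:-1])
        highs = list(partition.boundaries)
        return [self.well(lo, hi) for lo, hi in zip(lows, highs)]


@dataclass
class SASAResult:
    """Per-atom and decomposed solvent-accessible surface areas in nm²."""

    per_atom: np.ndarray     # nm², 0 for atoms outside the solute selection
    hydrophobic: float
    hydrophilic: float
    total: float
    probe_radius: float      # Å
    n_sphere_points: int


@dataclass
class RMSFProfile:
    atom_ids: np.ndarray
    rmsf: np.ndarray         # Å
    selection: dict


@dataclass
class TorsionDistribution:
    """Per-quadruple torsion histograms over (−180°, 180°] plus their average.

    ``per_quadruple`` has shape (n_quadruples, n_bins); ``average`` is the mean
    over quadruples, and ``running_average`` a circular moving-average smoothing
    of it.
    """

    bin_edges: np.ndarray
    per_quadruple: np.ndarray
    average: np.ndarray
    running_average: np.ndarray
    quadruples: list

    @property
    def angles(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


# ---------------------------------------------------------------------------
# PMF
# ---------------------------------------------------------------------------

def pmf_from_rdf(rdf: RadialDistribution, T=298.15) -> PMFProfile:
    """Potential of mean force w(r) = −R·T·ln g(r), in kJ/mol.

    Wherever g = 0 the free energy is undefined (infinitely repulsive at this
    sampling) and the profile is masked rather than set to −∞/+∞.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    g = np.asarray(rdf.g, dtype=float)
    w = np.full_like(g, np.nan)
    pos = g > 0
    w[pos] = -GAS_CONSTANT * T * np.log(g[pos]) / 1000.0
    return PMFProfile(r=rdf.r.copy(), w=w, temperature=float(T))


def rdf_from_pmf(pmf: PMFProfile) -> np.ndarray:
    """Inverse map g = exp(−w/RT) (round-trip check; NaN stays NaN)."""
    return np.exp(-1000.0 * pmf.w / (pmf.gas_constant * pmf.temperature))


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley)
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def compute_sasa(frame_coords, topology: Topology, probe_radius=1.4,
                 n_points=960, solute_roles=SOLUTE_ROLES) -> SASAResult:
    """Shrake–Rupley surface area of the solute, decomposed by polarity.

    Each solute atom's sphere of radius r_vdw + probe is sampled with
    ``n_points`` quasi-uniform points; the accessible fraction (points outside
    every neighbour's inflated sphere) times the sphere area gives the per-atom
    SASA. Solvent atoms are excluded from the solute surface. Areas in nm².
    """
    coords = np.asarray(frame_coords, dtype=float)
    sel = topology.indices_with_role(solute_roles)
    if sel.size == 0:
        raise ValueError("empty solute selection")
    if topology.vdw_radius is None:
        raise ValueError("topology has no van der Waals radii")
    radii = np.asarray(topology.vdw_radius, dtype=float)[sel]
    missing = np.where(np.isnan(radii))[0]
    if missing.size:
        i = sel[missing[0]]
        raise ValueError(
            f"missing vdW radius for atom {i} ({topology.names[i]}/"
            f"{topology.elements[i]})"
        )
    pos = coords[sel]
    inflated = radii + probe_radius
    sphere = _fibonacci_sphere(n_points)
    per_atom = np.zeros(topology.n_atoms)
    for a in range(sel.size):
        pts = pos[a] + inflated[a] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for b in range(sel.size):
            if b == a:
                continue
            dab = np.linalg.norm(pos[b] - pos[a])
            if dab >= inflated[a] + inflated[b]:
                continue
            d2 = np.sum((pts - pos[b]) ** 2, axis=1)
            r2 = inflated[b] ** 2
            # A point exactly on a neighbour's surface (degenerate contact,
            # e.g. coincident identical spheres) is kept by the lower-index
            # atom only, so shared surface is counted once.
            eps = 1e-9 * r2
            buried = d2 < r2 - eps
            if b < a:
                buried |= np.abs(d2 - r2) <= eps
            accessible &= ~buried
        area_A2 = 4.0 * math.pi * inflated[a] ** 2 * accessible.mean()
        per_atom[sel[a]] = area_A2 / 100.0                      # Å² → nm²
    polarity = topology.polarity or ["hydrophobic"] * topology.n_atoms
    phob = float(sum(per_atom[i] for i in sel if polarity[i] == "hydrophobic"))
    phil = float(sum(per_atom[i] for i in sel if polarity[i] == "hydrophilic"))
    return SASAResult(per_atom=per_atom, hydrophobic=phob, hydrophilic=phil,
                      total=phob + phil, probe_radius=probe_radius,
                      n_sphere_points=n_points)


def time_averaged_sasa(traj: Trajectory, topology: Topology, stride=1,
                       probe_radius=1.4, n_points=960,
                       solute_roles=SOLUTE_ROLES) -> SASAResult:
    """Mean of per-frame Shrake–Rupley areas over strided frames."""
    frames = range(0, traj.n_frames, max(1, int(stride)))
    acc = None
    n = 0
    for f in frames:
        res = compute_sasa(traj.coordinates[f], topology, probe_radius,
                           n_points, solute_roles)
        if acc is None:
            acc = res
            acc.per_atom = acc.per_atom.copy()
        else:
            acc.per_atom += res.per_atom
            acc.hydrophobic += res.hydrophobic
            acc.hydrophilic += res.hydrophilic
            acc.total += res.total
        n += 1
    acc.per_atom /= n
    acc.hydrophobic /= n
    acc.hydrophilic /= n
    acc.total /= n
    return acc


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

def compute_rmsf(aligned_traj: Trajectory, topology: Topology,
                 selection_roles=("ring_N", "ring_C_alpha", "ring_C_beta",
                                  "ring_C_meso")) -> RMSFProfile:
    """Per-atom RMSF about the time-mean position, after alignment.

    The default selection is the heavy ring atoms with the metal excluded;
    pass explicit roles to change it. Input must already be superposed
    (``kabsch_align``), otherwise rigid-body motion inflates the fluctuations.
    """
    sel = topology.indices_with_role(selection_roles)
    if sel.size == 0:
        raise ValueError("empty RMSF selection")
    x = aligned_traj.coordinates[:, sel, :]
    mean = x.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=-1), axis=0))
    return RMSFProfile(atom_ids=sel, rmsf=rmsf,
                       selection={"roles": list(selection_roles)})


# ---------------------------------------------------------------------------
# Torsions
# ---------------------------------------------------------------------------

def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral of the p2–p3 axis in degrees, in (−180, 180].

    IUPAC sign convention via the atan2 formulation: looking from p2 to p3, a
    clockwise rotation from p1 to p4 is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0, axis, b2 = p1 - p2, p3 - p2, p4 - p3
    if min(np.linalg.norm(b0), np.linalg.norm(axis), np.linalg.norm(b2)) < 1e-10:
        raise ValueError("coincident consecutive points; dihedral undefined")
    b1 = axis / np.linalg.norm(axis)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise ValueError("collinear triple; dihedral undefined")
    ang = math.degrees(math.atan2(np.cross(b1, v) @ w, v @ w))
    return 180.0 if ang == -180.0 else ang


def _dihedrals_frames(coords, quad):
    """Vectorized signed dihedral for one quadruple across all frames."""
    p1, p2, p3, p4 = (coords[:, i, :] for i in quad)
    b0, axis, b2 = p1 - p2, p3 - p2, p4 - p3
    b1 = axis / np.linalg.norm(axis, axis=1, keepdims=True)
    v = b0 - np.sum(b0 * b1, axis=1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=1, keepdims=True) * b1
    ang = np.degrees(np.arctan2(np.sum(np.cross(b1, v) * w, axis=1),
                                np.sum(v * w, axis=1)))
    return np.where(ang == -180.0, 180.0, ang)


def torsion_distribution(traj: Trajectory, quadruples, bin_width=5.0,
                         running_window=5) -> TorsionDistribution:
    """Histograms of torsion angles for a set of quadruples, plus their average.

    The conventional macrocycle set is one proper N–N–N–N quadruple and four
    improper metal–Cα–Cα–N quadruples (one per pyrrole); any list of 4-tuples
    works. The running average smooths the averaged histogram circularly over
    ``running_window`` bins (the ±180° seam wraps).
    """
    quadruples = [tuple(int(i) for i in q) for q in quadruples]
    if not quadruples:
        raise ValueError("no torsion quadruples given")
    nb = int(round(360.0 / bin_width))
    edges = np.linspace(-180.0, 180.0, nb + 1)
    per = np.zeros((len(quadruples), nb))
    for qi, quad in enumerate(quadruples):
        ang = _dihedrals_frames(traj.coordinates, quad)
        # (−180, 180]: fold an exact −180 onto +180 before the half-open bins.
        ang = np.where(ang <= -180.0, ang + 360.0, ang)
        h, _ = np.histogram(ang, bins=edges)
        per[qi] = h / traj.n_frames
    per_norm = per / per.sum(axis=1, keepdims=True)
    avg = per_norm.mean(axis=0)
    w = max(1, int(running_window))
    kernel = np.ones(w) / w
    padded = np.concatenate([avg[-(w // 2):], avg, avg[: w // 2]])
    run = np.convolve(padded, kernel, mode="valid")[:nb] if w > 1 else avg.copy()
    return TorsionDistribution(bin_edges=edges, per_quadruple=per_norm,
                               average=avg, running_average=run,
                               quadruples=quadruples)
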