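"""Solute-frame alignment and 3D solvent-density maps.

Kabsch superposition onto a reference frame, voxelised spatial distribution
functions (SDF), least-squares porphyrin-plane fitting, and angular-radial
distribution (ARD) maps of solvent density as a function of metal distance and
angle to the ring-plane normal, with optional first-shell subtraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .trajectory_io import (
    RING_HEAVY_ROLES,
    Topology,
    Trajectory,
    minimum_image_displacement,
)


@dataclass
class SpatialDensityGrid:
    """Regular 3D grid of mean solvent count density (atoms/Å³)."""

    origin: np.ndarray        # corner of voxel (0,0,0), Å
    spacing: float            # voxel edge, Å
    density: np.ndarray       # (nx, ny, nz)
    n_frames: int

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def mean_in_grid_count(self) -> float:
        return float(self.density.sum() * self.voxel_volume)


@dataclass
class ARDGrid:
    """Joint (r, θ) solvent density around the metal, θ from the ring normal.

    ``density[i, j]`` is normalized per azimuthally-integrated volume element
    ``(2π/3)(r_hi³ − r_lo³)(cos θ_lo − cos θ_hi)``, which stays finite in the
    polar bins where sin θ → 0.
    """

    r_edges: np.ndarray       # Å
    theta_edges: np.ndarray   # degrees, [0, 180]
    density: np.ndarray
    counts: np.ndarray
    n_frames: int
    plane: dict

    def volume_elements(self) -> np.ndarray:
        r3 = self.r_edges**3
        ct = np.cos(np.radians(self.theta_edges))
        dv = (2.0 * np.pi / 3.0) * np.subtract.outer(r3[1:] - r3[:-1],
                                                     ct[:-1] - ct[1:])
        return dv


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def kabsch_rotation(P, Q):
    """Optimal proper rotation R (and centroids) with R·(P−p̄) ≈ Q−q̄.

    Standard SVD solution with the determinant correction that forbids
    reflections. Raises on degenerate (collinear) point sets.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1e-300):
        raise ValueError("reference atoms are collinear or degenerate")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, pc, qc


def kabsch_align(traj: Trajectory, topology: Topology | None = None,
                 ref_roles=RING_HEAVY_ROLES, ref_indices=None,
                 ref_frame=0) -> Trajectory:
    """Rigidly superpose every frame onto ``ref_frame``.

    The fit minimises the RMSD over the reference atom set (default: the ring
    heavy atoms plus metal) using proper rotations only; the transform is then
    applied to all atoms (and to velocities, rotation only, when present).
    """
    if ref_indices is None:
        if topology is None:
            raise ValueError("need a topology or explicit ref_indices")
        ref_indices = topology.indices_with_role(ref_roles)
        if ref_indices.size == 0:
            ref_indices = np.arange(traj.n_atoms)
    ref_indices = np.asarray(ref_indices, dtype=int)
    if ref_indices.size < 3:
        raise ValueError("need at least 3 reference atoms")
    ref = traj.coordinates[ref_frame][ref_indices]
    out = np.empty_like(traj.coordinates)
    vel = np.empty_like(traj.velocities) if traj.velocities is not None else None
    for f in range(traj.n_frames):
        R, pc, qc = kabsch_rotation(traj.coordinates[f][ref_indices], ref)
        out[f] = (traj.coordinates[f] - pc) @ R.T + qc
        if vel is not None:
            vel[f] = traj.velocities[f] @ R.T
    return replace(traj, coordinates=out, velocities=vel, box_length=None)


def fit_ring_plane(frame_coords, ring_N_ids, prev_normal=None):
    """Least-squares plane through the four ring nitrogens.

    Returns ``(unit_normal, centroid)``. The normal's sign keeps continuity
    with ``prev_normal`` when given; otherwise it points along +z (tie-break:
    +x when the z-component vanishes).
    """
    pts = np.asarray(frame_coords, float)[np.asarray(ring_N_ids, int)]
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    U, S, Vt = np.linalg.svd(centered)
    if S[1] < 1e-10 * max(S[0], 1e-300):
        raise ValueError("ring nitrogens are collinear; plane undefined")
    normal = Vt[2]
    if prev_normal is not None:
        if normal @ np.asarray(prev_normal) < 0:
            normal = -normal
    elif normal[2] < 0 or (normal[2] == 0 and normal[0] < 0):
        normal = -normal
    return normal, centroid


# ---------------------------------------------------------------------------
# SDF
# ---------------------------------------------------------------------------

def compute_sdf(traj: Trajectory, topology: Topology, target_role="water_O",
                spacing=0.5, extent=8.0, origin=None,
                shape=None) -> SpatialDensityGrid:
    """Voxel histogram of target positions in the (aligned) solute frame.

    The grid defaults to a cube of half-width ``extent`` centred on the metal's
    frame-0 position. Input should already be aligned (``kabsch_align``); the
    density is the per-frame mean count per voxel volume.
    """
    if traj.n_frames == 0:
        raise ValueError("zero frames")
    targets = topology.indices_with_role(target_role)
    if targets.size == 0:
        raise ValueError(f"no atoms with role {target_role!r}")
    metal = topology.metal_index
    center = traj.coordinates[0][metal]
    if origin is None:
        origin = center - extent
    origin = np.asarray(origin, float)
    if shape is None:
        n = int(round(2 * extent / spacing))
        shape = (n, n, n)
    hi = origin + np.array(shape) * spacing
    if np.any(center < origin) or np.any(center >= hi):
        warnings.warn("SDF grid does not contain the metal center", stacklevel=2)
    pos = traj.coordinates[:, targets, :].reshape(-1, 3)
    edges = [np.linspace(origin[k], hi[k], shape[k] + 1) for k in range(3)]
    counts, _ = np.histogramdd(pos, bins=edges)
    density = counts / (traj.n_frames * spacing**3)
    return SpatialDensityGrid(origin=origin, spacing=spacing, density=density,
                              n_frames=traj.n_frames)


# ---------------------------------------------------------------------------
# ARD
# ---------------------------------------------------------------------------

def compute_ard(traj: Trajectory, topology: Topology, target_role="water_O",
                r_max=8.0, dr=0.1, dtheta=2.0, center_role="metal") -> ARDGrid:
    """Angular-radial density map of targets around the metal.

    For every frame the ring plane is refit from the four nitrogens (normal
    sign carried over between frames to avoid spurious θ ↔ 180−θ flips); each
    target contributes at (metal distance r, angle θ to the normal).
    """
    if traj.n_frames == 0:
        raise ValueError("zero frames")
    targets = topology.indices_with_role(target_role)
    if targets.size == 0:
        raise ValueError(f"no atoms with role {target_role!r}")
    center = topology.indices_with_role(center_role)
    if center.size != 1:
        raise ValueError("ARD requires exactly one center atom")
    center = int(center[0])
    ring_n = topology.ring_n_indices
    nr = int(round(r_max / dr))
    nt = int(round(180.0 / dtheta))
    r_edges = np.linspace(0.0, nr * dr, nr + 1)
    t_edges = np.linspace(0.0, 180.0, nt + 1)
    counts = np.zeros((nr, nt))
    normal = None
    for f in range(traj.n_frames):
        frame = traj.coordinates[f]
        normal, _ = fit_ring_plane(frame, ring_n, prev_normal=normal)
        disp = minimum_image_displacement(frame[center], frame[targets],
                                          traj.box_length)
        r = np.sqrt(np.sum(disp * disp, axis=-1))
        ok = (r > 0) & (r < r_edges[-1])
        cost = np.clip(disp[ok] @ normal / r[ok], -1.0, 1.0)
        theta = np.degrees(np.arccos(cost))
        h, _, _ = np.histogram2d(r[ok], theta, bins=[r_edges, t_edges])
        counts += h
    grid = ARDGrid(r_edges=r_edges, theta_edges=t_edges, counts=counts,
                   density=np.zeros_like(counts), n_frames=traj.n_frames,
                   plane={"ring_N_ids": [int(i) for i in ring_n],
                          "sign_convention": "continuity; first frame +z"})
    grid.density = counts / (traj.n_frames * grid.volume_elements())
    return grid


def subtract_first_shell(ard: ARDGrid, shell_r_limit) -> ARDGrid:
    """Zero all (r, θ) cells with any overlap below ``shell_r_limit``.

    Implements the radius-band reading of first-shell subtraction: every bin
    whose lower radial edge lies below the limit is removed, the remainder is
    untouched. (Identity-tracked subtraction of specific coordinated molecules
    is a different, stricter operation not implemented here.)
    """
    if not (0 <= shell_r_limit <= ard.r_edges[-1] + 1e-12):
        raise ValueError("shell_r_limit outside the ARD grid")
    mask = ard.r_edges[:-1] < shell_r_limit
    density = ard.density.copy()
    counts = ard.counts.copy()
    density[mask, :] = 0.0
    counts[mask, :] = 0.0
    return ARDGrid(r_edges=ard.r_edges.copy(), theta_edges=ard.theta_edges.copy(),
                   density=density, counts=counts, n_frames=ard.n_frames,
                   plane=dict(ard.plane))
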