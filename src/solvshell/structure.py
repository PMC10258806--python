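"""Radial and angular solvation statistics.

Pair distribution functions g(r) with running coordination-number integrals,
shell-boundary detection from smoothed minima, angular distribution functions
of ligand–center–ligand angles, and coordination-number distributions — the 1D
statistics that characterise how water organises around a metalloporphyrin.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import argrelextrema

from .trajectory_io import Topology, Trajectory, minimum_image_displacement


def _resolve_selection(topology, role, indices, what):
    if indices is not None:
        sel = np.asarray(indices, dtype=int)
    else:
        sel = topology.indices_with_role(role)
    if sel.size == 0:
        raise ValueError(f"empty {what} selection (role={role!r})")
    return sel


@dataclass
class RadialDistribution:
    """Binned g(r) with its running coordination-number integral.

    ``bin_edges`` (length nb+1, half-open bins), ``g`` per bin, reference
    density ``rho`` in atoms/Å³, and ``cumulative_cn`` evaluated at the bin
    edges (``cumulative_cn[0] = 0``).
    """

    bin_edges: np.ndarray
    g: np.ndarray
    rho: float
    cumulative_cn: np.ndarray
    n_frames: int
    n_centers: int = 1

    @property
    def r(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class ShellPartition:
    """Shell boundaries (strictly increasing radii of g(r) minima).

    Shell ``i`` is the half-open interval ``[boundaries[i-1], boundaries[i])``
    with an implicit inner edge at 0; radii beyond the last boundary belong to
    shell ``len(boundaries)``. ``zero_minimum[i]`` records whether the minimum
    defining boundary ``i`` sits on a g = 0 run — the stability diagnostic
    (a nonzero minimum signals ongoing shell exchange).
    """

    boundaries: list
    zero_minimum: list

    def __post_init__(self):
        b = list(self.boundaries)
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def n_shells(self) -> int:
        return len(self.boundaries)


@dataclass
class AngularDistribution:
    """Normalized histogram of registered center angles over [0°, 180°]."""

    bin_edges: np.ndarray
    frequency: np.ndarray
    counts: np.ndarray
    n_angles: int

    @property
    def angles(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class CNDistribution:
    """Empirical distribution of per-frame integer coordination numbers."""

    probabilities: dict
    n_frames: int

    def p(self, k: int) -> float:
        return self.probabilities.get(int(k), 0.0)

    def mean(self) -> float:
        return sum(k * p for k, p in self.probabilities.items())


# ---------------------------------------------------------------------------
# RDF
# ---------------------------------------------------------------------------

def _pair_distances_frame(frame, centers, targets, box_length):
    """Center–target minimum-image distances for one frame, self-pairs removed."""
    disp = minimum_image_displacement(frame[centers][:, None, :],
                                      frame[targets][None, :, :], box_length)
    d = np.sqrt(np.sum(disp * disp, axis=-1))
    same = centers[:, None] == targets[None, :]
    return d[~same]


def compute_rdf(traj: Trajectory, topology: Topology, center_role, target_role,
                r_max, dr=0.05, rho=None, center_indices=None,
                target_indices=None) -> RadialDistribution:
    """Radial distribution function of targets around centers.

    Normalized by ideal-gas shell counts at density ``ρ = N_target/V`` for a
    periodic box (a non-periodic system requires an explicit ``rho``). The
    cumulative coordination number is accumulated from the same raw pair
    counts, so ``integrate_coordination`` is exact rather than a quadrature of
    the binned g(r).
    """
    centers = _resolve_selection(topology, center_role, center_indices, "center")
    targets = _resolve_selection(topology, target_role, target_indices, "target")
    if dr <= 0:
        raise ValueError("dr must be positive")
    if traj.box_length is not None and r_max > traj.box_length / 2 + 1e-12:
        raise ValueError(
            f"r_max={r_max} exceeds half the box length ({traj.box_length / 2})"
        )
    nb = int(round(r_max / dr))
    edges = np.linspace(0.0, nb * dr, nb + 1)
    counts = np.zeros(nb, dtype=np.int64)
    for f in range(traj.n_frames):
        d = _pair_distances_frame(traj.coordinates[f], centers, targets,
                                  traj.box_length)
        h, _ = np.histogram(d[d < edges[-1]], bins=edges)
        counts += h

    if rho is None:
        if traj.box_length is None:
            raise ValueError("non-periodic trajectory requires an explicit rho")
        rho = len(targets) / traj.box_length**3
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = traj.n_frames * len(centers) * rho * shell_vol
    g = counts / norm
    cn = np.concatenate([[0.0], np.cumsum(counts)]) / (traj.n_frames * len(centers))
    return RadialDistribution(bin_edges=edges, g=g, rho=rho, cumulative_cn=cn,
                              n_frames=traj.n_frames, n_centers=len(centers))


def integrate_coordination(rdf: RadialDistribution, r_cut) -> float:
    """Average coordination number n(r_cut), linearly interpolated on the grid."""
    edges = rdf.bin_edges
    if not (edges[0] <= r_cut <= edges[-1]):
        raise ValueError(f"r_cut={r_cut} outside the RDF grid [{edges[0]}, {edges[-1]}]")
    return float(np.interp(r_cut, edges, rdf.cumulative_cn))


def detect_shell_boundaries(rdf: RadialDistribution, smoothing_window=5,
                            n_shells=1, min_peak_ratio=2.0) -> ShellPartition:
    """Shell limits from local minima of the moving-average-smoothed g(r).

    A minimum lying on a contiguous g = 0 run is placed at the run's midpoint
    and flagged as a zero minimum (no exchange across that boundary); otherwise
    the smoothed minimum's radius is used and flagged nonzero. A nonzero
    minimum only counts as a shell boundary when some preceding peak exceeds
    ``min_peak_ratio`` times its depth — statistical ripple on a flat
    (ideal-gas-like) profile is not shell structure.
    """
    g = np.asarray(rdf.g, dtype=float)
    if g.size == 0:
        raise ValueError("empty RDF")
    w = max(1, int(smoothing_window))
    kernel = np.ones(w) / w
    smooth = np.convolve(g, kernel, mode="same")
    r = rdf.r

    maxima = argrelextrema(smooth, np.greater_equal, order=max(1, w // 2))[0]
    # Collapse plateau runs of equal smoothed value to a single peak index.
    maxima = [m for m in maxima if smooth[m] > 0]
    peaks = []
    for m in maxima:
        if not peaks or m - peaks[-1] > w:
            peaks.append(m)
    if not peaks:
        raise ValueError("g(r) has no peak; cannot define shells (monotone profile?)")

    minima_idx = argrelextrema(smooth, np.less_equal, order=max(1, w // 2))[0]
    first_peak = peaks[0]
    candidates = []  # (radius, zero_flag)
    # Zero runs strictly after the first occupied bin of the first peak
    # (smoothing widens a narrow peak into a plateau whose left edge can sit
    # on empty bins; those are not inter-shell gaps).
    n = g.size
    start = first_peak
    while start < n and g[start] <= 0:
        start += 1
    in_zero = g <= 0
    i = start + 1
    while i < n:
        if in_zero[i]:
            j = i
            while j < n and in_zero[j]:
                j += 1
            if j < n:  # run ends before the grid does → genuine inter-peak gap
                candidates.append((0.5 * (r[i] + r[j - 1]), True))
            i = j
        else:
            i += 1
    for m in minima_idx:
        if m <= start or g[m] <= 0:
            continue
        if np.max(smooth[:m]) < min_peak_ratio * smooth[m]:
            continue  # shallow ripple, not a shell limit
        candidates.append((float(r[m]), False))
    candidates.sort()
    # Merge candidates closer than the smoothing window.
    merged = []
    for rad, flag in candidates:
        if merged and rad - merged[-1][0] < w * (r[1] - r[0] if r.size > 1 else 1.0):
            if flag and not merged[-1][1]:
                merged[-1] = (rad, flag)
            continue
        merged.append((rad, flag))
    if len(merged) < n_shells:
        raise ValueError(
            f"found only {len(merged)} shell boundaries "
            f"{[round(b, 3) for b, _ in merged]}, need {n_shells}"
        )
    sel = merged[:n_shells]
    return ShellPartition(boundaries=[b for b, _ in sel],
                          zero_minimum=[z for _, z in sel])


# ---------------------------------------------------------------------------
# ADF / CND
# ---------------------------------------------------------------------------

def compute_adf(traj: Trajectory, topology: Topology, center_role="metal",
                ligand_roles=("ring_N", "water_O"), r_cut=2.67,
                bin_width=2.0) -> AngularDistribution:
    """Distribution of all registered ligand–center–ligand angles.

    Per frame and center, every unordered pair of ligand atoms within ``r_cut``
    of the center contributes the angle subtended at the center; the histogram
    is normalized over all registered angles.
    """
    centers = _resolve_selection(topology, center_role, None, "center")
    ligands = _resolve_selection(topology, ligand_roles, None, "ligand")
    if r_cut <= 0:
        raise ValueError("r_cut must be positive")
    nb = int(round(180.0 / bin_width))
    edges = np.linspace(0.0, 180.0, nb + 1)
    counts = np.zeros(nb, dtype=np.int64)
    registered = 0
    any_pair = False
    for f in range(traj.n_frames):
        frame = traj.coordinates[f]
        for c in centers:
            disp = minimum_image_displacement(frame[c], frame[ligands],
                                              traj.box_length)
            d = np.sqrt(np.sum(disp * disp, axis=-1))
            mask = (d < r_cut) & (ligands != c)
            if mask.sum() < 2:
                continue
            any_pair = True
            u = disp[mask] / d[mask][:, None]
            cosang = np.clip(u @ u.T, -1.0, 1.0)
            iu = np.triu_indices(len(u), k=1)
            angles = np.degrees(np.arccos(cosang[iu]))
            h, _ = np.histogram(angles, bins=edges)
            counts += h
            registered += angles.size
    if not any_pair:
        raise ValueError("no frame has two or more ligands within r_cut of a center")
    freq = counts / registered
    return AngularDistribution(bin_edges=edges, frequency=freq, counts=counts,
                               n_angles=registered)


def compute_cnd(traj: Trajectory, topology: Topology, center_role="metal",
                target_roles=("ring_N", "water_O"), r_cut=2.67) -> CNDistribution:
    """Per-frame integer count of targets within r_cut of the center(s).

    Counting uses the strict ``d < r_cut`` convention so that the distribution
    mean equals ``integrate_coordination`` at the same cutoff.
    """
    centers = _resolve_selection(topology, center_role, None, "center")
    targets = _resolve_selection(topology, target_roles, None, "target")
    if r_cut <= 0:
        raise ValueError("r_cut must be positive")
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    per_frame = []
    for f in range(traj.n_frames):
        frame = traj.coordinates[f]
        for c in centers:
            disp = minimum_image_displacement(frame[c], frame[targets],
                                              traj.box_length)
            d = np.sqrt(np.sum(disp * disp, axis=-1))
            per_frame.append(int(np.sum((d < r_cut) & (targets != c))))
    vals, cts = np.unique(per_frame, return_counts=True)
    total = len(per_frame)
    probs = {int(v): c / total for v, c in zip(vals, cts)}
    return CNDistribution(probabilities=probs, n_frames=traj.n_frames)


def compute_nh_cnd(traj: Trajectory, topology: Topology,
                   h_bond_cutoff=2.5) -> CNDistribution:
    """Per-frame count of water hydrogens H-bond-close to any ring nitrogen.

    A pure distance criterion (default 2.5 Å): a water H counts once if it is
    within the cutoff of at least one ring N.
    """
    ring_n = topology.indices_with_role("ring_N")
    water_h = topology.indices_with_role("water_H")
    if ring_n.size == 0 or water_h.size == 0:
        raise ValueError("topology must have ring_N and water_H atoms")
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    per_frame = []
    for f in range(traj.n_frames):
        frame = traj.coordinates[f]
        disp = minimum_image_displacement(frame[water_h][:, None, :],
                                          frame[ring_n][None, :, :],
                                          traj.box_length)
        d = np.sqrt(np.sum(disp * disp, axis=-1))
        per_frame.append(int(np.sum(np.any(d < h_bond_cutoff, axis=1))))
    vals, cts = np.unique(per_frame, return_counts=True)
    probs = {int(v): c / len(per_frame) for v, c in zip(vals, cts)}
    return CNDistribution(probabilities=probs, n_frames=traj.n_frames)
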