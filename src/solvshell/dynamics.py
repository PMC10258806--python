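"""Shell-exchange dynamics: occupancy series, direct-method residence times.

The direct method counts how often a ligand leaves its coordination shell and
stays away longer than a persistence threshold t*; the mean residence time is
then τ = CN · t_sim / N_ex. Two thresholds are conventional: t* = 0.0 ps
counts every boundary crossing, t* = 0.5 ps (≈ the H-bond lifetime in water)
counts only sustainable exchanges. Their ratio R_ex = N_ex^0.0 / N_ex^0.5
measures how many attempts a successful exchange needs; its reciprocal is the
sustainability coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .structure import ShellPartition
from .trajectory_io import Topology, Trajectory, minimum_image_displacement


@dataclass
class OccupancySeries:
    """Per-ligand shell index per frame (0 = innermost, k = beyond last boundary)."""

    shell_index: np.ndarray    # (n_frames, n_ligands) int
    ligand_ids: np.ndarray
    dt: float
    partition: ShellPartition

    @property
    def n_frames(self) -> int:
        return self.shell_index.shape[0]

    @property
    def n_ligands(self) -> int:
        return self.shell_index.shape[1]

    @property
    def t_sim(self) -> float:
        return (self.n_frames - 1) * self.dt

    def mean_occupancy(self, shell: int) -> float:
        return float(np.mean(np.sum(self.shell_index == shell, axis=1)))


class ExchangeCounts(NamedTuple):
    """Departures from the probed shell and (separately) entries into it,
    each requiring persistence strictly longer than t*."""

    departures: int
    entries: int


@dataclass
class NoExchange:
    """Sentinel for an unobservable residence time (no exchange events)."""

    t_sim: float

    def __str__(self):
        return f"> {self.t_sim:g} ps (no exchange observed)"


@dataclass
class RexResult:
    r_ex: float | None
    sustainability: float | None

    @property
    def defined(self) -> bool:
        return self.r_ex is not None


@dataclass
class ResidenceStats:
    """The direct-method bundle for one probed shell."""

    cn: float               # mean occupancy of the probed shell
    t_sim: float            # ps
    n_ex: dict              # t* (ps) -> departures
    tau: dict               # t* (ps) -> τ (ps) or NoExchange
    r_ex: float | None
    sustainability: float | None


@dataclass
class DistanceSeries:
    """Per-ligand center distance vs time, with shell-boundary annotations."""

    times: np.ndarray
    distances: np.ndarray    # (n_frames, n_ligands)
    ligand_ids: np.ndarray
    boundaries: list


def shell_occupancy_series(traj: Trajectory, topology: Topology,
                           center_role="metal", target_role="water_O",
                           partition: ShellPartition = None) -> OccupancySeries:
    """Assign every target a shell index per frame from its metal distance.

    Half-open ``[lo, hi)`` shells: a ligand exactly on a boundary radius is in
    the shell whose lower edge that boundary is.
    """
    if partition is None:
        raise ValueError("a ShellPartition is required")
    centers = topology.indices_with_role(center_role)
    targets = topology.indices_with_role(target_role)
    if centers.size != 1:
        raise ValueError("occupancy tracking requires exactly one center atom")
    if targets.size == 0:
        raise ValueError("empty target selection")
    c = int(centers[0])
    disp = minimum_image_displacement(
        traj.coordinates[:, c, None, :], traj.coordinates[:, targets, :],
        traj.box_length)
    d = np.sqrt(np.sum(disp * disp, axis=-1))
    bounds = np.asarray(partition.boundaries, dtype=float)
    idx = np.searchsorted(bounds, d, side="right")
    return OccupancySeries(shell_index=idx.astype(int), ligand_ids=targets,
                           dt=traj.dt, partition=partition)


def _persistence_frames(t_star: float, dt: float) -> int:
    """Minimum run length (frames) for an absence strictly longer than t*."""
    return int(math.floor(t_star / dt + 1e-9))


def count_exchanges(series: OccupancySeries, shell_index: int,
                    t_star: float) -> ExchangeCounts:
    """Count shell departures (and entries) persisting strictly longer than t*.

    A single continuous absence is one event no matter how many frames it
    spans; a run truncated by the end of the trajectory counts once its
    observed length already exceeds t*. ``t_star = 0`` counts every crossing.
    """
    n_shells = len(series.partition.boundaries)
    if not (0 <= shell_index <= n_shells):
        raise ValueError(f"shell_index {shell_index} out of range [0, {n_shells}]")
    if t_star < 0:
        raise ValueError("t_star must be non-negative")
    m_min = _persistence_frames(t_star, series.dt)
    departures = entries = 0
    for lig in range(series.n_ligands):
        inside = series.shell_index[:, lig] == shell_index
        # Run-length encode.
        change = np.nonzero(np.diff(inside))[0] + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [inside.size]])
        for s, e in zip(starts, ends):
            run_inside = bool(inside[s])
            if s == 0:
                continue  # initial state, not a crossing
            if not run_inside:       # departure at frame s
                if (e - s) > m_min:
                    departures += 1
            else:                    # entry at frame s
                if (e - s) > m_min:
                    entries += 1
    return ExchangeCounts(departures=departures, entries=entries)


def mean_residence_time(cn: float, t_sim: float, n_ex: int):
    """Direct-method mean residence time τ = CN · t_sim / N_ex (ps).

    With no registered exchange the residence time exceeds the simulated
    window; a :class:`NoExchange` sentinel is returned instead of a number.
    """
    if n_ex < 0:
        raise ValueError("n_ex must be non-negative")
    if n_ex == 0:
        return NoExchange(t_sim=t_sim)
    return cn * t_sim / n_ex


def compute_rex(n_ex_0: int, n_ex_05: int) -> RexResult:
    """R_ex = N_ex^0.0 / N_ex^0.5 and the sustainability coefficient 1/R_ex."""
    if n_ex_05 == 0:
        return RexResult(r_ex=None, sustainability=None)
    r = n_ex_0 / n_ex_05
    return RexResult(r_ex=r, sustainability=1.0 / r)


def residence_stats(series: OccupancySeries, shell_index: int,
                    t_stars=(0.0, 0.5)) -> ResidenceStats:
    """Full direct-method bundle (CN, N_ex, τ at each t*, R_ex) for one shell."""
    cn = series.mean_occupancy(shell_index)
    t_sim = series.t_sim
    n_ex, tau = {}, {}
    for ts in t_stars:
        n = count_exchanges(series, shell_index, ts).departures
        n_ex[ts] = n
        tau[ts] = mean_residence_time(cn, t_sim, n)
    rex = None
    if 0.0 in n_ex and 0.5 in n_ex:
        rex = compute_rex(n_ex[0.0], n_ex[0.5])
    return ResidenceStats(
        cn=cn, t_sim=t_sim, n_ex=n_ex, tau=tau,
        r_ex=rex.r_ex if rex else None,
        sustainability=rex.sustainability if rex else None,
    )


def distance_series(traj: Trajectory, topology: Topology, center_role="metal",
                    target_role="water_O",
                    partition: ShellPartition = None) -> DistanceSeries:
    """Minimum-image center–target distances per frame (Å vs ps).

    One column per (center, target) pair, excluding self-pairs, so the table
    is symmetric under swapping the two roles.
    """
    centers = topology.indices_with_role(center_role)
    targets = topology.indices_with_role(target_role)
    if centers.size == 0 or targets.size == 0:
        raise ValueError("empty selection")
    cols = []
    ids = []
    for c in centers:
        disp = minimum_image_displacement(
            traj.coordinates[:, c, None, :], traj.coordinates[:, targets, :],
            traj.box_length)
        d = np.sqrt(np.sum(disp * disp, axis=-1))
        keep = targets != c
        cols.append(d[:, keep])
        ids.extend((int(c), int(t)) for t in targets[keep])
    return DistanceSeries(times=traj.times, distances=np.concatenate(cols, axis=1),
                          ligand_ids=np.array(ids),
                          boundaries=list(partition.boundaries) if partition else [])
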