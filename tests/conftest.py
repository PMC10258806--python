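import numpy as np
import pytest

import solvshell as sv


@pytest.fixture(scope="session")
def scaffold():
    """Idealized planar Co-porphine scaffold (topology, coords)."""
    return sv.generate_porphyrin_scaffold(2.0)


@pytest.fixture(scope="session")
def octahedral_snapshot(scaffold):
    """Scaffold plus two axial first-shell waters at 2.2 Å (6-coordination)."""
    shells = sv.ShellSpec([(1.93, 2.67)], [2], placement_radius=[2.2])
    return sv.generate_shell_snapshot(scaffold, shells, seed=11)


@pytest.fixture(scope="session")
def square_pyramid_snapshot(scaffold):
    """Scaffold plus a single axial water at 2.2 Å (5-coordination)."""
    shells = sv.ShellSpec([(1.93, 2.67)], [1], placement_radius=[2.2])
    return sv.generate_shell_snapshot(scaffold, shells, seed=12)


@pytest.fixture(scope="session")
def exchange_system(scaffold):
    """Two-shell telegraph exchange trajectory with its exact event log."""
    shells = sv.ShellSpec([(1.93, 2.67), (3.27, 5.03)], [0, 0], jitter=0.05)
    spec = sv.ExchangeSpec(rate=0.5, n_ligands=10, duration=100.0, dt=0.01, seed=21)
    traj, topo, log = sv.generate_exchange_trajectory(scaffold, spec, shells)
    return traj, topo, log, spec, shells


def brute_force_pair_histogram(frame, centers, targets, box, edges):
    """Independent O(N²) pair-count oracle using an explicit python loop."""
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    dists = []
    for c in centers:
        for t in targets:
            if c == t:
                continue
            dv = frame[t] - frame[c]
            if box is not None:
                dv = dv - box * np.floor(dv / box + 0.5)
            dists.append(np.sqrt(np.sum(dv * dv)))
    d = np.array(dists)
    h, _ = np.histogram(d[d < edges[-1]], bins=edges)
    return h
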