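# solvshell

Hydration-shell structure and dynamics analysis for MD trajectories of
metal–macrocycle complexes — written for simulators who have a Cartesian
trajectory of a solvated metalloporphyrin (or any single-center solute) and
want the full standard battery of solvation analyses with tested, reproducible
numerics.

## What it computes

Given a trajectory (multi-frame XYZ) and a topology (PDB) with atom roles
(metal center, the four pyrrole nitrogens, ring carbons/hydrogens, water
O/H), `solvshell` produces:

- **g(r) and coordination numbers** — the pair distribution of water oxygens
  around the metal, normalized to the bulk density ρ, with the running
  integral n(r) = ∫₀ʳ 4πr′²ρ g(r′) dr′ and automatic detection of shell
  boundaries at the (smoothed) minima of g(r), flagging whether each minimum
  is zero (no exchange across it) or nonzero.
- **ADF / CND** — the distribution of all registered X–M–X angles within a
  cutoff, and the per-frame coordination-number distribution. A rigid
  octahedron gives angle mass 12:3 at 90°/180°; a square pyramid gives 8:2.
- **SDF / ARD** — 3D solvent density in the Kabsch-aligned solute frame, and
  the angular-radial map of density vs (metal distance r, angle θ to the
  ring-plane normal), with first-shell subtraction to expose the second
  shell.
- **Residence times (direct method)** — shell-occupancy series, exchange
  counts N_ex at persistence thresholds t\* (0.0 and 0.5 ps by default), the
  mean residence time **τ = CN · t_sim / N_ex**, the exchange ratio
  R_ex = N_ex^0.0/N_ex^0.5 and its reciprocal, the sustainability
  coefficient.
- **Vibrational power spectra** — C(t) = ⟨Σⱼ vⱼ(tᵢ)·vⱼ(tᵢ+t)⟩ over evenly
  spaced time origins (2.0 ps correlation length, 5000 origins by default,
  hydrogens excluded), cosine-transformed to intensity vs wavenumber (cm⁻¹).
- **PMF** — w(r) = −RT ln g(r) in kJ/mol at T = 298.15 K (R = 8.314
  J·K⁻¹·mol⁻¹), masked where g = 0, with per-shell well depths.
- **SASA** — Shrake–Rupley surface areas (1.4 Å probe, 960 sphere points,
  Bondi radii) decomposed into hydrophobic (C, ring H) and hydrophilic
  (metal, N, O) contributions, in nm².
- **Flexibility** — per-atom RMSF of ring heavy atoms after rigid-body
  alignment, and dihedral (N–N–N–N) / improper (M–Cα–Cα–N) torsional
  distributions.

Because ab initio trajectories of such systems are rarely deposited, the
package ships first-class **synthetic generators** with exact ground truth:
layered hydration shells with prescribed occupancies, telegraph-process shell
exchange with a complete event log, analytically propagated harmonic
oscillators, rigid-body and known-σ jitter trajectories, and an ideal-gas
box. Every analysis stage is validated by parameter recovery against these
generators.

## Worked example

```python
import solvshell as sv
from solvshell.structure import ShellPartition

scaffold = sv.generate_porphyrin_scaffold(2.0)
shells = sv.ShellSpec([(1.93, 2.67), (3.27, 5.03)], [0, 0], jitter=0.05)
spec = sv.ExchangeSpec(rate=0.5, n_ligands=20, duration=200.0, dt=0.01, seed=3)
traj, topo, log = sv.generate_exchange_trajectory(scaffold, spec, shells)

series = sv.shell_occupancy_series(
    traj, topo, partition=ShellPartition(shells.boundaries, [False, False]))
stats = sv.residence_stats(series, shell_index=0, t_stars=(0.0, 0.5))
print(stats.cn, stats.n_ex, stats.tau)
```

prints (see `examples/03_exchange_residence_times.py` for the full script):

```
mean first-shell occupancy CN = 9.83 over 200 ps
N_ex(t*=0.0) = 982  (event log: 982)
N_ex(t*=0.5) = 770  (event log: 770)
tau_0.0 = 2.00 ps   (true mean dwell 1/k = 2.00 ps)
R_ex = 1.28, sustainability = 0.78
```

The ligands hop between the two shells with rate k = 0.5/ps, so the true mean
dwell time is 2 ps; the direct method recovers it from CN·t_sim/N_ex, and the
exchange counts agree exactly with the generator's event log at both
persistence thresholds. The other scripts in `examples/` cover g(r) and
coordination numbers, ADF/CND geometry fingerprints, vibrational spectra,
PMF/SASA/RMSF/torsions, and the one-command pipeline.

## Command line

A thin CLI mirrors the library:

```bash
solvshell synth exchange --rate 0.5 --n-ligands 10 -o ex.xyz   # + ground truth JSON
solvshell rdf traj.xyz topo.pdb --dt 0.002 --box 39.28 -o rdf.tsv
solvshell run -c config.yml                                     # full battery
```

`solvshell run` executes every stage in order and writes tab-separated
curves, JSON summaries, an OpenDX volumetric grid for the SDF, and a
deterministic `report.json` (byte-identical on rerun with the same config
and seed).

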