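"""Direct-method mean residence times on a trajectory with known exchange.

Ligands hop between two hydration shells as a telegraph process with rate
k = 0.5 /ps (mean dwell 2 ps). The direct method should recover τ ≈ 1/k at
t* = 0, and the counts at both persistence thresholds match the generator's
event log exactly.
"""

import solvshell as sv
from solvshell.structure import ShellPartition

scaffold = sv.generate_porphyrin_scaffold(2.0)
shells = sv.ShellSpec([(1.93, 2.67), (3.27, 5.03)], [0, 0], jitter=0.05)
spec = sv.ExchangeSpec(rate=0.5, n_ligands=20, duration=200.0, dt=0.01, seed=3)
traj, topo, log = sv.generate_exchange_trajectory(scaffold, spec, shells)

part = ShellPartition(shells.boundaries, [False, False])
series = sv.shell_occupancy_series(traj, topo, partition=part)
stats = sv.residence_stats(series, shell_index=0, t_stars=(0.0, 0.5))

print(f"mean first-shell occupancy CN = {stats.cn:.2f} over {stats.t_sim:.0f} ps")
print(f"N_ex(t*=0.0) = {stats.n_ex[0.0]}  (event log: {log.crossings_from(0, 0.0)})")
print(f"N_ex(t*=0.5) = {stats.n_ex[0.5]}  (event log: {log.crossings_from(0, 0.5)})")
print(f"tau_0.0 = {stats.tau[0.0]:.2f} ps   (true mean dwell 1/k = 2.00 ps)")
print(f"R_ex = {stats.r_ex:.2f}, sustainability = {stats.sustainability:.2f}")
# τ_0.0 within ~10% of 2 ps demonstrates the CN·t_sim/N_ex estimator; R_ex
# near 1.3 says most crossings here persist longer than 0.5 ps.
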