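"""One-command end-to-end hydration analysis with a machine-readable report.

``validate_config`` resolves a hierarchical YAML (or dict) configuration
against documented defaults, rejecting unknown keys; ``run_full_analysis``
executes the full battery — RDF → shell detection → ADF/CND → alignment →
SDF/ARD → occupancy/residence times → VACF/spectrum → PMF/SASA/RMSF/torsions
— writing tabular curves plus a deterministic JSON report (no timestamps, so
reruns with the same config and seed are byte-identical).
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dynamics import NoExchange, residence_stats, shell_occupancy_series, distance_series
from .energetics import compute_rmsf, pmf_from_rdf, time_averaged_sasa, torsion_distribution
from .serialize import write_dx_grid, write_json, write_tsv
from .spatial import compute_ard, compute_sdf, kabsch_align, subtract_first_shell
from .structure import compute_adf, compute_cnd, compute_nh_cnd, compute_rdf, \
    detect_shell_boundaries, integrate_coordination
from .synthetic import (
    ExchangeSpec,
    ShellSpec,
    generate_exchange_trajectory,
    generate_ideal_gas_box,
    generate_porphyrin_scaffold,
    generate_shell_snapshot,
)
from .trajectory_io import assign_roles, read_pdb_topology, read_xyz_trajectory
from .vibrational import compute_vacf, find_spectrum_peaks, power_spectrum

log = logging.getLogger("solvshell")

#: Defaults mirror the standard analysis parameters: dr = 0.05 Å bins, the
#: two persistence thresholds t* = 0.0 and 0.5 ps, a 2.0 ps correlation
#: length with 5000 origins, T = 298.15 K and a 1.4 Å probe.
DEFAULT_CONFIG = {
    "input": {
        "xyz": None,
        "topology": None,
        "dt": 0.002,
        "box": None,
        "synthetic": None,
    },
    "rdf": {"r_max": 8.0, "dr": 0.05, "center": "metal", "target": "water_O"},
    "shells": {"n_shells": 2, "smoothing_window": 5},
    "adf": {"r_cut": 2.67, "bin_width": 2.0},
    "cnd": {"r_cut": 2.67},
    "nh_cnd": {"h_bond_cutoff": 2.5},
    "sdf": {"spacing": 0.5, "extent": 8.0},
    "ard": {"r_max": 8.0, "dr": 0.1, "dtheta": 2.0},
    "mrt": {"t_star": [0.0, 0.5], "shell": 0},
    "vacf": {"correlation_length": 2.0, "n_origins": 5000, "window": "hann",
             "zero_padding_factor": 4},
    "pmf": {"temperature": 298.15},
    "sasa": {"probe_radius": 1.4, "n_points": 960, "stride": 1},
    "torsions": {"bin_width": 5.0, "running_window": 5},
    "seed": 0,
    "output_dir": "solvshell_out",
}


class ConfigError(ValueError):
    """Invalid, unknown, or out-of-range configuration entries."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, cause):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """Fully resolved configuration plus its provenance hash."""

    values: dict
    source: str = "<dict>"

    def __getitem__(self, key):
        return self.values[key]

    @property
    def sha256(self) -> str:
        canon = json.dumps(self.values, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class AnalysisReport:
    """Manifest of written files plus headline summary statistics."""

    manifest: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _merge_defaults(user, defaults, path=""):
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        if key not in defaults:
            raise ConfigError(f"unknown configuration key '{path}{key}'")
        if isinstance(defaults[key], dict) and isinstance(val, dict):
            out[key] = _merge_defaults(val, defaults[key], f"{path}{key}.")
        else:
            out[key] = val
    return out


def _check_ranges(cfg):
    checks = [
        ("rdf.dr", cfg["rdf"]["dr"]), ("rdf.r_max", cfg["rdf"]["r_max"]),
        ("adf.r_cut", cfg["adf"]["r_cut"]), ("adf.bin_width", cfg["adf"]["bin_width"]),
        ("cnd.r_cut", cfg["cnd"]["r_cut"]),
        ("vacf.correlation_length", cfg["vacf"]["correlation_length"]),
        ("pmf.temperature", cfg["pmf"]["temperature"]),
        ("sasa.probe_radius", cfg["sasa"]["probe_radius"]),
        ("input.dt", cfg["input"]["dt"]),
    ]
    for name, v in checks:
        if not (isinstance(v, (int, float)) and v > 0):
            raise ConfigError(f"'{name}' must be a positive number, got {v!r}")
    for ts in cfg["mrt"]["t_star"]:
        if ts < 0:
            raise ConfigError(f"t_star values must be non-negative, got {ts}")


def validate_config(source) -> AnalysisConfig:
    """Load and validate a config from a YAML path or a dict.

    Unknown keys are an error (no silent ignore); defaults are filled in and
    the fully resolved configuration is echoed at INFO level.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
        src = str(source)
    else:
        user = copy.deepcopy(source)
        src = "<dict>"
    if not isinstance(user, dict):
        raise ConfigError("configuration must be a mapping")
    cfg = _merge_defaults(user, DEFAULT_CONFIG)
    _check_ranges(cfg)
    inp = cfg["input"]
    if inp["synthetic"] is None and inp["xyz"] is None:
        raise ConfigError("input requires either 'xyz' (+'topology') or 'synthetic'")
    if inp["xyz"] is not None:
        for key in ("xyz", "topology"):
            if inp[key] is None:
                raise ConfigError(f"input.{key} is required for file input")
            if not Path(inp[key]).exists():
                raise ConfigError(f"input.{key} path does not exist: {inp[key]}")
    resolved = AnalysisConfig(values=cfg, source=src)
    log.info("resolved configuration: %s", json.dumps(cfg, sort_keys=True, default=str))
    return resolved


# ---------------------------------------------------------------------------
# Input loading
# ---------------------------------------------------------------------------

def _load_input(cfg):
    inp = cfg["input"]
    if inp["synthetic"] is not None:
        return _build_synthetic(inp["synthetic"], cfg["seed"], inp["dt"])
    traj = read_xyz_trajectory(inp["xyz"], dt=inp["dt"], box_length=inp["box"])
    topo = read_pdb_topology(inp["topology"])
    topo = assign_roles(topo)
    return traj, topo, None


def _build_synthetic(spec, seed, dt):
    """Construct a generator-backed input; spec: {kind: ..., params...}."""
    spec = dict(spec)
    kind = spec.pop("kind", None)
    if kind == "exchange":
        scaffold = generate_porphyrin_scaffold(spec.pop("metal_N_distance", 2.0))
        shells = ShellSpec(
            shells=[tuple(s) for s in spec.pop("shells", [(1.93, 2.67), (3.27, 5.03)])],
            occupancy=spec.pop("occupancy", [1, 1]),
            jitter=spec.pop("jitter", 0.0),
        )
        ex = ExchangeSpec(
            rate=spec.pop("rate", 0.5), n_ligands=spec.pop("n_ligands", 8),
            duration=spec.pop("duration", 20.0), dt=dt, seed=seed,
        )
        if spec:
            raise ConfigError(f"unknown synthetic keys {sorted(spec)}")
        traj, topo, log_ = generate_exchange_trajectory(scaffold, ex, shells)
        return traj, topo, log_
    if kind == "shell":
        scaffold = generate_porphyrin_scaffold(spec.pop("metal_N_distance", 2.0))
        shells = ShellSpec(
            shells=[tuple(s) for s in spec.pop("shells", [(1.93, 2.67)])],
            occupancy=spec.pop("occupancy", [2]),
            jitter=spec.pop("jitter", 0.0),
        )
        n_frames = spec.pop("n_frames", 100)
        traj, topo = generate_shell_snapshot(
            scaffold, shells, n_bulk=spec.pop("n_bulk", 0),
            box_length=spec.pop("box", None), seed=seed, dt=dt,
        )
        if spec:
            raise ConfigError(f"unknown synthetic keys {sorted(spec)}")
        from .synthetic import repeat_snapshot
        return repeat_snapshot(traj, n_frames), topo, None
    if kind == "gas":
        traj, topo = generate_ideal_gas_box(
            n_atoms=spec.pop("n_atoms", 500), box_length=spec.pop("box", 20.0),
            n_frames=spec.pop("n_frames", 20), seed=seed, dt=dt,
        )
        if spec:
            raise ConfigError(f"unknown synthetic keys {sorted(spec)}")
        return traj, topo, None
    raise ConfigError(f"unknown synthetic input kind {kind!r}")


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_full_analysis(config: AnalysisConfig, output_dir=None) -> AnalysisReport:
    """Execute every analysis stage and write the report.

    Stage failures raise :class:`StageError` after the partial manifest has
    been written, so completed products survive an abort.
    """
    cfg = config.values
    outdir = Path(output_dir or cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    report = AnalysisReport(provenance={
        "config_sha256": config.sha256, "seed": cfg["seed"], "version": __version__,
    })

    def _finish(path=None):
        write_json(outdir / "report.json", {
            "manifest": report.manifest, "summary": report.summary,
            "flags": report.flags, "provenance": report.provenance,
        })

    def _fail(stage, exc):
        _finish()
        raise StageError(stage, exc) from exc

    stage = "input"
    try:
        traj, topo, truth = _load_input(cfg)
    except Exception as exc:  # noqa: BLE001 — any stage failure aborts by contract
        _fail(stage, exc)
    log.info("input: %d frames, %d atoms, dt=%g ps", traj.n_frames, traj.n_atoms,
             traj.dt)

    is_gas = len(topo.indices_with_role("metal")) != 1

    stage = "rdf"
    try:
        c = cfg["rdf"]
        if is_gas:
            centers = topo.indices_with_role("other")[:200]
            rdf = compute_rdf(traj, topo, None, None,
                              r_max=min(c["r_max"], (traj.box_length or 2 * c["r_max"]) / 2),
                              dr=c["dr"], center_indices=centers,
                              target_indices=np.arange(traj.n_atoms))
        else:
            rdf = compute_rdf(traj, topo, c["center"], c["target"], r_max=c["r_max"],
                              dr=c["dr"],
                              rho=None if traj.box_length else 0.03299)
        write_tsv(outdir / "rdf.tsv", ["r_A", "g", "n_of_r"],
                  [rdf.r, rdf.g, rdf.cumulative_cn[1:]])
        report.manifest["rdf"] = "rdf.tsv"
    except Exception as exc:
        _fail(stage, exc)

    stage = "shells"
    partition = None
    try:
        sh = cfg["shells"]
        # Fall back to fewer shells when the profile supports fewer minima
        # (e.g. no bulk solvent beyond the outermost generated shell).
        last_exc = None
        for n_shells in range(sh["n_shells"], 0, -1):
            try:
                partition = detect_shell_boundaries(rdf, sh["smoothing_window"],
                                                    n_shells)
                break
            except ValueError as exc:
                last_exc = exc
        if partition is None:
            raise last_exc
        report.summary["shell_boundaries_A"] = list(partition.boundaries)
        report.summary["shell_zero_minimum"] = list(partition.zero_minimum)
        report.summary["cn_first_shell"] = integrate_coordination(
            rdf, partition.boundaries[0])
        write_json(outdir / "shells.json", {
            "boundaries_A": partition.boundaries,
            "zero_minimum": partition.zero_minimum,
        })
        report.manifest["shells"] = "shells.json"
    except ValueError as exc:
        report.flags.append("no shell structure detected")
        log.info("shell detection: %s", exc)

    if not is_gas:
        stage = "adf"
        try:
            a = cfg["adf"]
            adf = compute_adf(traj, topo, r_cut=a["r_cut"], bin_width=a["bin_width"])
            write_tsv(outdir / "adf.tsv", ["angle_deg", "frequency"],
                      [adf.angles, adf.frequency])
            report.manifest["adf"] = "adf.tsv"
            top2 = adf.angles[np.argsort(adf.frequency)[::-1][:2]]
            report.summary["adf_peak_angles_deg"] = sorted(float(x) for x in top2)
        except Exception as exc:
            _fail(stage, exc)

        stage = "cnd"
        try:
            cnd = compute_cnd(traj, topo, r_cut=cfg["cnd"]["r_cut"])
            write_json(outdir / "cnd.json", {"p": cnd.probabilities})
            report.manifest["cnd"] = "cnd.json"
            report.summary["cnd_mean"] = cnd.mean()
            if topo.indices_with_role("water_H").size:
                nh = compute_nh_cnd(traj, topo, cfg["nh_cnd"]["h_bond_cutoff"])
                write_json(outdir / "nh_cnd.json", {"p": nh.probabilities})
                report.manifest["nh_cnd"] = "nh_cnd.json"
        except Exception as exc:
            _fail(stage, exc)

        stage = "align"
        try:
            aligned = kabsch_align(traj, topo)
        except Exception as exc:
            _fail(stage, exc)

        stage = "sdf"
        try:
            s = cfg["sdf"]
            sdf = compute_sdf(aligned, topo, spacing=s["spacing"], extent=s["extent"])
            write_dx_grid(outdir / "sdf.dx", sdf)
            report.manifest["sdf"] = "sdf.dx"
        except Exception as exc:
            _fail(stage, exc)

        stage = "ard"
        try:
            a = cfg["ard"]
            ard = compute_ard(traj, topo, r_max=a["r_max"], dr=a["dr"],
                              dtheta=a["dtheta"])
            rr, tt = np.meshgrid(0.5 * (ard.r_edges[:-1] + ard.r_edges[1:]),
                                 0.5 * (ard.theta_edges[:-1] + ard.theta_edges[1:]),
                                 indexing="ij")
            write_tsv(outdir / "ard.tsv", ["r_A", "theta_deg", "density"],
                      [rr.ravel(), tt.ravel(), ard.density.ravel()])
            report.manifest["ard"] = "ard.tsv"
            if partition is not None:
                ard2 = subtract_first_shell(ard, partition.boundaries[0])
                write_tsv(outdir / "ard_second_shell.tsv",
                          ["r_A", "theta_deg", "density"],
                          [rr.ravel(), tt.ravel(), ard2.density.ravel()])
                report.manifest["ard_second_shell"] = "ard_second_shell.tsv"
        except Exception as exc:
            _fail(stage, exc)

        if partition is not None:
            stage = "mrt"
            try:
                series = shell_occupancy_series(traj, topo, partition=partition)
                stats = residence_stats(series, cfg["mrt"]["shell"],
                                        tuple(cfg["mrt"]["t_star"]))
                mrt_json = {
                    "CN": stats.cn, "t_sim_ps": stats.t_sim,
                    "N_ex": {str(k): v for k, v in stats.n_ex.items()},
                    "tau_ps": {str(k): (str(v) if isinstance(v, NoExchange) else v)
                               for k, v in stats.tau.items()},
                    "R_ex": stats.r_ex, "sustainability": stats.sustainability,
                }
                write_json(outdir / "mrt.json", mrt_json)
                report.manifest["mrt"] = "mrt.json"
                report.summary["mrt"] = mrt_json
                ds = distance_series(traj, topo, partition=partition)
                cols = [ds.times] + [ds.distances[:, i]
                                     for i in range(ds.distances.shape[1])]
                write_tsv(outdir / "distances.tsv",
                          ["t_ps"] + [f"d{i}_A" for i in range(ds.distances.shape[1])],
                          cols)
                report.manifest["distances"] = "distances.tsv"
            except Exception as exc:
                _fail(stage, exc)

        stage = "vacf"
        try:
            v = cfg["vacf"]
            corr = min(v["correlation_length"], (traj.n_frames - 1) * traj.dt / 2)
            n_lags = int(round(corr / traj.dt)) + 1
            n_orig = min(v["n_origins"], traj.n_frames - n_lags + 1)
            vacf = compute_vacf(traj, topo, selection_roles=None,
                                correlation_length=corr, n_origins=n_orig)
            spec = power_spectrum(vacf, v["zero_padding_factor"], v["window"])
            write_tsv(outdir / "vacf.tsv", ["t_ps", "C"], [vacf.lags, vacf.c])
            write_tsv(outdir / "spectrum.tsv", ["wavenumber_cm-1", "intensity"],
                      [spec.wavenumbers, spec.intensity])
            report.manifest["vacf"] = "vacf.tsv"
            report.manifest["spectrum"] = "spectrum.tsv"
            peaks = find_spectrum_peaks(spec)
            report.summary["spectrum_peaks_cm1"] = [float(p) for p in peaks[:5]]
        except Exception as exc:
            _fail(stage, exc)

    stage = "pmf"
    try:
        pmf = pmf_from_rdf(rdf, cfg["pmf"]["temperature"])
        write_tsv(outdir / "pmf.tsv", ["r_A", "w_kJ_mol"], [pmf.r, pmf.w])
        report.manifest["pmf"] = "pmf.tsv"
        if partition is not None:
            wells = pmf.wells(partition)
            report.summary["pmf_wells"] = [
                {"r_A": w[0], "depth_kJ_mol": w[1]} if w else None for w in wells
            ]
    except Exception as exc:
        _fail(stage, exc)

    if not is_gas:
        stage = "sasa"
        try:
            s = cfg["sasa"]
            sasa = time_averaged_sasa(traj, topo, stride=s["stride"],
                                      probe_radius=s["probe_radius"],
                                      n_points=s["n_points"])
            sasa_json = {"hydrophobic_nm2": sasa.hydrophobic,
                         "hydrophilic_nm2": sasa.hydrophilic,
                         "total_nm2": sasa.total}
            write_json(outdir / "sasa.json", sasa_json)
            report.manifest["sasa"] = "sasa.json"
            report.summary["sasa"] = sasa_json
        except Exception as exc:
            _fail(stage, exc)

        stage = "rmsf"
        try:
            rmsf = compute_rmsf(aligned, topo)
            write_tsv(outdir / "rmsf.tsv", ["atom_id", "rmsf_A"],
                      [rmsf.atom_ids, rmsf.rmsf])
            report.manifest["rmsf"] = "rmsf.tsv"
            report.summary["rmsf_mean_A"] = float(np.mean(rmsf.rmsf))
        except Exception as exc:
            _fail(stage, exc)

        stage = "torsions"
        try:
            t = cfg["torsions"]
            quads = (topo.torsion_quadruples.get("proper", []) +
                     topo.torsion_quadruples.get("improper", []))
            if quads:
                td = torsion_distribution(traj, quads, bin_width=t["bin_width"],
                                          running_window=t["running_window"])
                write_tsv(outdir / "torsions.tsv",
                          ["angle_deg", "average", "running_average"],
                          [td.angles, td.average, td.running_average])
                report.manifest["torsions"] = "torsions.tsv"
                mean_angle = float(np.sum(td.angles * td.average))
                report.summary["torsion_mean_deg"] = mean_angle
        except Exception as exc:
            _fail(stage, exc)

    _finish()
    report.manifest["report"] = "report.json"
    # Re-write including the report's own manifest entry, still deterministic.
    _finish()
    return report
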