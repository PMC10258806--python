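"""Velocity autocorrelation functions and vibrational power spectra.

C(t) is averaged over evenly spaced time origins and over the selected atoms
(hydrogens excluded by default, mirroring constrained-H simulations), then
cosine-transformed against a wavenumber grid in cm⁻¹. When a trajectory
carries no velocities they are derived by central finite differences with
minimum-image handling across periodic boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import SPEED_OF_LIGHT_CM_PER_PS
from .trajectory_io import Topology, Trajectory, minimum_image_displacement


@dataclass
class VACF:
    """Normalized velocity autocorrelation, C(0) = 1."""

    lags: np.ndarray          # ps
    c: np.ndarray
    n_origins: int
    selection: dict

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0]) if self.lags.size > 1 else 0.0

    @property
    def correlation_length(self) -> float:
        return float(self.lags[-1])


@dataclass
class PowerSpectrum:
    """One-sided cosine-transform intensity against wavenumber (cm⁻¹).

    Intensity is the real part of the transform clipped at zero; ``resolution``
    is the honest figure 1/(2·c·correlation_length), independent of any zero
    padding applied for peak readability.
    """

    wavenumbers: np.ndarray
    intensity: np.ndarray
    resolution: float
    window: str

    def peak_wavenumber(self, nu_min=0.0) -> float:
        mask = self.wavenumbers >= nu_min
        return float(self.wavenumbers[mask][np.argmax(self.intensity[mask])])


def velocities_from_positions(traj: Trajectory) -> np.ndarray:
    """Central-difference velocities (Å/ps), one-sided at the endpoints.

    Frame-to-frame displacements are minimum-imaged first, so a particle
    crossing a periodic boundary produces a continuous velocity rather than a
    box-length spike.
    """
    if traj.n_frames < 3:
        raise ValueError("need at least 3 frames for finite-difference velocities")
    x = traj.coordinates
    step = minimum_image_displacement(x[:-1], x[1:], traj.box_length)  # (F-1, N, 3)
    v = np.empty_like(x)
    v[1:-1] = (step[1:] + step[:-1]) / (2.0 * traj.dt)
    v[0] = step[0] / traj.dt
    v[-1] = step[-1] / traj.dt
    return v


def compute_vacf(traj: Trajectory, topology: Topology | None = None,
                 selection_roles=None, correlation_length=2.0, n_origins=5000,
                 exclude_hydrogens=True) -> VACF:
    """Velocity autocorrelation over evenly spaced origins.

    ``C(t) = ⟨Σ_j v_j(t_i)·v_j(t_i + t)⟩ / C(0)`` with the sum over the
    selected atoms and the average over ``n_origins`` origins t_i. Velocities
    are taken from the trajectory or derived from positions. The selection is
    by roles when a topology is given, otherwise all atoms; hydrogens are
    dropped by default.
    """
    v = traj.velocities if traj.velocities is not None \
        else velocities_from_positions(traj)
    sel = np.arange(traj.n_atoms)
    if topology is not None and selection_roles is not None:
        sel = topology.indices_with_role(selection_roles)
    if exclude_hydrogens and traj.elements is not None:
        non_h = np.array([i for i in sel
                          if not str(traj.elements[i]).upper().startswith("H")],
                         dtype=int)
        if non_h.size:
            sel = non_h
    if sel.size == 0:
        raise ValueError("empty atom selection for VACF")

    n_lags = int(round(correlation_length / traj.dt)) + 1
    if n_lags > traj.n_frames:
        raise ValueError("correlation length exceeds the trajectory")
    n_avail = traj.n_frames - n_lags + 1
    if n_origins > n_avail:
        raise ValueError(
            f"requested {n_origins} origins but only {n_avail} fit; "
            f"reduce n_origins or the correlation length"
        )
    spacing = n_avail // n_origins
    origins = np.arange(n_origins) * spacing

    vs = v[:, sel, :].reshape(traj.n_frames, -1)
    v0 = vs[origins]
    raw = np.empty(n_lags)
    for lag in range(n_lags):
        raw[lag] = np.sum(v0 * vs[origins + lag]) / n_origins
    if raw[0] == 0:
        raise ValueError("zero kinetic energy in the selection; VACF undefined")
    return VACF(lags=np.arange(n_lags) * traj.dt, c=raw / raw[0],
                n_origins=n_origins,
                selection={"atoms": [int(i) for i in sel],
                           "exclude_hydrogens": bool(exclude_hydrogens)})


_WINDOWS = {
    "none": lambda n: np.ones(n),
    "hann": lambda n: 0.5 * (1.0 + np.cos(np.pi * np.arange(n) / (n - 1))),
    "blackman": lambda n: np.blackman(2 * n - 1)[n - 1:],
}


def power_spectrum(vacf: VACF, zero_padding_factor=4,
                   window="hann") -> PowerSpectrum:
    """Cosine transform of C(t) against wavenumber ν̃ = f/c (cm⁻¹).

    A one-sided taper (default Hann) is applied over the lag range; zero
    padding (default ×4) refines peak positions without changing the true
    resolution, which is reported from the correlation length.
    """
    c = np.asarray(vacf.c, dtype=float)
    if c.size == 0:
        raise ValueError("empty VACF")
    try:
        w = _WINDOWS[window](c.size)
    except KeyError:
        raise ValueError(f"unknown window {window!r}; choose from {sorted(_WINDOWS)}")
    dt = vacf.dt
    n_pad = int(c.size * max(1, zero_padding_factor))
    spec = np.fft.rfft(c * w, n=n_pad).real
    intensity = np.clip(spec, 0.0, None)
    freqs = np.fft.rfftfreq(n_pad, d=dt)                   # cycles/ps
    wavenumbers = freqs / SPEED_OF_LIGHT_CM_PER_PS          # cm⁻¹
    res = 1.0 / (2.0 * SPEED_OF_LIGHT_CM_PER_PS * vacf.correlation_length)
    return PowerSpectrum(wavenumbers=wavenumbers, intensity=intensity,
                         resolution=res, window=window)


def find_spectrum_peaks(spectrum: PowerSpectrum, prominence_fraction=0.05):
    """Wavenumbers of local intensity maxima above a prominence threshold."""
    from scipy.signal import find_peaks

    prom = prominence_fraction * float(spectrum.intensity.max())
    idx, _ = find_peaks(spectrum.intensity, prominence=prom)
    return spectrum.wavenumbers[idx]
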