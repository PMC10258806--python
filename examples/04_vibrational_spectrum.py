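"""Vibrational power spectrum from the velocity autocorrelation function.

Two superposed harmonic modes at 300 and 1000 cm⁻¹ are propagated analytically;
the VACF is accumulated over 2.0 ps with evenly spaced origins and cosine-
transformed. Both bands should reappear at their input wavenumbers.
"""

import solvshell as sv

dt = 0.0005  # ps
traj = sv.generate_oscillator_trajectory([300.0, 1000.0], dt=dt,
                                         n_frames=int(2.0 / dt) + 1200,
                                         amplitude=0.05)
vacf = sv.compute_vacf(traj, correlation_length=2.0, n_origins=1000)
spec = sv.power_spectrum(vacf, window="hann")
peaks = sv.find_spectrum_peaks(spec, prominence_fraction=0.05)

print(f"spectral resolution: {spec.resolution:.1f} cm⁻¹ "
      f"(correlation length {vacf.correlation_length:.1f} ps)")
print("recovered bands:", ", ".join(f"{p:.0f} cm⁻¹" for p in peaks))
# Peak positions land within one resolution element of 300 and 1000 cm⁻¹;
# the Hann window trades a little width for clean sidelobe suppression.
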