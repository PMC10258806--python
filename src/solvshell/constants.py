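"""Physical constants and reference data in the package's working units.

Working units throughout: lengths in Å, times in ps, angles in degrees,
wavenumbers in cm⁻¹, energies in kJ/mol, surface areas in nm², masses in amu,
temperatures in K.
"""

#: Speed of light in cm/ps (converts wavenumbers in cm⁻¹ to cycle frequencies in 1/ps).
SPEED_OF_LIGHT_CM_PER_PS = 2.99792458e-2

#: Universal gas constant in J·K⁻¹·mol⁻¹ (used for the potential of mean force).
GAS_CONSTANT = 8.314

#: Boltzmann constant in amu·Å²·ps⁻²·K⁻¹ (thermal velocities in Å/ps).
BOLTZMANN_AMU_A2_PS2 = 0.831446261815324

#: Bondi van der Waals radii in Å. Co is not in Bondi's set; 2.00 Å is the
#: conventional transition-metal placeholder used here.
BONDI_VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "MG": 1.73,
    "NA": 2.27,
    "K": 2.75,
    "FE": 2.00,
    "CO": 2.00,
    "NI": 1.63,
    "CU": 1.40,
    "ZN": 1.39,
    "MN": 2.00,
    "AR": 1.88,
}

#: Atomic masses in amu for the elements this package routinely encounters.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "MG": 24.305,
    "FE": 55.845,
    "CO": 58.933,
    "NI": 58.693,
    "CU": 63.546,
    "ZN": 65.38,
    "MN": 54.938,
    "AR": 39.948,
}
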