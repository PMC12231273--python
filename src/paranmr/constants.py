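"""Physical constants (CODATA 2018) and unit conversions.

Internal unit system is Hartree atomic units: energies in hartree, magnetic
flux density in a.u. of field (1 a.u. = hbar/(e*a0^2) ~ 2.35e5 T), lengths in
bohr, magnetic moments in a.u. (Bohr magneton = 1/2).  All public interfaces
use practical units (cm^-1, MHz, angstrom, tesla, kelvin, ppm); conversion is
confined to this module.
"""

from __future__ import annotations

import math

# --- CODATA 2018 defining/measured values (SI) ---
HARTREE_J = 4.3597447222071e-18          # hartree in joule
BOLTZMANN_J_PER_K = 1.380649e-23         # exact (SI 2019)
FINE_STRUCTURE = 7.2973525693e-3         # alpha
BOHR_RADIUS_M = 5.29177210903e-11        # a0 in metre
HBAR_JS = 1.054571817e-34                # exact-derived
E_CHARGE_C = 1.602176634e-19             # exact
GAMMA_PROTON_SI = 2.6752218744e8         # rad s^-1 T^-1 (shielded-free proton)

# --- derived conversion factors ---
HARTREE_PER_CM1 = 1.0 / 219474.6313632          # cm^-1 -> hartree
CM1_PER_HARTREE = 219474.6313632
HARTREE_HZ = 6.579683920502e15                  # hartree in Hz
HZ_PER_HARTREE = HARTREE_HZ
MHZ_PER_HARTREE = HARTREE_HZ * 1e-6

KBOLTZ_AU = BOLTZMANN_J_PER_K / HARTREE_J       # hartree / kelvin

# a.u. of magnetic flux density: hbar / (e * a0^2)
TESLA_PER_AU_B = HBAR_JS / (E_CHARGE_C * BOHR_RADIUS_M**2)   # ~2.3505e5 T
AU_B_PER_TESLA = 1.0 / TESLA_PER_AU_B

# a.u. of time
TIME_AU_S = HBAR_JS / HARTREE_J

# gyromagnetic ratio: rad s^-1 T^-1  ->  a.u. (moment per hbar per a.u. field)
GAMMA_SI_TO_AU = TESLA_PER_AU_B * TIME_AU_S

BOHR_PER_ANGSTROM = 1e-10 / BOHR_RADIUS_M
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

MU_BOHR_AU = 0.5                                 # Bohr magneton in a.u.
MU0_AU = 4.0 * math.pi * FINE_STRUCTURE**2       # vacuum permeability in a.u.

# volume conversion for susceptibility output (per-molecule chi)
M3_PER_AU_VOL = BOHR_RADIUS_M**3
CM3_MOL_PER_M3 = 1e6 * 6.02214076e23             # m^3/molecule -> cm^3/mol

# proton Larmor: MHz per tesla
PROTON_MHZ_PER_T = GAMMA_PROTON_SI / (2.0 * math.pi) * 1e-6   # ~42.577

#: built-in nuclear gyromagnetic ratios, rad s^-1 T^-1
GAMMA_SI_BY_ISOTOPE = {
    "1H": 2.6752218744e8,
    "13C": 6.728284e7,
    "15N": -2.7126e7,
    "19F": 2.518148e8,
    "31P": 1.08394e8,
}


def cm1_to_au(x):
    return x * HARTREE_PER_CM1


def au_to_cm1(x):
    return x * CM1_PER_HARTREE


def mhz_to_au(x):
    """Frequency-style energy in MHz -> hartree."""
    return x * 1e6 / HARTREE_HZ


def au_to_mhz(x):
    return x * HARTREE_HZ * 1e-6


def tesla_to_au(x):
    return x * AU_B_PER_TESLA


def au_to_tesla(x):
    return x * TESLA_PER_AU_B


def angstrom_to_au(x):
    return x * BOHR_PER_ANGSTROM


def gamma_si_to_au(x):
    return x * GAMMA_SI_TO_AU


def larmor_to_field(nu_mhz: float) -> float:
    """Magnetic flux density (tesla) of a magnet with the given 1H Larmor
    frequency in MHz.  The proton gyromagnetic ratio labels the magnet
    regardless of the observed nucleus (a "400 MHz spectrometer").
    """
    if nu_mhz < 0:
        raise ValueError(f"Larmor frequency must be >= 0, got {nu_mhz}")
    return nu_mhz / PROTON_MHZ_PER_T


def field_to_larmor(b0_tesla: float) -> float:
    """Inverse of :func:`larmor_to_field` (tesla -> 1H MHz)."""
    return b0_tesla * PROTON_MHZ_PER_T
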