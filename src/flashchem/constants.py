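"""Physical constants and unit conversions.

Internal unit conventions used throughout the package:

* length: nm
* time:   ns  (simulation clock; seconds at the API surface where noted)
* diffusion coefficient: nm^2/ns  (numerically equal to 1e-9 m^2/s)
* energy: keV for bookkeeping, eV for G-value arithmetic
* rate constants: M^-1 s^-1 (bimolecular), s^-1 (first order)
* concentration: mol/L
* yield (G value): molecules per 100 eV of absorbed energy
"""

AVOGADRO = 6.02214076e23  # 1/mol

#: MeV, atomic mass unit rest energy (used for per-nucleon kinematics)
AMU_MEV = 931.494

#: keV, electron rest energy
ELECTRON_MC2_KEV = 511.0

#: Conventional radiation-chemistry conversion: 1 molecule/100 eV in umol/J.
#: This is the constant used for all G <-> concentration conversions.
G_UMOL_PER_J = 0.103364

#: nm, Onsager escape radius in liquid water at 25 C (e^2/(4 pi eps0 eps_r kT))
ONSAGER_RADIUS_NM = 0.714

#: g/cm^3, density of the medium (liquid water, 25 C)
WATER_DENSITY = 1.0

#: Gy per (keV / um^3) in unit-density water:
#: 1 keV = 1.602176634e-16 J; 1 um^3 water = 1e-12 g = 1e-15 kg
#: => 1 keV/um^3 = 1.602176634e-16 / 1e-15 J/kg = 0.1602176634 Gy
GY_PER_KEV_UM3 = 0.1602176634

#: Conversion from a bimolecular rate constant k (M^-1 s^-1) and a summed
#: diffusion coefficient D' (nm^2/ns) to the Smoluchowski encounter radius (nm):
#: R = k / (4 pi D' N_A), with k converted to nm^3/ns:
#: k [M^-1 s^-1] = k * 1e24 / (N_A) [nm^3 / (molecule s)] = k * 1e15/N_A nm^3/ns
K_TO_NM3_PER_NS = 1.0e15 / AVOGADRO

PS = 1e-3  # ns
US = 1e3   # ns
S = 1e9    # ns


def smoluchowski_radius_nm(k: float, d_sum_nm2_ns: float) -> float:
    """Encounter radius (nm) for a fully diffusion-controlled reaction.

    R = k / (4 pi D' N_A) with consistent units.
    """
    import math

    if d_sum_nm2_ns <= 0:
        raise ValueError("summed diffusion coefficient must be positive")
    return k * K_TO_NM3_PER_NS / (4.0 * math.pi * d_sum_nm2_ns)


def smoluchowski_rate(radius_nm: float, d_sum_nm2_ns: float) -> float:
    """Forward Smoluchowski formula: k (M^-1 s^-1) from radius and D'."""
    import math

    return 4.0 * math.pi * d_sum_nm2_ns * radius_nm / K_TO_NM3_PER_NS
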