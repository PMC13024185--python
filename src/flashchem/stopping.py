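"""Approximate stopping-power and electron-range lookups.

The chemistry pipeline takes LET as an *input*; these tables exist only to
(a) pick a physically consistent energy per nucleon for an ion at a requested
LET (which sets the delta-ray kinematics) and (b) bound the radial extent of
the delta-ray penumbra.  Values are interpolated log-log from standard
water-stopping compilations and are approximate at the few-percent level,
which is ample for track-structure sampling.
"""

from __future__ import annotations

import math

import numpy as np

# Proton electronic stopping power in liquid water, keV/um (~MeV cm^2/g),
# descending branch plus relativistic minimum.  (E in MeV.)
_PROTON_E_MEV = np.array(
    [0.10, 0.15, 0.20, 0.30, 0.50, 0.70, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0,
     15.0, 20.0, 30.0, 50.0, 70.0, 100.0, 150.0, 200.0, 300.0, 500.0,
     1000.0, 2000.0]
)
_PROTON_LET_KEV_UM = np.array(
    [80.0, 71.0, 63.0, 52.0, 42.0, 34.5, 27.0, 16.2, 12.3, 8.1, 6.0, 4.56,
     3.27, 2.61, 1.88, 1.25, 0.97, 0.73, 0.55, 0.44, 0.30, 0.24,
     0.22, 0.21]
)

# Electron CSDA-style range in liquid water, um (T in keV).  Sub-keV entries
# are effective penetration depths rather than true CSDA values.
_ELECTRON_T_KEV = np.array(
    [0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0, 10000.0]
)
_ELECTRON_RANGE_UM = np.array(
    [0.005, 0.010, 0.020, 0.05, 0.15, 0.7, 2.5, 18.0, 143.0, 840.0,
     4400.0, 15000.0, 50000.0]
)


def proton_let(energy_mev: float) -> float:
    """Proton LET in water (keV/um) on the descending branch, log-log interp."""
    e = float(np.clip(energy_mev, _PROTON_E_MEV[0], _PROTON_E_MEV[-1]))
    return float(
        np.exp(np.interp(np.log(e), np.log(_PROTON_E_MEV), np.log(_PROTON_LET_KEV_UM)))
    )


def beta_from_energy(energy_per_nucleon_mev: float) -> float:
    from .constants import AMU_MEV

    gamma = 1.0 + energy_per_nucleon_mev / AMU_MEV
    return math.sqrt(max(0.0, 1.0 - 1.0 / gamma**2))


def effective_charge(z: int, beta: float) -> float:
    """Barkas effective charge; ~Z except at low velocity."""
    if beta <= 0:
        return 0.0
    return z * (1.0 - math.exp(-125.0 * beta / z ** (2.0 / 3.0)))


def ion_let(z: int, energy_per_nucleon_mev: float) -> float:
    """Ion LET (keV/um) via effective-charge scaling of the proton table."""
    beta = beta_from_energy(energy_per_nucleon_mev)
    return effective_charge(z, beta) ** 2 * proton_let(energy_per_nucleon_mev)


def energy_for_let(z: int, let_kev_um: float) -> float:
    """Energy per nucleon (MeV/u) at which the ion has the requested LET.

    Solves on the descending (fast) branch of the stopping curve by bisection.
    """
    lo, hi = _PROTON_E_MEV[1], _PROTON_E_MEV[-1]
    f_lo, f_hi = ion_let(z, lo) - let_kev_um, ion_let(z, hi) - let_kev_um
    if f_lo < 0:
        return float(lo)
    if f_hi > 0:
        return float(hi)
    for _ in range(80):
        mid = math.sqrt(lo * hi)
        if ion_let(z, mid) > let_kev_um:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def electron_range_nm(t_kev: float) -> float:
    """Penetration depth (nm) of an electron of kinetic energy T (keV)."""
    t = float(np.clip(t_kev, _ELECTRON_T_KEV[0], _ELECTRON_T_KEV[-1]))
    um = np.exp(np.interp(np.log(t), np.log(_ELECTRON_T_KEV), np.log(_ELECTRON_RANGE_UM)))
    return float(um) * 1e3
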