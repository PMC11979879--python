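"""Shared physical relations: water viscosity and Stokes-Einstein diffusion.

Units follow instrument conventions throughout the package: temperatures in
degrees Celsius, viscosity in centipoise (= mPa s), diffusion coefficients in
cm^2/s, hydrodynamic radii in nm.
"""

from __future__ import annotations

import math

BOLTZMANN_J_K = 1.380649e-23

# Vogel-Fulcher-Tammann parameters for pure water (mPa s, K, K); smooth and
# accurate between 0 and 40 degC.
_VOGEL_A_MPAS = 0.02939
_VOGEL_B_K = 507.88
_VOGEL_T0_K = 149.3


def water_viscosity_cp(temp_c: float) -> float:
    """Viscosity of pure water in cP at ``temp_c`` (Vogel closed form)."""
    t_k = temp_c + 273.15
    return _VOGEL_A_MPAS * math.exp(_VOGEL_B_K / (t_k - _VOGEL_T0_K))


def stokes_einstein_d(rh_nm: float, temp_c: float) -> float:
    """Diffusion coefficient (cm^2/s) of a sphere of radius ``rh_nm`` in water.

    D = kT / (6 pi eta Rh), with water viscosity from the Vogel form.
    """
    if rh_nm <= 0:
        raise ValueError("hydrodynamic radius must be positive")
    eta_pa_s = water_viscosity_cp(temp_c) * 1e-3
    r_m = rh_nm * 1e-9
    d_m2_s = BOLTZMANN_J_K * (temp_c + 273.15) / (6.0 * math.pi * eta_pa_s * r_m)
    return d_m2_s * 1e4


def d0_at_temperature(d0_ref: float, temp_c: float, ref_temp_c: float = 20.0) -> float:
    """Translate an infinite-dilution D from ``ref_temp_c`` to ``temp_c``.

    Stokes-Einstein scaling at constant radius: D proportional to T/eta(T).
    """
    t_k = temp_c + 273.15
    t_ref_k = ref_temp_c + 273.15
    return d0_ref * (t_k / t_ref_k) * (
        water_viscosity_cp(ref_temp_c) / water_viscosity_cp(temp_c)
    )
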