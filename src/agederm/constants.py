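"""Physical constants and model defaults used across the package.

Every constant here may be overridden through the run configuration
(:mod:`agederm.io_cli`) or through function keyword arguments; nothing
downstream hard-codes these numbers.
"""

from __future__ import annotations

#: Speed of light in vacuum, m s^-1.
SPEED_OF_LIGHT = 299_792_458.0

#: Vacuum permittivity, F m^-1.
VACUUM_PERMITTIVITY = 8.8541878128e-12

#: Free-space wave impedance eta_0, ohm.
FREE_SPACE_IMPEDANCE = 376.730313668

#: Blood mass density rho_b, kg m^-3.
BLOOD_DENSITY = 1050.0

#: Blood specific heat capacity C_b, J kg^-1 degC^-1.
BLOOD_HEAT_CAPACITY = 3617.0

#: Convective heat-transfer coefficient between air and skin, W m^-2 degC^-1.
#: Printed sources sometimes list W m^-1 C^-1, which is dimensionally
#: impossible for a surface-exchange coefficient; the value is a standard
#: still-air convective coefficient.
HEAT_TRANSFER_COEFFICIENT = 7.0

#: Ambient air temperature, degC.
T_AIR = 20.0

#: Arterial blood temperature, degC.
T_BLOOD = 37.0

#: Adult reference age (years) at which the hydration rate equals the adult
#: value alpha_A, i.e. where the age model reproduces the tabulated adult
#: permittivities exactly.  Mid-adult plateau of the hydration curves.
ADULT_REFERENCE_AGE = 35.0

#: Real permittivity of free water per frequency (Hz), from a single-Debye
#: pure-water model at 25 degC (eps_s = 78.36, eps_inf = 5.16,
#: tau = 8.27 ps).  Used as eps'_W in the Lichtenecker hydration mixing law.
WATER_EPS_REAL = {
    26e9: 31.1,
    60e9: 12.0,
}

#: Dermal blood-flow regression coefficients (forearm skin, resting
#: conditions): BF_D(age) = BF_INTERCEPT - age * BF_SLOPE, in s^-1.
BLOOD_FLOW_INTERCEPT = 6.033e-4
BLOOD_FLOW_SLOPE = 3.55e-6

#: ICNIRP / IEEE local-exposure incident power density limits above 6 GHz:
#: limit = coefficient * f_GHz ** ICNIRP_EXPONENT, W m^-2.
ICNIRP_EXPONENT = -0.177
ICNIRP_COEFF_GENERAL = 55.0
ICNIRP_COEFF_OCCUPATIONAL = 275.0
ICNIRP_FREQ_RANGE_GHZ = (6.0, 300.0)
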