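"""Physical constants used throughout the energy-balance accounting.

Values are SI unless noted. Tunable defaults (e.g. dry-soil heat capacity)
are function arguments in the modules that use them; only fixed physical
constants live here.
"""

#: Solar constant (W m-2), total solar irradiance at 1 AU.
SOLAR_CONSTANT = 1361.0

#: Stefan-Boltzmann constant (W m-2 K-4).
STEFAN_BOLTZMANN = 5.670374419e-8

#: Specific heat of air at constant pressure (J kg-1 K-1).
CP_AIR = 1004.0

#: Specific gas constant of dry air (J kg-1 K-1).
R_DRY = 287.04

#: Universal gas constant (J mol-1 K-1).
R_GAS = 8.314462618

#: Volumetric heat capacity of liquid water (J m-3 K-1).
C_WATER_VOL = 4.18e6

#: Default volumetric heat capacity of dry soil matrix (J m-3 K-1).
C_SOIL_DRY_DEFAULT = 1.2e6

#: Latent heat of vaporization of water (J kg-1), default constant value.
LAMBDA_VAP = 2.45e6

#: Molar mass of water (kg mol-1).
M_WATER = 0.018

#: Molar mass of CO2 (kg mol-1).
M_CO2 = 0.044

#: Specific biochemical energy of photosynthetic CO2 fixation (J per kg CO2).
MU_PHOTOSYNTHESIS = 10.88e6

#: Specific heat capacity of fresh biomass (wood + leaves) (J kg-1 K-1).
C_BIOMASS = 2958.0

#: Dry-to-fresh biomass conversion factor (fresh = factor * dry).
DRY_TO_FRESH = 2.0

#: Seconds in one half-hourly averaging interval.
HALF_HOUR_S = 1800.0

#: On-disk missing-value sentinel (FLUXNET convention).
MISSING_SENTINEL = -9999.0
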