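"""Physical constants used throughout the package.

All values are CODATA 2018.  ``h``, ``c`` and ``k_B`` are exact in the
2019 SI redefinition; they are written out here (rather than pulled from
:mod:`scipy.constants` at import time) so that the radiometric kernel is
pinned to one immutable table.
"""

#: Planck constant, J s (exact).
PLANCK_H = 6.62607015e-34

#: Speed of light in vacuum, m/s (exact).
SPEED_OF_LIGHT = 299792458.0

#: Boltzmann constant, J/K (exact).
BOLTZMANN_K = 1.380649e-23

#: Wien displacement-law constant b, m K (CODATA 2018).
WIEN_B = 2.897771955e-3

#: Fixed reference spectral radiance per kelvin^4, W m^-3 K^-4.
#:
#: Illumination matrices are expressed as dimensionless multiples of this
#: constant.  Its magnitude is chosen so that, for the default visible-range
#: geometry, simulated imaging signals are of order one and the 1/SNR
#: regularization-weight rule is well scaled.  Any fixed value would leave
#: the physics unchanged (the forward model and the reconstruction share
#: the same matrix); only the meaning of the printed weights depends on it.
REFERENCE_RADIANCE_PER_K4 = 2.0e-8
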