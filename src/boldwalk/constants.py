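"""Physical constants and unit conventions.

Internal units throughout the package: lengths in micrometres (um), times in
milliseconds (ms), magnetic fields in Tesla, angles in radians, diffusivities
in um^2/ms.  The static field B0 points along the +z axis.
"""

import numpy as np

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_PROTON: float = 2.675222e8

#: Unit vector of the static field B0 (lab frame z axis).
B0_DIRECTION = np.array([0.0, 0.0, 1.0])

#: Conversion factor: gamma [rad/s/T] * B [T] * dt [ms] -> phase [rad].
MS_TO_S: float = 1e-3
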