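"""Physical constants and unit conversions.

All energies are wavenumbers (cm^-1), distances Angstrom, times femtoseconds,
transition dipoles Debye.  This module is the single source of truth for the
conversion factors; nothing else in the package hard-codes them.
"""

from __future__ import annotations

from typing import Final

#: Q_y transition energy of monomeric BChl c in methanol (cm^-1).
OMEGA0_CM: Final[float] = 15390.0

#: Q_y transition dipole magnitude of BChl c (Debye).
DIPOLE_DEBYE: Final[float] = 5.48

#: Point-dipole coupling prefactor, 1/(4 pi eps0) in cm^-1 * Angstrom^3 / Debye^2.
DIPOLE_PREFACTOR: Final[float] = 5034.12

#: Speed of light in cm/fs.
C_CM_PER_FS: Final[float] = 2.99792458e-5

#: Phase accumulated per (cm^-1 * fs): phi = 2 pi c E t  [rad].
PHASE_PER_CM_FS: Final[float] = 2.0 * 3.141592653589793 * C_CM_PER_FS  # 1.88365e-4

#: Hamiltonian trajectory time step (fs); nuclear motion is frozen within a step.
DT_FS: Final[float] = 4.0
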