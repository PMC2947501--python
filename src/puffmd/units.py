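"""Internal unit system and the conversions the pulling protocol relies on.

Everything inside the package is expressed in Å (length), ps (time),
Da (mass) and K (temperature).  Forces only become pN at the analysis
boundary.  Two constants tie the system together:

``FORCE_PN_PER_DA_ACCEL``
    1 Da·Å/ps² expressed in pN.  This is also the factor that turns a
    pulling mass in Da into the ``pN·ps²/Å`` mass used by the
    momentum-to-force bookkeeping (e.g. 262 Da ≈ 43.5, printed as 44).

``BOLTZMANN``
    k_B in Da·Å²/(ps²·K), used by the kinetic-temperature estimator and
    the Langevin thermostat.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateDofError, InvalidArgumentError

__all__ = [
    "FORCE_PN_PER_DA_ACCEL",
    "BOLTZMANN",
    "mass_to_force_units",
    "kinetic_temperature",
]

# 1 Da·Å/ps² = 1.66053906660e-27 kg * 1e-10 m / (1e-12 s)^2 = 1.66053906660e-13 N
FORCE_PN_PER_DA_ACCEL: float = 0.166_053_906_660

# k_B = 1.380649e-23 J/K over 1.66053906660e-23 J per Da·Å²/ps²
BOLTZMANN: float = 0.831_446_261_815


def mass_to_force_units(mass_da: float) -> float:
    """Convert a pulling mass in Da to pN·ps²/Å.

    Linear; rounding for display is the caller's concern
    (``round(mass_to_force_units(262))`` → 44).

    Raises
    ------
    InvalidArgumentError
        If ``mass_da`` is negative.
    """
    if mass_da < 0:
        raise InvalidArgumentError(f"mass must be non-negative, got {mass_da}")
    return mass_da * FORCE_PN_PER_DA_ACCEL


def kinetic_temperature(
    velocities: np.ndarray,
    masses: np.ndarray,
    remove_com: bool = True,
) -> float:
    """Instantaneous kinetic temperature of a set of particles, in K.

    T = Σ mᵢ|vᵢ|² / (k_B · n_dof) with n_dof = 3N−3 when ``remove_com``
    is set (the mass-weighted centre-of-mass velocity is subtracted
    before summing, so injected drift is not counted as heat), else 3N.

    Parameters
    ----------
    velocities : (N, 3) array, Å/ps
    masses : (N,) array, Da
    remove_com : subtract COM translation and use 3N−3 degrees of freedom.
    """
    velocities = np.asarray(velocities, dtype=float)
    masses = np.asarray(masses, dtype=float)
    n = masses.shape[0]
    if velocities.shape != (n, 3):
        raise InvalidArgumentError(
            f"velocities must have shape ({n}, 3), got {velocities.shape}"
        )
    if np.any(masses <= 0):
        raise InvalidArgumentError("masses must be strictly positive")
    if remove_com:
        if n < 2:
            raise DegenerateDofError(
                "kinetic temperature with COM removal needs at least 2 particles"
            )
        com_v = masses @ velocities / masses.sum()
        velocities = velocities - com_v
        n_dof = 3 * n - 3
    else:
        if n < 1:
            raise InvalidArgumentError("need at least one particle")
        n_dof = 3 * n
    twice_ke = float(np.sum(masses * np.sum(velocities * velocities, axis=1)))
    return twice_ke / (BOLTZMANN * n_dof)
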