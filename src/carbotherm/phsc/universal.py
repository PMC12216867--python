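"""Universal temperature functions of the perturbed hard-sphere-chain EoS.

The attraction and covolume parameters are

    a_ij(T) = (2 pi / 3) sigma_ij^3 eps_ij F_a(kT/eps_ij)
    b_ij(T) = (2 pi / 3) sigma_ij^3       F_b(kT/eps_ij)

with F_a and F_b universal functions of the reduced temperature fitted once to
argon/methane data in the original PHSC formulation (Song, Lambert &
Prausnitz); the coefficients below are that published parameterization.  The
effective hard-sphere diameter follows from the covolume, d^3 = sigma^3 F_b,
so F_b is also the cube of the temperature-dependent diameter ratio.
"""

from __future__ import annotations

import numpy as np

# Song-Lambert-Prausnitz universal-function fit coefficients.
_A1, _A2, _A3, _A4 = 1.8681, -0.0619, 0.6715, -1.7317
_B1, _B2, _B3, _B4 = 0.7303, -0.1649, 0.2697, -2.3973


def f_attraction(t_reduced):
    """F_a(kT/eps); dimensionless, positive, decreasing in T."""
    t = np.asarray(t_reduced, dtype=float)
    if np.any(t <= 0):
        raise ValueError("reduced temperature must be positive")
    return _A1 * np.exp(_A2 * t) + _A3 * np.exp(_A4 * t ** 1.5)


def f_covolume(t_reduced):
    """F_b(kT/eps) = (d/sigma)^3; in (0, 1], decreasing in T."""
    t = np.asarray(t_reduced, dtype=float)
    if np.any(t <= 0):
        raise ValueError("reduced temperature must be positive")
    return _B1 * np.exp(_B2 * np.sqrt(t)) + _B3 * np.exp(_B4 * t ** 1.5)
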