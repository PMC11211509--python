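"""Nonlinear viscoelastic ligament constitutive law for PF and PL.

Tension follows the exponential collagen model

    F(lam, lam_dot) = A lam^2 (k / 2 alpha) {exp[alpha (lam^2 - 1)] - 1}
                      x (1 + d lam_dot)

for lam >= 1 with a positive damping factor; otherwise the ligament is slack
and carries no force.  ``lam = l / l0`` is the strain ratio and ``lam_dot`` its
time derivative (1/s).  The damping condition ``d * lam_dot > -1`` caps the
relaxation rate: a ligament shortening faster than its maximum relaxation
velocity goes slack instead of pushing.
"""

from __future__ import annotations

import math

import numpy as np

from .params import LigamentParams


def ligament_force(lam: float, lam_dot: float, params: LigamentParams) -> float:
    """Tensile force (N) of a ligament at strain ratio ``lam``.

    Parameters are converted to SI (A in m^2, k in Pa) so the returned value
    is in newtons.  The force is tension-only and never negative.
    """
    if not (math.isfinite(lam) and math.isfinite(lam_dot)):
        raise ValueError("non-finite ligament strain state")
    if lam < 1.0:
        return 0.0
    damp = 1.0 + params.d * lam_dot
    if damp <= 0.0:
        return 0.0
    A = params.area
    k = params.k
    a = params.alpha
    elastic = A * lam * lam * (k / (2.0 * a)) * (math.exp(a * (lam * lam - 1.0)) - 1.0)
    return elastic * damp


def ligament_force_array(lam, lam_dot, params: LigamentParams):
    """Vectorized :func:`ligament_force` for trajectory post-processing."""
    lam = np.asarray(lam, dtype=float)
    lam_dot = np.asarray(lam_dot, dtype=float)
    A, k, a, d = params.area, params.k, params.alpha, params.d
    elastic = A * lam**2 * (k / (2 * a)) * (np.exp(a * (lam**2 - 1.0)) - 1.0)
    out = elastic * (1.0 + d * lam_dot)
    out = np.where((lam >= 1.0) & (1.0 + d * lam_dot > 0.0), out, 0.0)
    return out
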