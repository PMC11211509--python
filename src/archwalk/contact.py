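"""Circular rolling ground-contact elements.

Vertical force is a Hunt-Crossley viscoelastic law,

    F_v = -k_y dy (1 - v_y / v_max)   for dy <= 0 and v_y < v_max, else 0,

where ``dy`` is the penetration depth of the deepest point of the circle
(negative in contact) and ``v_y`` its upward-positive vertical velocity.
Horizontal force uses a continuous velocity-based friction curve,

    F_h = F_v (mu_d tanh(4 vbar) + (mu_s - mu_d) vbar / (vbar^2/4 + 3/4)^2),

``vbar = v_x / v_t``.  The curve is odd and continuous in the slip velocity;
it is applied as a reaction opposing the foot's sliding direction so contact
friction always dissipates energy.

The point of action is the lowest point of the circle; as the element rotates
the point of action rolls along the circumference, so for a rolling element
the material slip velocity at the contact (``v_center_x + omega * R``)
vanishes and no friction force is produced.
"""

from __future__ import annotations

import math

import numpy as np

from .params import ContactParams


def contact_point(center_xy, radius: float, ground_height: float = 0.0):
    """Deepest point of a circular element and its penetration depth.

    Returns ``(point, dy)`` with ``point = center - (0, R)`` and
    ``dy = point_y - ground``; ``dy > 0`` means no contact.  A zero-radius
    element degenerates to a point contact at its center.
    """
    if radius < 0:
        raise ValueError("contact radius must be >= 0")
    cx, cy = float(center_xy[0]), float(center_xy[1])
    point = (cx, cy - radius)
    return point, point[1] - ground_height


def vertical_force(dy: float, v_y: float, params: ContactParams) -> float:
    """Hunt-Crossley vertical contact force (N, >= 0).

    ``v_y`` is the upward-positive vertical velocity of the point of action;
    when it exceeds the maximum relaxation speed the force releases to zero.
    """
    if dy > 0.0:
        return 0.0
    vbar = v_y / params.v_max
    if vbar >= 1.0:
        return 0.0
    return -params.k_y * dy * (1.0 - vbar)


def friction_factor(v_x: float, params: ContactParams) -> float:
    """Dimensionless friction curve mu(v_x); odd, continuous, -> mu_d."""
    vbar = v_x / params.v_t
    return params.mu_d * math.tanh(4.0 * vbar) + (params.mu_s - params.mu_d) * (
        vbar / (0.25 * vbar * vbar + 0.75) ** 2
    )


def horizontal_force(F_v: float, v_x: float, params: ContactParams) -> float:
    """Friction force magnitude-with-sign per the continuous friction model.

    The returned value carries the sign of ``v_x``; the reaction applied to
    the foot is its negative (opposing sliding).
    """
    if F_v < 0:
        raise ValueError("vertical force must be >= 0")
    return F_v * friction_factor(v_x, params)


def center_of_pressure(forces, points_x, heel_x: float = 0.0) -> float:
    """Force-weighted mean x-position of the active contact points.

    Reported relative to ``heel_x`` (the heel position at touch-down in the
    gait-analysis convention).  Raises if no element carries load.
    """
    f = np.asarray(forces, dtype=float)
    x = np.asarray(points_x, dtype=float)
    tot = f.sum()
    if tot <= 0.0:
        raise ValueError("center of pressure undefined: no vertical load")
    return float((f * x).sum() / tot - heel_x)


def cop_series(forces, points_x, heel_x: float = 0.0):
    """CoP time series; samples without load are NaN (flagged, not interpolated)."""
    f = np.asarray(forces, dtype=float)
    x = np.asarray(points_x, dtype=float)
    tot = f.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cop = (f * x).sum(axis=-1) / tot - heel_x
    return np.where(tot > 0.0, cop, np.nan)
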