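"""Interface force laws: shoulder contact, tip suspension, hand control.

Sign conventions: forces are those acting *on the pole* at the shoulder
(``contact_force``), *on a load* from its suspension (``suspension_force``),
and the vertical hand force on the pole (``hand_control_force``).  ``hs`` is
negative under compression, so the vertical contact force ``-(khs*hs + ...)``
is positive (supporting) at equilibrium.
"""

from __future__ import annotations

import math
from typing import NamedTuple

from ..errors import RopeConfigurationError
from .params import ContactParams, ControlParams


class ForcePair(NamedTuple):
    """A planar force, +x forward, +y up (N)."""

    fx: float
    fy: float


def contact_force(
    hs: float,
    hs_dot: float,
    ds: float,
    ds_dot: float,
    theta: float,
    contact: ContactParams,
    projection: str = "as_printed",
) -> ForcePair:
    """Shoulder contact force on the pole.

    The default ``"as_printed"`` projection is::

        Fx = kds*ds + cds*ds_dot + (khs*hs + chs*hs_dot) * sin(theta) * cos(theta)
        Fy = -(khs*hs + chs*hs_dot)

    ``"tangential"`` is an alternative for sensitivity studies that carries
    the tangential spring force along the pole axis instead:
    ``F = (kds*ds + cds*ds_dot) * (cos, sin) + (0, -(khs*hs + chs*hs_dot))``.
    """
    ev = contact.khs * hs + contact.chs * hs_dot
    et = contact.kds * ds + contact.cds * ds_dot
    if projection == "as_printed":
        return ForcePair(et + ev * math.sin(theta) * math.cos(theta), -ev)
    if projection == "tangential":
        return ForcePair(et * math.cos(theta), et * math.sin(theta) - ev)
    raise ValueError(f"unknown contact projection {projection!r}")


def suspension_force(h: float, h_dot: float, alpha: float, k: float, c: float) -> ForcePair:
    """Force on a load from its tip spring and rope.

    Vertical component ``k*h + c*h_dot`` (spring tension), horizontal
    component ``-(k*h + c*h_dot)*tan(alpha)`` from the rope inclination.
    Undefined at ``|alpha| >= pi/2``.
    """
    if abs(alpha) >= math.pi / 2:
        raise RopeConfigurationError(
            f"rope angle {alpha:.4f} rad is at or beyond 90 deg; force law undefined"
        )
    e = k * h + c * h_dot
    return ForcePair(-e * math.tan(alpha), e)


def hand_control_force(theta: float, theta_dot: float, control: ControlParams | None) -> float:
    """PD balance force ``-Kp*theta - Kd*theta_dot`` (N), 0 when disabled."""
    if control is None or not control.enabled:
        return 0.0
    return -control.Kp * theta - control.Kd * theta_dot
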