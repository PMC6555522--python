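"""Planar kinematics of the pole, loads and interface points.

All positions are expressed in the sagittal plane, +x forward, +y up.
With the shoulder at ``p_o = (xo, yo)`` and full coordinate vector
``(hs, ds, theta, h1, alpha1, h2, alpha2)``:

* pole center      ``p_p = p_o + (-ds*cos(th), hs - ds*sin(th))``
* rear load        ``p_1 = p_p + (-Lp1*cos(th) + Lr1*sin(a1), -Lp1*sin(th) - Lr1*cos(a1) - h1)``
* front load       ``p_2 = p_p + ( Lp2*cos(th) + Lr2*sin(a2),  Lp2*sin(th) - Lr2*cos(a2) - h2)``
* contact point    ``p_s = p_o + (0, hs)``
* hand point       ``p_h = p_p + Dh*(cos(th), sin(th))``

Coordinates that a variant lacks are held at zero, which collapses these
expressions to the reduced geometry (e.g. a load sits at the tip when
``Lr = 0`` and ``h = 0``).
"""

from __future__ import annotations

import math

import numpy as np

from .params import PoleParams

#: canonical full coordinate ordering shared by every variant
FULL_COORDS = ("hs", "ds", "theta", "h1", "alpha1", "h2", "alpha2")


def positions(qf, pole: PoleParams, Dh: float = 0.3, shoulder=(0.0, 0.0)) -> dict[str, np.ndarray]:
    """Points of interest for one full-coordinate state.

    Returns a dict with keys ``pp, p1, p2, ps, ph``, each a length-2 array.
    """
    hs, ds, th, h1, a1, h2, a2 = qf
    xo, yo = shoulder
    c, s = math.cos(th), math.sin(th)
    pp = np.array([xo - ds * c, yo + hs - ds * s])
    p1 = pp + np.array([-pole.Lp1 * c + pole.Lr1 * math.sin(a1),
                        -pole.Lp1 * s - pole.Lr1 * math.cos(a1) - h1])
    p2 = pp + np.array([pole.Lp2 * c + pole.Lr2 * math.sin(a2),
                        pole.Lp2 * s - pole.Lr2 * math.cos(a2) - h2])
    ps = np.array([xo, yo + hs])
    ph = pp + Dh * np.array([c, s])
    return {"pp": pp, "p1": p1, "p2": p2, "ps": ps, "ph": ph}


def velocities(qf, qdf, pole: PoleParams, shoulder_vel=(0.0, 0.0)):
    """Velocities of the pole center and both loads.

    Hand-differentiated once from :func:`positions`; the dynamics assembler
    and the residual oracle both lean on this, so it is cross-checked against
    finite differences of :func:`positions` in the test suite.
    """
    hs, ds, th, h1, a1, h2, a2 = qf
    hsd, dsd, thd, h1d, a1d, h2d, a2d = qdf
    vxo, vyo = shoulder_vel
    c, s = math.cos(th), math.sin(th)
    vpp = np.array([vxo - dsd * c + ds * s * thd,
                    vyo + hsd - dsd * s - ds * c * thd])
    v1 = vpp + np.array([pole.Lp1 * s * thd + pole.Lr1 * math.cos(a1) * a1d,
                         -pole.Lp1 * c * thd + pole.Lr1 * math.sin(a1) * a1d - h1d])
    v2 = vpp + np.array([-pole.Lp2 * s * thd + pole.Lr2 * math.cos(a2) * a2d,
                         pole.Lp2 * c * thd + pole.Lr2 * math.sin(a2) * a2d - h2d])
    return vpp, v1, v2


def jacobians(qf, pole: PoleParams):
    """Position Jacobians ``d p / d q`` (2x7) of pole center and loads."""
    _, ds, th, _, a1, _, a2 = qf
    c, s = math.cos(th), math.sin(th)
    Jp = np.zeros((2, 7))
    Jp[1, 0] = 1.0
    Jp[0, 1] = -c
    Jp[1, 1] = -s
    Jp[0, 2] = ds * s
    Jp[1, 2] = -ds * c
    J1 = Jp.copy()
    J1[0, 2] += pole.Lp1 * s
    J1[1, 2] -= pole.Lp1 * c
    J1[1, 3] = -1.0
    J1[0, 4] = pole.Lr1 * math.cos(a1)
    J1[1, 4] = pole.Lr1 * math.sin(a1)
    J2 = Jp.copy()
    J2[0, 2] -= pole.Lp2 * s
    J2[1, 2] += pole.Lp2 * c
    J2[1, 5] = -1.0
    J2[0, 6] = pole.Lr2 * math.cos(a2)
    J2[1, 6] = pole.Lr2 * math.sin(a2)
    return Jp, J1, J2


def gammas(qf, qdf, pole: PoleParams):
    """Velocity-product acceleration remainders: ``p_ddot = J @ q_ddot + gamma + p_o_ddot``."""
    _, ds, th, _, a1, _, a2 = qf
    _, dsd, thd, _, a1d, _, a2d = qdf
    c, s = math.cos(th), math.sin(th)
    gp = np.array([2.0 * dsd * thd * s + ds * thd * thd * c,
                   -2.0 * dsd * thd * c + ds * thd * thd * s])
    g1 = gp + np.array([pole.Lp1 * c * thd * thd - pole.Lr1 * math.sin(a1) * a1d * a1d,
                        pole.Lp1 * s * thd * thd + pole.Lr1 * math.cos(a1) * a1d * a1d])
    g2 = gp + np.array([-pole.Lp2 * c * thd * thd - pole.Lr2 * math.sin(a2) * a2d * a2d,
                        -pole.Lp2 * s * thd * thd + pole.Lr2 * math.cos(a2) * a2d * a2d])
    return gp, g1, g2


def positions_series(QF: np.ndarray, pole: PoleParams, Dh: float, shoulder: np.ndarray):
    """Vectorized :func:`positions` over a trajectory.

    Parameters
    ----------
    QF : ndarray, shape (n, 7)
        Full coordinate vectors per sample.
    shoulder : ndarray, shape (n, 2)
        Shoulder positions per sample.

    Returns
    -------
    dict of ndarray, shape (n, 2)
    """
    hs, ds, th = QF[:, 0], QF[:, 1], QF[:, 2]
    h1, a1, h2, a2 = QF[:, 3], QF[:, 4], QF[:, 5], QF[:, 6]
    c, s = np.cos(th), np.sin(th)
    pp = np.column_stack([shoulder[:, 0] - ds * c, shoulder[:, 1] + hs - ds * s])
    p1 = pp + np.column_stack([-pole.Lp1 * c + pole.Lr1 * np.sin(a1),
                               -pole.Lp1 * s - pole.Lr1 * np.cos(a1) - h1])
    p2 = pp + np.column_stack([pole.Lp2 * c + pole.Lr2 * np.sin(a2),
                               pole.Lp2 * s - pole.Lr2 * np.cos(a2) - h2])
    ps = np.column_stack([shoulder[:, 0], shoulder[:, 1] + hs])
    ph = pp + Dh * np.column_stack([c, s])
    return {"pp": pp, "p1": p1, "p2": p2, "ps": ps, "ph": ph}
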