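"""Per-variant assembly and solution of the instantaneous equations of motion.

At every state the Newton-Euler balances of the two loads and the pole are
written as a linear system ``A @ u = b`` in the unknown vector ``u`` holding
the active coordinate accelerations plus, for reduced variants, the
constraint-force components that the removed springs/ropes no longer supply:

==========  =========================  ==============================
variant     coordinates                constraint-force unknowns
==========  =========================  ==============================
``NSNR``    hs, ds, theta              F1x, F1y, F2x, F2y (rigid ties)
``WSNR``    hs, ds, theta, h1, h2      F1x, F2x (horizontal ties)
``NSWR``    hs, ds, theta, a1, a2      T1, T2 (rope tensions, vertical comp.)
``WSWR``    all seven                  none
==========  =========================  ==============================

Every variant therefore yields a 7x7 system matching the seven balance
equations (load linear momenta, pole linear momentum, pole angular
momentum).  Torques on the pole use the reaction forces ``-F1, -F2`` at the
load attachment line together with ``+Fs`` at the contact point and the hand
force at its lever arm; this is the sign set under which the rigid pole's
effective pitch inertia is the parallel-axis sum ``I0 + m1*Lp1^2 + m2*Lp2^2``.

An independent residual oracle re-evaluates the balances with accelerations
obtained by finite differencing the analytic velocity map, giving a second
route that never touches the assembled matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..errors import (
    NumericalSingularityError,
    RopeConfigurationError,
    VariantMismatchError,
)
from . import geometry as kin
from .forces import contact_force, hand_control_force, suspension_force
from .params import (
    GRAVITY,
    ContactParams,
    ControlParams,
    LoadParams,
    PoleParams,
    Variant,
)

#: indices of each variant's active coordinates within the full ordering
_ACTIVE = {
    Variant.NSNR: (0, 1, 2),
    Variant.WSNR: (0, 1, 2, 3, 5),
    Variant.NSWR: (0, 1, 2, 4, 6),
    Variant.WSWR: (0, 1, 2, 3, 4, 5, 6),
}

#: labels of the constraint-force unknowns appended after the accelerations
_FORCE_UNKNOWNS = {
    Variant.NSNR: ("F1x", "F1y", "F2x", "F2y"),
    Variant.WSNR: ("F1x", "F2x"),
    Variant.NSWR: ("T1", "T2"),
    Variant.WSWR: (),
}


class SystemState:
    """Generalized coordinates and rates of one variant.

    Coordinates: ``hs`` (vertical contact deformation, m), ``ds`` (tangential
    offset of the pole center behind the contact point, m), ``theta`` (pitch,
    rad, + = front end up), ``h1/h2`` (tip spring extensions, m), ``alpha1/
    alpha2`` (rope angles from vertical, rad).  Rates use a ``_dot`` suffix.
    Only the coordinates active for ``variant`` may be set.
    """

    def __init__(self, variant: Variant | str, **values: float):
        self._variant = Variant(variant)
        names = self._variant.coords
        q = np.zeros(len(names))
        qd = np.zeros(len(names))
        index = {n: i for i, n in enumerate(names)}
        for key, val in values.items():
            base, is_rate = (key[:-4], True) if key.endswith("_dot") else (key, False)
            if base not in index:
                if base in kin.FULL_COORDS:
                    raise VariantMismatchError(
                        f"coordinate {base!r} is not active for variant {self._variant.value}"
                    )
                raise TypeError(f"unknown coordinate {key!r}")
            (qd if is_rate else q)[index[base]] = float(val)
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(qd))):
            raise ValueError("state values must be finite")
        self._q = q
        self._qd = qd
        self._index = index

    @classmethod
    def from_vectors(cls, variant: Variant | str, q, qd) -> "SystemState":
        variant = Variant(variant)
        names = variant.coords
        q = np.asarray(q, dtype=float)
        qd = np.asarray(qd, dtype=float)
        if q.shape != (len(names),) or qd.shape != (len(names),):
            raise VariantMismatchError(
                f"variant {variant.value} expects {len(names)} coordinates, "
                f"got shapes {q.shape} and {qd.shape}"
            )
        state = cls(variant)
        state._q = q.copy()
        state._qd = qd.copy()
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(qd))):
            raise ValueError("state values must be finite")
        return state

    @property
    def variant(self) -> Variant:
        return self._variant

    @property
    def coords(self) -> tuple[str, ...]:
        return self._variant.coords

    @property
    def q(self) -> np.ndarray:
        return self._q.copy()

    @property
    def qd(self) -> np.ndarray:
        return self._qd.copy()

    def __getattr__(self, name: str):
        index = object.__getattribute__(self, "_index")
        if name.endswith("_dot") and name[:-4] in index:
            return self._qd[index[name[:-4]]]
        if name in index:
            return self._q[index[name]]
        raise AttributeError(name)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        parts = [f"{n}={v:.6g}" for n, v in zip(self.coords, self._q)]
        return f"SystemState({self._variant.value}, {', '.join(parts)})"


@dataclass
class AssembledSystem:
    """The instantaneous linear system ``matrix @ u = rhs``.

    ``unknowns`` labels each entry of ``u``: coordinate names map to
    accelerations, the remaining labels to constraint forces.
    """

    matrix: np.ndarray
    rhs: np.ndarray
    unknowns: tuple[str, ...]
    n_coords: int
    cond_threshold: float = 1e12

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def solve(self) -> np.ndarray:
        if not (np.all(np.isfinite(self.matrix)) and np.all(np.isfinite(self.rhs))):
            raise NumericalSingularityError("non-finite entries in the assembled system")
        try:
            u = np.linalg.solve(self.matrix, self.rhs)
        except np.linalg.LinAlgError as exc:
            raise NumericalSingularityError(f"singular dynamics matrix: {exc}") from exc
        cond = self.condition_number
        if cond > self.cond_threshold:
            raise NumericalSingularityError(
                f"dynamics matrix condition number {cond:.3e} exceeds {self.cond_threshold:.1e}"
            )
        return u


def _cross(rx: float, ry: float, fx: float, fy: float) -> float:
    return rx * fy - ry * fx


class PoleLoadModel:
    """Closed dynamics of one pole variant, driven by shoulder acceleration.

    Parameters
    ----------
    pole, loads, contact : parameter blocks.
    control : ControlParams or None
        PD hand control; ``None`` or ``enabled=False`` leaves ``Fh = 0``.
    include_pole_weight : bool
        The pole momentum balance omits the pole's own weight by default
        (reproducing the reference behavior); set True to add ``-m0*g``.
    contact_projection : str
        ``"as_printed"`` (default) or ``"tangential"``, see
        :func:`polecarry.model_core.forces.contact_force`.
    """

    def __init__(
        self,
        pole: PoleParams,
        loads: LoadParams,
        contact: ContactParams,
        control: ControlParams | None = None,
        include_pole_weight: bool = False,
        contact_projection: str = "as_printed",
    ):
        self.pole = pole
        self.loads = loads
        self.contact = contact
        self.control = control
        self.include_pole_weight = bool(include_pole_weight)
        self.contact_projection = contact_projection
        self.variant = pole.variant
        self._active = _ACTIVE[self.variant]
        self._force_labels = _FORCE_UNKNOWNS[self.variant]
        self.coords = self.variant.coords
        self.n_coords = len(self._active)

    # -- basic helpers -----------------------------------------------------

    @property
    def Dh(self) -> float:
        return self.control.Dh if self.control is not None else 0.3

    @property
    def total_mass(self) -> float:
        return self.pole.m0 + self.loads.m1 + self.loads.m2

    @property
    def is_stiff(self) -> bool:
        """True when any finite stiffness reaches 1e5 N/m (stiff integrator)."""
        candidates = [self.contact.kds, self.contact.khs]
        for k in (self.pole.k1, self.pole.k2):
            if math.isfinite(k):
                candidates.append(k)
        return max(candidates) >= 1e5

    def expand(self, vec) -> np.ndarray:
        """Active coordinate vector -> full 7-vector (inactive entries 0)."""
        full = np.zeros(7)
        full[list(self._active)] = vec
        return full

    def state(self, q, qd) -> SystemState:
        return SystemState.from_vectors(self.variant, q, qd)

    def hand_force(self, theta: float, theta_dot: float) -> float:
        return hand_control_force(theta, theta_dot, self.control)

    # -- assembly ----------------------------------------------------------

    def _known_suspension(self, qf, qdf):
        """Known parts of F1, F2 plus guard on rope angles."""
        p = self.pole
        a1, a2 = qf[4], qf[6]
        if self.variant.has_rope and (abs(a1) >= math.pi / 2 or abs(a2) >= math.pi / 2):
            raise RopeConfigurationError(
                f"rope angle at or beyond 90 deg (alpha1={a1:.3f}, alpha2={a2:.3f} rad)"
            )
        if self.variant is Variant.WSWR:
            e1 = p.k1 * qf[3] + p.c1 * qdf[3]
            e2 = p.k2 * qf[5] + p.c2 * qdf[5]
            return (-e1 * math.tan(a1), e1), (-e2 * math.tan(a2), e2)
        if self.variant is Variant.WSNR:
            return (0.0, p.k1 * qf[3] + p.c1 * qdf[3]), (0.0, p.k2 * qf[5] + p.c2 * qdf[5])
        return (0.0, 0.0), (0.0, 0.0)

    def _build(self, q, qd, shoulder_accel=(0.0, 0.0), Fh: float = 0.0):
        """Assemble ``A, b`` and return them with geometry scratch values."""
        p, lo, co = self.pole, self.loads, self.contact
        qf = self.expand(q)
        qdf = self.expand(qd)
        hs, ds, th, h1, a1, h2, a2 = qf
        axo, ayo = shoulder_accel
        c, s = math.cos(th), math.sin(th)

        Jp, J1, J2 = kin.jacobians(qf, p)
        idx = list(self._active)
        Jp, J1, J2 = Jp[:, idx], J1[:, idx], J2[:, idx]
        gp, g1, g2 = kin.gammas(qf, qdf, p)

        r1 = (-p.Lp1 * c + p.Lr1 * math.sin(a1), -p.Lp1 * s - p.Lr1 * math.cos(a1) - h1)
        r2 = (p.Lp2 * c + p.Lr2 * math.sin(a2), p.Lp2 * s - p.Lr2 * math.cos(a2) - h2)
        rs = (ds * c, ds * s)

        Fs = contact_force(hs, qdf[0], ds, qdf[1], th, co, self.contact_projection)
        F1k, F2k = self._known_suspension(qf, qdf)

        nq = self.n_coords
        A = np.zeros((7, 7))
        b = np.zeros(7)
        m1, m2, m0 = lo.m1, lo.m2, p.m0

        A[0, :nq] = m1 * J1[0]
        A[1, :nq] = m1 * J1[1]
        A[2, :nq] = m2 * J2[0]
        A[3, :nq] = m2 * J2[1]
        A[4, :nq] = m0 * Jp[0]
        A[5, :nq] = m0 * Jp[1]
        A[6, 2] = p.I0

        b[0] = F1k[0] - m1 * (g1[0] + axo)
        b[1] = F1k[1] - m1 * GRAVITY - m1 * (g1[1] + ayo)
        b[2] = F2k[0] - m2 * (g2[0] + axo)
        b[3] = F2k[1] - m2 * GRAVITY - m2 * (g2[1] + ayo)
        b[4] = Fs[0] - F1k[0] - F2k[0] - m0 * (gp[0] + axo)
        b[5] = Fs[1] - F1k[1] - F2k[1] + Fh - m0 * (gp[1] + ayo)
        if self.include_pole_weight:
            b[5] -= m0 * GRAVITY
        b[6] = (
            _cross(*rs, *Fs)
            + Fh * self.Dh * c
            - _cross(*r1, *F1k)
            - _cross(*r2, *F2k)
        )

        # constraint-force columns (coefficients on the LHS)
        v = self.variant
        if v is Variant.NSNR:
            A[0, 3] = -1.0
            A[1, 4] = -1.0
            A[2, 5] = -1.0
            A[3, 6] = -1.0
            A[4, 3] = 1.0
            A[4, 5] = 1.0
            A[5, 4] = 1.0
            A[5, 6] = 1.0
            A[6, 3] = -r1[1]
            A[6, 4] = r1[0]
            A[6, 5] = -r2[1]
            A[6, 6] = r2[0]
        elif v is Variant.WSNR:
            A[0, 5] = -1.0
            A[2, 6] = -1.0
            A[4, 5] = 1.0
            A[4, 6] = 1.0
            A[6, 5] = -r1[1]
            A[6, 6] = -r2[1]
        elif v is Variant.NSWR:
            t1, t2 = math.tan(a1), math.tan(a2)
            A[0, 5] = t1
            A[1, 5] = -1.0
            A[2, 6] = t2
            A[3, 6] = -1.0
            A[4, 5] = -t1
            A[5, 5] = 1.0
            A[4, 6] = -t2
            A[5, 6] = 1.0
            A[6, 5] = r1[0] + r1[1] * t1
            A[6, 6] = r2[0] + r2[1] * t2
        return A, b

    def assemble(self, q, qd, shoulder_accel=(0.0, 0.0), Fh: float = 0.0) -> AssembledSystem:
        """Public assembly with labeled unknowns and a conditioning check."""
        A, b = self._build(np.asarray(q, float), np.asarray(qd, float), shoulder_accel, Fh)
        return AssembledSystem(
            matrix=A,
            rhs=b,
            unknowns=tuple(self.coords) + self._force_labels,
            n_coords=self.n_coords,
        )

    def accelerations(self, q, qd, shoulder_accel=(0.0, 0.0), Fh: float | None = None):
        """Solve for coordinate accelerations and constraint forces.

        ``Fh=None`` applies the PD control law; pass an explicit value to
        override (e.g. 0 for uncontrolled studies).

        Returns ``(qdd, forces)`` with ``forces`` a dict keyed by the
        variant's constraint-force labels.
        """
        q = np.asarray(q, float)
        qd = np.asarray(qd, float)
        if Fh is None:
            Fh = self.hand_force(q[2], qd[2])
        u = self.assemble(q, qd, shoulder_accel, Fh).solve()
        nq = self.n_coords
        return u[:nq], dict(zip(self._force_labels, u[nq:]))

    def rhs(self, t: float, y: np.ndarray, shoulder_accel_fn) -> np.ndarray:
        """ODE right-hand side over ``y = [q, qd]`` (fast path, no labels)."""
        nq = self.n_coords
        q, qd = y[:nq], y[nq:]
        Fh = self.hand_force(q[2], qd[2])
        A, b = self._build(q, qd, shoulder_accel_fn(t), Fh)
        try:
            u = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise NumericalSingularityError(
                f"singular dynamics matrix at t={t:.6f}, q={q!r}"
            ) from exc
        out = np.empty(2 * nq)
        out[:nq] = qd
        out[nq:] = u[:nq]
        return out

    # -- equilibrium, diagnostics, energy ---------------------------------

    def static_equilibrium(self):
        """Rest state ``(q0, qd0)`` with the pole level and the springs loaded.

        ``hs`` balances the carried weight on the vertical contact spring;
        tip springs stretch by ``m_i*g/k_i``.  Exact when the static moments
        about the support balance (``m1*Lp1 == m2*Lp2``).
        """
        lo = self.loads
        m_supported = lo.m1 + lo.m2 + (self.pole.m0 if self.include_pole_weight else 0.0)
        q0 = np.zeros(self.n_coords)
        q0[0] = -m_supported * GRAVITY / self.contact.khs
        if self.variant.has_spring:
            names = self.coords
            if self.pole.k1 > 0:
                q0[names.index("h1")] = lo.m1 * GRAVITY / self.pole.k1
            if self.pole.k2 > 0:
                q0[names.index("h2")] = lo.m2 * GRAVITY / self.pole.k2
        return q0, np.zeros(self.n_coords)

    def point_accelerations(self, q, qd, qdd, shoulder_accel=(0.0, 0.0)):
        """Cartesian accelerations of pole center and loads via the Jacobian map."""
        qf = self.expand(q)
        qdf = self.expand(qd)
        Jp, J1, J2 = kin.jacobians(qf, self.pole)
        idx = list(self._active)
        gp, g1, g2 = kin.gammas(qf, qdf, self.pole)
        po_dd = np.asarray(shoulder_accel, float)
        qdd = np.asarray(qdd, float)
        return (
            Jp[:, idx] @ qdd + gp + po_dd,
            J1[:, idx] @ qdd + g1 + po_dd,
            J2[:, idx] @ qdd + g2 + po_dd,
        )

    def residuals(
        self,
        q,
        qd,
        qdd,
        forces: dict[str, float] | None = None,
        shoulder_accel=(0.0, 0.0),
        Fh: float | None = None,
        eps: float = 1e-6,
    ) -> np.ndarray:
        """Momentum-balance residuals for a solved acceleration (oracle route).

        Cartesian accelerations are recomputed by central finite differences
        of the analytic velocity map advanced along ``(qd, qdd)``, never via
        the assembled Jacobians, and substituted back into the seven balance
        equations.  Order: load-1 x/y, load-2 x/y, pole x/y, pole torque.
        """
        p, lo = self.pole, self.loads
        q = np.asarray(q, float)
        qd = np.asarray(qd, float)
        qdd = np.asarray(qdd, float)
        forces = forces or {}
        if Fh is None:
            Fh = self.hand_force(q[2], qd[2])

        def vel(sign):
            qf = self.expand(q + sign * eps * qd)
            qdf = self.expand(qd + sign * eps * qdd)
            return kin.velocities(qf, qdf, p)

        vp_p, v1_p, v2_p = vel(+1.0)
        vp_m, v1_m, v2_m = vel(-1.0)
        po_dd = np.asarray(shoulder_accel, float)
        app = (vp_p - vp_m) / (2 * eps) + po_dd
        a1dd = (v1_p - v1_m) / (2 * eps) + po_dd
        a2dd = (v2_p - v2_m) / (2 * eps) + po_dd

        qf = self.expand(q)
        qdf = self.expand(qd)
        hs, ds, th, h1, a1, h2, a2 = qf
        Fs = contact_force(hs, qdf[0], ds, qdf[1], th, self.contact, self.contact_projection)
        v = self.variant
        if v is Variant.WSWR:
            F1 = suspension_force(h1, qdf[3], a1, p.k1, p.c1)
            F2 = suspension_force(h2, qdf[5], a2, p.k2, p.c2)
        elif v is Variant.WSNR:
            F1 = (forces["F1x"], p.k1 * h1 + p.c1 * qdf[3])
            F2 = (forces["F2x"], p.k2 * h2 + p.c2 * qdf[5])
        elif v is Variant.NSWR:
            F1 = (-forces["T1"] * math.tan(a1), forces["T1"])
            F2 = (-forces["T2"] * math.tan(a2), forces["T2"])
        else:
            F1 = (forces["F1x"], forces["F1y"])
            F2 = (forces["F2x"], forces["F2y"])

        g_vec = np.array([0.0, -GRAVITY])
        res = np.empty(7)
        res[0:2] = np.asarray(F1) + lo.m1 * g_vec - lo.m1 * a1dd
        res[2:4] = np.asarray(F2) + lo.m2 * g_vec - lo.m2 * a2dd
        res[4:6] = np.asarray(Fs) - np.asarray(F1) - np.asarray(F2) + [0.0, Fh] - p.m0 * app
        if self.include_pole_weight:
            res[5] -= p.m0 * GRAVITY
        c = math.cos(th)
        r1 = (-p.Lp1 * c + p.Lr1 * math.sin(a1), -p.Lp1 * math.sin(th) - p.Lr1 * math.cos(a1) - h1)
        r2 = (p.Lp2 * c + p.Lr2 * math.sin(a2), p.Lp2 * math.sin(th) - p.Lr2 * math.cos(a2) - h2)
        rs = (ds * c, ds * math.sin(th))
        res[6] = (
            -_cross(*r1, *F1)
            - _cross(*r2, *F2)
            + _cross(*rs, *Fs)
            + Fh * self.Dh * c
            - p.I0 * qdd[2]
        )
        return res

    def energy(self, q, qd, shoulder_pos=(0.0, 0.0), shoulder_vel=(0.0, 0.0)):
        """Mechanical energy bookkeeping for the active variant.

        Gravitational potential covers the loads (and the pole only when
        ``include_pole_weight`` is set, mirroring the momentum balance);
        elastic terms cover the contact springs and, for springy variants,
        the tip springs.  Returns a dict with ``kinetic, gravitational,
        elastic, total``.
        """
        p, lo, co = self.pole, self.loads, self.contact
        qf = self.expand(np.asarray(q, float))
        qdf = self.expand(np.asarray(qd, float))
        pos = kin.positions(qf, p, self.Dh, shoulder_pos)
        vpp, v1, v2 = kin.velocities(qf, qdf, p, shoulder_vel)
        ke = 0.5 * (
            p.m0 * float(vpp @ vpp)
            + p.I0 * qdf[2] ** 2
            + lo.m1 * float(v1 @ v1)
            + lo.m2 * float(v2 @ v2)
        )
        pe = GRAVITY * (lo.m1 * pos["p1"][1] + lo.m2 * pos["p2"][1])
        if self.include_pole_weight:
            pe += GRAVITY * p.m0 * pos["pp"][1]
        el = 0.5 * (co.khs * qf[0] ** 2 + co.kds * qf[1] ** 2)
        if self.variant.has_spring:
            el += 0.5 * (p.k1 * qf[3] ** 2 + p.k2 * qf[5] ** 2)
        return {"kinetic": ke, "gravitational": pe, "elastic": el, "total": ke + pe + el}


def nsnr_composite_inertia(pole: PoleParams, loads: LoadParams) -> float:
    """Pitch inertia of the rigid pole with both loads lumped at the tips.

    Parallel-axis sum ``I0 + m1*Lp1**2 + m2*Lp2**2`` about the pole center.
    """
    return pole.I0 + loads.m1 * pole.Lp1**2 + loads.m2 * pole.Lp2**2


# -- spec-level functional wrappers ---------------------------------------


def variant_dynamics(
    pole: PoleParams,
    loads: LoadParams,
    contact: ContactParams,
    control: ControlParams | None = None,
    **kwargs,
) -> PoleLoadModel:
    """Build the callable dynamics for the pole's variant."""
    return PoleLoadModel(pole, loads, contact, control, **kwargs)


def assemble_dynamics(
    state: SystemState,
    shoulder_accel,
    Fh: float,
    pole: PoleParams,
    loads: LoadParams,
    contact: ContactParams,
    control: ControlParams | None = None,
    **kwargs,
):
    """One-shot solve of the instantaneous system at ``state``.

    Returns ``(accelerations, constraint_forces)`` as dicts keyed by
    coordinate / force-label names.
    """
    if state.variant is not pole.variant:
        raise VariantMismatchError(
            f"state variant {state.variant.value} != pole variant {pole.variant.value}"
        )
    model = PoleLoadModel(pole, loads, contact, control, **kwargs)
    qdd, forces = model.accelerations(state.q, state.qd, shoulder_accel, Fh)
    return dict(zip(model.coords, qdd)), forces


def static_equilibrium(
    pole: PoleParams,
    loads: LoadParams,
    contact: ContactParams,
    control: ControlParams | None = None,
    **kwargs,
) -> SystemState:
    """Rest state of the loaded system (pole level, springs carrying gravity)."""
    model = PoleLoadModel(pole, loads, contact, control, **kwargs)
    q0, qd0 = model.static_equilibrium()
    return model.state(q0, qd0)
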