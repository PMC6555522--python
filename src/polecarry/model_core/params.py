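"""Parameter types and the small closed-form structural formulas.

The pole's bending compliance is lumped into an equivalent vertical tip
spring at each end (cantilever tip stiffness ``3*E*I/L**3``); the shoulder
interface is a pair of spring-damper units (one vertical, one along the
pole axis); balance control is a PD law on the pitch angle applied as a
vertical hand force ahead of the shoulder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

from ..errors import InvalidParameterError, NoSupportError, VariantMismatchError

#: standard gravity used throughout (m/s^2)
GRAVITY = 9.81


class Variant(str, Enum):
    """The four structural idealizations of the carrying pole.

    ``NS``/``WS`` = rigid / springy pole tips, ``NR``/``WR`` = loads attached
    directly at the tips / hung from ropes of nonzero length.  All four carry
    the same static load; they differ only dynamically.
    """

    NSNR = "NSNR"
    WSNR = "WSNR"
    NSWR = "NSWR"
    WSWR = "WSWR"

    @property
    def has_spring(self) -> bool:
        return self in (Variant.WSNR, Variant.WSWR)

    @property
    def has_rope(self) -> bool:
        return self in (Variant.NSWR, Variant.WSWR)

    @property
    def coords(self) -> tuple[str, ...]:
        """Names of the active generalized coordinates, in canonical order."""
        names = ["hs", "ds", "theta"]
        if self is Variant.WSNR:
            names += ["h1", "h2"]
        elif self is Variant.NSWR:
            names += ["alpha1", "alpha2"]
        elif self is Variant.WSWR:
            names += ["h1", "alpha1", "h2", "alpha2"]
        return tuple(names)


def _require_positive(**values: float) -> None:
    for name, value in values.items():
        if not (value > 0) or not math.isfinite(value):
            raise InvalidParameterError(f"{name} must be positive and finite, got {value!r}")


def _require_nonnegative(**values: float) -> None:
    for name, value in values.items():
        if not (value >= 0):
            raise InvalidParameterError(f"{name} must be nonnegative, got {value!r}")


@dataclass(frozen=True)
class BeamSection:
    """Cantilever description of one arm of the pole.

    Parameters
    ----------
    E : float
        Young's modulus (Pa).
    I : float
        Second moment of area (m^4).
    L : float
        Arm length from the shoulder support to the tip (m).
    """

    E: float
    I: float
    L: float

    def __post_init__(self) -> None:
        _require_positive(E=self.E, I=self.I, L=self.L)


def static_deflection(m: float, section: BeamSection) -> float:
    """Static tip deflection ``m*g*L**3 / (3*E*I)`` of a loaded cantilever arm.

    Parameters
    ----------
    m : float
        Suspended mass (kg), ``m >= 0``.
    section : BeamSection
        Arm geometry and material.
    """
    if m < 0:
        raise InvalidParameterError(f"load mass must be nonnegative, got {m!r}")
    return m * GRAVITY * section.L**3 / (3.0 * section.E * section.I)


def tip_stiffness(section: BeamSection) -> float:
    """Equivalent vertical tip stiffness ``3*E*I/L**3`` of a cantilever arm (N/m)."""
    return 3.0 * section.E * section.I / section.L**3


def default_pole_inertia(m0: float, Lp1: float, Lp2: float) -> float:
    """Slender-rod pitch inertia ``m0*(Lp1+Lp2)**2/12`` about the pole center.

    ``m0`` must be strictly positive: a massless pole makes the angular
    acceleration singular.
    """
    _require_positive(m0=m0, Lp1=Lp1, Lp2=Lp2)
    return m0 * (Lp1 + Lp2) ** 2 / 12.0


def damping_from_ratio(zeta: float, k: float, m_ref: float) -> float:
    """Damping coefficient ``zeta * 2 * sqrt(k * m_ref)`` (N*s/m).

    Expresses a viscous coefficient through a dimensionless damping ratio
    against a reference mass, e.g. ``zeta=0.25`` with the total carried mass
    for the shoulder contact and ``zeta=0.01`` with one load mass for the
    tip suspension.
    """
    _require_nonnegative(zeta=zeta, k=k)
    _require_positive(m_ref=m_ref)
    return zeta * 2.0 * math.sqrt(k * m_ref)


@dataclass(frozen=True)
class LoadParams:
    """The two suspended loads (point masses; rotary inertia unused)."""

    m1: float
    m2: float
    I1: float = 0.0
    I2: float = 0.0

    def __post_init__(self) -> None:
        _require_positive(m1=self.m1, m2=self.m2)
        _require_nonnegative(I1=self.I1, I2=self.I2)


@dataclass(frozen=True)
class PoleParams:
    """Structural description of the pole and its tip suspensions.

    ``Lp1``/``Lp2`` are the arm lengths behind/ahead of the shoulder support
    (+x forward).  Rigid variants use ``k = inf``; rope-less variants use
    ``Lr = 0``.  ``I0`` defaults to the slender-rod value.
    """

    Lp1: float
    Lp2: float
    variant: Variant
    k1: float = math.inf
    k2: float = math.inf
    c1: float = 0.0
    c2: float = 0.0
    Lr1: float = 0.0
    Lr2: float = 0.0
    m0: float = 1.0
    I0: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", Variant(self.variant))
        _require_positive(Lp1=self.Lp1, Lp2=self.Lp2, m0=self.m0)
        _require_nonnegative(c1=self.c1, c2=self.c2, Lr1=self.Lr1, Lr2=self.Lr2)
        if self.k1 < 0 or self.k2 < 0:
            raise InvalidParameterError("tip stiffnesses must be nonnegative")
        if self.I0 is None:
            object.__setattr__(self, "I0", default_pole_inertia(self.m0, self.Lp1, self.Lp2))
        _require_positive(I0=self.I0)
        v = self.variant
        if v.has_spring:
            if math.isinf(self.k1) or math.isinf(self.k2):
                raise VariantMismatchError(f"{v.value} requires finite tip stiffnesses k1, k2")
        else:
            if not (math.isinf(self.k1) and math.isinf(self.k2)):
                raise VariantMismatchError(f"{v.value} is rigid: k1, k2 must be inf")
        if v.has_rope:
            if not (self.Lr1 > 0 and self.Lr2 > 0):
                raise VariantMismatchError(f"{v.value} requires positive rope lengths Lr1, Lr2")
        else:
            if self.Lr1 != 0 or self.Lr2 != 0:
                raise VariantMismatchError(f"{v.value} has no ropes: Lr1, Lr2 must be 0")

    @property
    def length(self) -> float:
        """Total pole length ``Lp1 + Lp2`` (m)."""
        return self.Lp1 + self.Lp2

    @classmethod
    def make(
        cls,
        variant: Variant | str,
        L: float = 1.4,
        k: float | None = None,
        Lr: float = 0.0,
        m0: float = 1.0,
        I0: float | None = None,
        suspension_zeta: float = 0.01,
        m_ref: float = 10.0,
    ) -> "PoleParams":
        """Symmetric factory: support at midspan, equal arms and suspensions.

        For springy variants ``k`` is required and the tip damping defaults to
        ``damping_from_ratio(suspension_zeta, k, m_ref)``.
        """
        variant = Variant(variant)
        if variant.has_spring:
            if k is None or not math.isfinite(k):
                raise InvalidParameterError(f"{variant.value} requires a finite tip stiffness k")
            c = damping_from_ratio(suspension_zeta, k, m_ref)
        else:
            k, c = math.inf, 0.0
        if variant.has_rope and Lr <= 0:
            raise InvalidParameterError(f"{variant.value} requires a positive rope length")
        if not variant.has_rope:
            Lr = 0.0
        return cls(
            Lp1=L / 2.0, Lp2=L / 2.0, variant=variant,
            k1=k, k2=k, c1=c, c2=c, Lr1=Lr, Lr2=Lr, m0=m0, I0=I0,
        )


@dataclass(frozen=True)
class ContactParams:
    """Shoulder contact: tangential (along-pole) and vertical spring-dampers."""

    kds: float
    khs: float
    cds: float = 0.0
    chs: float = 0.0

    def __post_init__(self) -> None:
        _require_nonnegative(kds=self.kds, cds=self.cds, chs=self.chs)
        if not (self.khs > 0):
            raise NoSupportError("khs must be positive: the vertical contact spring carries the load")

    @classmethod
    def from_stiffness(
        cls, kds: float, khs: float, m_ref: float = 20.0, zeta: float = 0.25
    ) -> "ContactParams":
        """Build with dampings from a common ratio against the carried mass."""
        return cls(
            kds=kds,
            khs=khs,
            cds=damping_from_ratio(zeta, kds, m_ref),
            chs=damping_from_ratio(zeta, khs, m_ref),
        )


@dataclass(frozen=True)
class ControlParams:
    """PD balance control: vertical hand force ``-Kp*theta - Kd*thetadot``.

    Gains act on the pitch angle in radians; the force is applied ``Dh``
    meters ahead of the shoulder along the pole.
    """

    Kp: float = 1000.0
    Kd: float = 500.0
    Dh: float = 0.3
    enabled: bool = True

    def __post_init__(self) -> None:
        _require_nonnegative(Kp=self.Kp, Kd=self.Kd)
        if self.enabled and not (self.Dh > 0):
            raise InvalidParameterError("Dh must be positive when control is enabled")

    def disabled(self) -> "ControlParams":
        return replace(self, enabled=False)


#: convenience: control switched off entirely
NO_CONTROL = ControlParams(Kp=0.0, Kd=0.0, Dh=0.3, enabled=False)
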