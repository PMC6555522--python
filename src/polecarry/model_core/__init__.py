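"""Domain types, structural formulas, force laws and per-variant dynamics."""

from __future__ import annotations

from . import forces as _forces
from .dynamics import (
    AssembledSystem,
    PoleLoadModel,
    SystemState,
    assemble_dynamics,
    nsnr_composite_inertia,
    static_equilibrium,
    variant_dynamics,
)
from .forces import ForcePair, hand_control_force, suspension_force
from .geometry import FULL_COORDS, positions, positions_series, velocities
from .params import (
    GRAVITY,
    NO_CONTROL,
    BeamSection,
    ContactParams,
    ControlParams,
    LoadParams,
    PoleParams,
    Variant,
    damping_from_ratio,
    default_pole_inertia,
    static_deflection,
    tip_stiffness,
)


def kinematics(state: SystemState, shoulder_pos, pole: PoleParams, control: ControlParams | None = None):
    """Positions of pole center, loads, contact and hand points for a state."""
    from .dynamics import PoleLoadModel as _M  # local to avoid cycles

    if state.variant is not pole.variant:
        from ..errors import VariantMismatchError

        raise VariantMismatchError(
            f"state variant {state.variant.value} != pole variant {pole.variant.value}"
        )
    full = [0.0] * 7
    for name, value in zip(state.coords, state.q):
        full[FULL_COORDS.index(name)] = value
    Dh = control.Dh if control is not None else 0.3
    return positions(full, pole, Dh, shoulder_pos)


def contact_force(state: SystemState, contact: ContactParams, projection: str = "as_printed") -> ForcePair:
    """Shoulder contact force on the pole at a given state."""
    return _forces.contact_force(
        state.hs, state.hs_dot, state.ds, state.ds_dot, state.theta, contact, projection
    )


__all__ = [
    "GRAVITY",
    "NO_CONTROL",
    "FULL_COORDS",
    "AssembledSystem",
    "BeamSection",
    "ContactParams",
    "ControlParams",
    "ForcePair",
    "LoadParams",
    "PoleLoadModel",
    "PoleParams",
    "SystemState",
    "Variant",
    "assemble_dynamics",
    "contact_force",
    "damping_from_ratio",
    "default_pole_inertia",
    "hand_control_force",
    "kinematics",
    "nsnr_composite_inertia",
    "positions",
    "positions_series",
    "static_deflection",
    "static_equilibrium",
    "suspension_force",
    "tip_stiffness",
    "variant_dynamics",
    "velocities",
]
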