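"""Per-variant dynamics: equilibria, oracles, limits, error contracts."""

import math

import numpy as np
import pytest

from polecarry import (
    ContactParams,
    ControlParams,
    GRAVITY,
    LoadParams,
    NO_CONTROL,
    PoleLoadModel,
    PoleParams,
    SystemState,
    integrate,
    make_step,
    static_equilibrium,
)
from polecarry.errors import (
    NumericalSingularityError,
    RopeConfigurationError,
    VariantMismatchError,
)
from polecarry.model_core import assemble_dynamics, nsnr_composite_inertia

LOADS = LoadParams(10.0, 10.0)
CONTACT = ContactParams.from_stiffness(500.0, 10000.0, m_ref=20.0)


def make_model(variant, **kw):
    pole = PoleParams.make(variant, L=1.4, **kw)
    return PoleLoadModel(pole, LOADS, CONTACT, NO_CONTROL)


ALL_MODELS = {
    "NSNR": make_model("NSNR"),
    "WSNR": make_model("WSNR", k=500.0),
    "NSWR": make_model("NSWR", Lr=0.5),
    "WSWR": make_model("WSWR", k=500.0, Lr=0.5),
}


class TestSystemState:
    def test_attribute_access(self):
        state = SystemState("WSWR", hs=-0.02, theta=0.1, alpha1=0.05, h2_dot=0.3)
        assert state.hs == -0.02
        assert state.theta == 0.1
        assert state.alpha1 == 0.05
        assert state.h2_dot == 0.3
        assert state.ds == 0.0

    def test_inactive_coordinate_rejected(self):
        with pytest.raises(VariantMismatchError):
            SystemState("NSNR", h1=0.1)

    def test_unknown_coordinate_rejected(self):
        with pytest.raises(TypeError):
            SystemState("NSNR", bogus=1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            SystemState("NSNR", hs=float("nan"))

    def test_vector_shape_checked(self):
        with pytest.raises(VariantMismatchError):
            SystemState.from_vectors("NSNR", [0.0, 0.0], [0.0, 0.0])


class TestStaticEquilibrium:
    @pytest.mark.parametrize("name", list(ALL_MODELS))
    def test_accelerations_vanish(self, name):
        model = ALL_MODELS[name]
        q0, qd0 = model.static_equilibrium()
        qdd, _ = model.accelerations(q0, qd0, Fh=0.0)
        assert np.max(np.abs(qdd)) < 1e-8

    @pytest.mark.parametrize("name", list(ALL_MODELS))
    def test_residuals_vanish(self, name):
        model = ALL_MODELS[name]
        q0, qd0 = model.static_equilibrium()
        qdd, forces = model.accelerations(q0, qd0, Fh=0.0)
        res = model.residuals(q0, qd0, qdd, forces, Fh=0.0)
        assert np.max(np.abs(res)) < 1e-8 * model.total_mass * GRAVITY

    def test_contact_compression(self):
        state = static_equilibrium(
            PoleParams.make("NSNR", L=1.4), LOADS, CONTACT, NO_CONTROL
        )
        assert state.hs == pytest.approx(-0.019620, abs=1e-9)

    def test_spring_extension(self):
        state = static_equilibrium(
            PoleParams.make("WSNR", L=1.4, k=500.0), LOADS, CONTACT, NO_CONTROL
        )
        assert state.h1 == pytest.approx(0.19620, abs=1e-9)
        assert state.h2 == pytest.approx(0.19620, abs=1e-9)

    def test_doubling_khs_halves_compression(self):
        hard = ContactParams.from_stiffness(500.0, 20000.0, m_ref=20.0)
        a = static_equilibrium(PoleParams.make("NSNR"), LOADS, CONTACT, NO_CONTROL)
        b = static_equilibrium(PoleParams.make("NSNR"), LOADS, hard, NO_CONTROL)
        assert b.hs == pytest.approx(a.hs / 2.0)

    def test_pole_weight_flag_increases_compression(self):
        pole = PoleParams.make("NSNR")
        model = PoleLoadModel(pole, LOADS, CONTACT, NO_CONTROL, include_pole_weight=True)
        q0, qd0 = model.static_equilibrium()
        assert q0[0] == pytest.approx(-21.0 * GRAVITY / CONTACT.khs)
        qdd, _ = model.accelerations(q0, qd0, Fh=0.0)
        assert np.max(np.abs(qdd)) < 1e-8


class TestAssembly:
    def test_spec_level_wrapper(self):
        pole = PoleParams.make("NSNR")
        state = static_equilibrium(pole, LOADS, CONTACT, NO_CONTROL)
        accels, forces = assemble_dynamics(state, (0.0, 0.0), 0.0, pole, LOADS, CONTACT)
        assert set(accels) == {"hs", "ds", "theta"}
        assert forces["F1y"] == pytest.approx(98.1)
        assert max(abs(v) for v in accels.values()) < 1e-8

    def test_wrapper_variant_mismatch(self):
        pole = PoleParams.make("NSNR")
        state = SystemState("WSNR")
        with pytest.raises(VariantMismatchError):
            assemble_dynamics(state, (0.0, 0.0), 0.0, pole, LOADS, CONTACT)

    def test_assembled_system_labels(self):
        model = ALL_MODELS["NSWR"]
        sys = model.assemble(*model.static_equilibrium())
        assert sys.unknowns == ("hs", "ds", "theta", "alpha1", "alpha2", "T1", "T2")
        assert sys.matrix.shape == (7, 7)
        assert np.isfinite(sys.condition_number)

    def test_free_fall_with_zero_springs(self):
        # WSWR with k = c = 0: the loads are disconnected and fall freely
        pole = PoleParams(
            Lp1=0.7, Lp2=0.7, variant="WSWR", k1=0.0, k2=0.0, c1=0.0, c2=0.0,
            Lr1=0.5, Lr2=0.5,
        )
        model = PoleLoadModel(pole, LOADS, CONTACT, NO_CONTROL)
        q0, qd0 = model.static_equilibrium()
        q0[0] = 0.0  # unload the contact as well
        qdd, _ = model.accelerations(q0, qd0, Fh=0.0)
        _, a1, a2 = model.point_accelerations(q0, qd0, qdd)
        assert a1 == pytest.approx([0.0, -GRAVITY], abs=1e-9)
        assert a2 == pytest.approx([0.0, -GRAVITY], abs=1e-9)

    def test_rope_angle_limit_raises(self):
        model = ALL_MODELS["NSWR"]
        q0, qd0 = model.static_equilibrium()
        q0[model.coords.index("alpha1")] = math.pi / 2
        with pytest.raises(RopeConfigurationError):
            model.accelerations(q0, qd0, Fh=0.0)

    def test_singular_matrix_reported(self):
        sys_ = ALL_MODELS["NSNR"].assemble(*ALL_MODELS["NSNR"].static_equilibrium())
        sys_.matrix[:] = 0.0
        with pytest.raises(NumericalSingularityError):
            sys_.solve()


class TestCompositeInertia:
    def test_parallel_axis_value(self):
        pole = PoleParams.make("NSNR", L=1.4)
        assert nsnr_composite_inertia(pole, LOADS) == pytest.approx(9.963, abs=1e-3)


class TestResidualOracle:
    @pytest.mark.parametrize("name", list(ALL_MODELS))
    def test_random_states_balance(self, name, rng):
        model = ALL_MODELS[name]
        n = model.n_coords
        tol = 1e-8 * model.total_mass * GRAVITY
        for _ in range(20):
            q = rng.uniform(-0.2, 0.2, n)
            qd = rng.uniform(-0.5, 0.5, n)
            accel = tuple(rng.uniform(-2.0, 2.0, 2))
            Fh = float(rng.uniform(-50.0, 50.0))
            qdd, forces = model.accelerations(q, qd, accel, Fh=Fh)
            res = model.residuals(q, qd, qdd, forces, accel, Fh=Fh)
            assert np.max(np.abs(res)) < tol


class TestHandForceRouting:
    def test_pd_force_applied_in_rhs(self):
        ctl = ControlParams(Kp=1000.0, Kd=500.0, Dh=0.3)
        pole = PoleParams.make("NSNR")
        model = PoleLoadModel(pole, LOADS, CONTACT, ctl)
        q0, qd0 = model.static_equilibrium()
        q0[2] = 0.05  # tilted; the controller should push theta back down
        qdd_ctl, _ = model.accelerations(q0, qd0)  # Fh=None -> PD law
        qdd_off, _ = model.accelerations(q0, qd0, Fh=0.0)
        assert qdd_ctl[2] < qdd_off[2]

    def test_hand_force_value(self):
        ctl = ControlParams(Kp=1000.0, Kd=500.0, Dh=0.3)
        model = PoleLoadModel(PoleParams.make("NSNR"), LOADS, CONTACT, ctl)
        assert model.hand_force(0.1, -0.1) == pytest.approx(-100.0 + 50.0)


class TestVerticalMotionSymmetry:
    def test_pure_vertical_shoulder_motion_never_tips(self):
        from polecarry import make_walking

        model = PoleLoadModel(PoleParams.make("NSNR"), LOADS, CONTACT, ControlParams())
        traj = make_walking(Ax=0.0, duration=4.0, variability=())
        result = integrate(model, traj)
        assert np.max(np.abs(np.radians(result.theta_deg))) < 1e-10


class TestStiffLimits:
    """Reduced-coordinate variants agree with their stiff/short-rope limits."""

    AMPLITUDE = 0.05  # small enough that the tiny pendulum stays well-behaved

    @pytest.fixture(scope="class")
    def reference(self):
        from polecarry import step_response

        return step_response(
            PoleParams.make("NSNR", L=1.4), LOADS, CONTACT, NO_CONTROL,
            step_amplitude=self.AMPLITUDE, duration=2.0,
        )

    def _max_dtheta(self, pole, reference):
        from polecarry import step_response

        res = step_response(
            pole, LOADS, CONTACT, NO_CONTROL,
            step_amplitude=self.AMPLITUDE, duration=2.0,
        )
        n = min(len(res.theta_deg), len(reference.theta_deg))
        return float(np.max(np.abs(res.theta_deg[:n] - reference.theta_deg[:n])))

    def test_wsnr_stiff_limit(self, reference):
        pole = PoleParams.make("WSNR", L=1.4, k=1e6)
        assert self._max_dtheta(pole, reference) < 0.5

    def test_nswr_short_rope_limit(self, reference):
        pole = PoleParams.make("NSWR", L=1.4, Lr=0.05)
        assert self._max_dtheta(pole, reference) < 0.5

    def test_wswr_double_limit(self, reference):
        pole = PoleParams.make("WSWR", L=1.4, k=1e6, Lr=0.05, suspension_zeta=1.0)
        assert self._max_dtheta(pole, reference) < 0.5


class TestEnergyConservation:
    """Undamped, uncontrolled, shoulder fixed: mechanical energy is constant."""

    def _drift(self, model, q0, qd0, t_end=10.0):
        from polecarry import energy_audit

        traj = make_step(0.0, t_end)
        result = integrate(model, traj, x0=(q0, qd0))
        e = energy_audit(result)
        scale = max(abs(e["total"][0]), 1.0)
        return float(np.max(np.abs(e["total"] - e["total"][0]))) / scale

    def test_wsnr_vertical_bounce(self):
        contact = ContactParams(kds=500.0, khs=10000.0, cds=0.0, chs=0.0)
        pole = PoleParams(Lp1=0.7, Lp2=0.7, variant="WSNR", k1=500.0, k2=500.0)
        model = PoleLoadModel(pole, LOADS, contact, None)
        q0, qd0 = model.static_equilibrium()
        q0[model.coords.index("h1")] += 0.05
        q0[model.coords.index("h2")] += 0.05
        q0[0] += 0.01
        assert self._drift(model, q0, qd0) < 1e-6

    def test_wswr_vertical_bounce(self):
        contact = ContactParams(kds=500.0, khs=10000.0, cds=0.0, chs=0.0)
        pole = PoleParams(
            Lp1=0.7, Lp2=0.7, variant="WSWR", k1=500.0, k2=500.0, Lr1=0.5, Lr2=0.5
        )
        model = PoleLoadModel(pole, LOADS, contact, None)
        q0, qd0 = model.static_equilibrium()
        q0[model.coords.index("h1")] += 0.05
        q0[model.coords.index("h2")] += 0.05
        assert self._drift(model, q0, qd0) < 1e-6

    def test_damped_run_dissipates(self):
        from polecarry import energy_audit

        model = PoleLoadModel(
            PoleParams.make("WSNR", L=1.4, k=500.0), LOADS, CONTACT, None
        )
        q0, qd0 = model.static_equilibrium()
        q0[model.coords.index("h1")] += 0.05
        q0[model.coords.index("h2")] += 0.05
        result = integrate(model, make_step(0.0, 4.0), x0=(q0, qd0))
        e = energy_audit(result)
        diffs = np.diff(e["total"])
        assert np.all(diffs <= 1e-9)
        assert e["total"][-1] < e["total"][0]
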