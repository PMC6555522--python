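"""Integration wrapper, experiment protocols and metrics."""

import numpy as np
import pytest

from polecarry import (
    ContactParams,
    ControlParams,
    LoadParams,
    NO_CONTROL,
    PoleLoadModel,
    PoleParams,
    calibrate_step_amplitude,
    integrate,
    make_step,
    oscillation_metrics,
    rollover_metrics,
    step_response,
    walking_response,
)
from polecarry.errors import CalibrationError, InvalidParameterError

LOADS = LoadParams(10.0, 10.0)
CONTACT = ContactParams.from_stiffness(500.0, 10000.0, m_ref=20.0)
NSNR = PoleParams.make("NSNR", L=1.4)


class TestIntegrate:
    def test_equilibrium_is_fixed_point(self):
        model = PoleLoadModel(NSNR, LOADS, CONTACT, NO_CONTROL)
        result = integrate(model, make_step(0.0, 2.0), rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(result.q - result.q[0])) < 1e-10
        assert np.max(np.abs(result.theta_deg)) < 1e-10

    def test_theta_starts_at_zero(self):
        result = step_response(NSNR, LOADS, CONTACT, NO_CONTROL, step_amplitude=0.1, duration=0.5)
        assert result.theta_deg[0] == pytest.approx(0.0, abs=1e-12)

    def test_output_grid_independence(self):
        kw = dict(step_amplitude=0.1, duration=1.0)
        a = step_response(NSNR, LOADS, CONTACT, NO_CONTROL, output_dt=2e-3, **kw)
        b = step_response(NSNR, LOADS, CONTACT, NO_CONTROL, output_dt=1e-3, **kw)
        assert b.theta_deg[::2] == pytest.approx(a.theta_deg, abs=1e-6)

    def test_clamped_spring_mass_period(self):
        # pole clamped by a stiff, near-critically damped contact; each load
        # then bounces on its tip spring: T = 2*pi*sqrt(m/k) = 0.8886 s
        kc = 1e6
        clamp = ContactParams(kds=kc, khs=kc, cds=2 * np.sqrt(kc * 21), chs=2 * np.sqrt(kc * 21))
        pole = PoleParams(Lp1=0.7, Lp2=0.7, variant="WSNR", k1=500.0, k2=500.0)
        model = PoleLoadModel(pole, LOADS, clamp, None)
        q0, qd0 = model.static_equilibrium()
        q0[model.coords.index("h1")] += 0.02
        q0[model.coords.index("h2")] += 0.02
        result = integrate(model, make_step(0.0, 5.0), x0=(q0, qd0))
        _, period = oscillation_metrics(result.t, result.q[:, model.coords.index("h1")])
        assert period == pytest.approx(0.8886, rel=0.01)

    def test_rollover_terminates(self):
        result = step_response(NSNR, LOADS, CONTACT, NO_CONTROL, step_amplitude=0.45, duration=5.0)
        assert result.rollover
        assert result.t[-1] < 5.0
        assert np.max(np.abs(result.theta_deg)) <= 90.5

    def test_forces_recomputed_from_states(self):
        result = step_response(NSNR, LOADS, CONTACT, NO_CONTROL, step_amplitude=0.1, duration=0.5)
        i = len(result.t) // 2
        hs, ds = result.q[i, 0], result.q[i, 1]
        hsd, dsd = result.qd[i, 0], result.qd[i, 1]
        ev = CONTACT.khs * hs + CONTACT.chs * hsd
        assert result.Fsy[i] == pytest.approx(-ev)
        assert result.Fh[i] == 0.0


class TestStepResponse:
    def test_zero_amplitude_stays_level(self):
        result = step_response(NSNR, LOADS, CONTACT, NO_CONTROL, step_amplitude=0.0, duration=1.0)
        assert np.max(np.abs(result.theta_deg)) < 1e-10

    def test_negative_amplitude_rejected(self):
        with pytest.raises(InvalidParameterError):
            step_response(NSNR, LOADS, CONTACT, NO_CONTROL, step_amplitude=-0.1)

    @pytest.mark.parametrize("rise_time", [0.0, 0.3])
    def test_uncontrolled_rollover_is_monotone(self, rise_time):
        for amplitude in (0.05, 0.15, 0.3):
            result = step_response(
                NSNR, LOADS, CONTACT, NO_CONTROL,
                step_amplitude=amplitude, duration=1.0, rise_time=rise_time,
            )
            theta = np.abs(np.radians(result.theta_deg))
            assert np.all(np.diff(theta) >= -1e-9)

    def test_theta_at_1s_increasing_in_amplitude(self):
        amps = [0.05, 0.1, 0.2, 0.3]
        values = [
            step_response(NSNR, LOADS, CONTACT, NO_CONTROL, step_amplitude=a, duration=1.0).theta_deg[-1]
            for a in amps
        ]
        assert np.all(np.diff(values) > 0)

    def test_deterministic(self):
        a = step_response(NSNR, LOADS, CONTACT, NO_CONTROL, step_amplitude=0.1, duration=0.5)
        b = step_response(NSNR, LOADS, CONTACT, NO_CONTROL, step_amplitude=0.1, duration=0.5)
        assert np.array_equal(a.theta_deg, b.theta_deg)
        assert np.array_equal(a.Fsy, b.Fsy)


class TestWalkingResponse:
    def test_requires_control(self):
        from polecarry import make_walking

        with pytest.raises(InvalidParameterError):
            walking_response(NSNR, LOADS, CONTACT, NO_CONTROL, make_walking(duration=1.0))

    def test_deterministic(self):
        from polecarry import make_walking

        ctl = ControlParams()
        traj = make_walking(duration=1.0)
        a = walking_response(NSNR, LOADS, CONTACT, ctl, traj)
        b = walking_response(NSNR, LOADS, CONTACT, ctl, traj)
        assert np.array_equal(a.theta_deg, b.theta_deg)


class TestRolloverMetrics:
    def test_zero_series(self):
        m = rollover_metrics(np.zeros(100), np.linspace(0, 1, 100))
        assert m.theta_max == 0.0
        assert m.settling_time == 0.0
        assert m.settled

    def test_exponential_decay_closed_form(self):
        t = np.linspace(0, 6, 60001)
        theta = 0.5 * np.exp(-t)
        m = rollover_metrics(theta, t, band=0.1)
        assert m.theta_max == pytest.approx(0.5)
        assert m.settling_time == pytest.approx(np.log(5.0), abs=2e-4)

    def test_not_settled_when_band_exceeded_at_end(self):
        t = np.linspace(0, 1, 101)
        theta = np.full_like(t, 0.2)
        m = rollover_metrics(theta, t, band=0.1)
        assert m.settling_time is None
        assert not m.settled

    def test_empty_series_rejected(self):
        with pytest.raises(InvalidParameterError):
            rollover_metrics([], [])


class TestOscillationMetrics:
    def test_known_sinusoid_period(self):
        t = np.arange(0, 10, 0.001)
        x = np.sin(2 * np.pi * 1.8 * t)
        amp, period = oscillation_metrics(t, x)
        assert period == pytest.approx(1 / 1.8, abs=0.001)
        assert amp == pytest.approx(1.0, rel=1e-3)

    def test_constant_series(self):
        t = np.linspace(0, 1, 1000)
        amp, period = oscillation_metrics(t, np.full_like(t, 3.0))
        assert amp == 0.0
        assert period is None

    def test_amplitude_linearity(self):
        t = np.arange(0, 5, 0.001)
        x = np.sin(2 * np.pi * 2.0 * t) + 0.3
        a1, _ = oscillation_metrics(t, x)
        a2, _ = oscillation_metrics(t, 2 * x)
        assert a2 == pytest.approx(2 * a1, rel=1e-9)

    def test_window_selection(self):
        t = np.arange(0, 10, 0.001)
        x = np.where(t < 5, np.sin(2 * np.pi * 1.0 * t), np.sin(2 * np.pi * 3.0 * t))
        _, period = oscillation_metrics(t, x, window=(6.0, 10.0))
        assert period == pytest.approx(1 / 3.0, abs=0.002)


class TestCalibration:
    def test_deterministic(self, calibrated_amplitude, nsnr_pole, loads, contact):
        again = calibrate_step_amplitude(nsnr_pole, loads, contact, target_angle=15.0, at_time=1.0)
        assert again == calibrated_amplitude

    def test_hits_target(self, calibrated_amplitude, nsnr_pole, loads, contact):
        result = step_response(
            nsnr_pole, loads, contact, NO_CONTROL,
            step_amplitude=calibrated_amplitude, duration=1.0,
        )
        assert result.theta_deg[-1] == pytest.approx(15.0, abs=0.05)

    def test_degenerate_target_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_step_amplitude(NSNR, LOADS, CONTACT, target_angle=0.0)

    def test_unreachable_target_reports_range(self):
        with pytest.raises(CalibrationError, match="achieved range"):
            calibrate_step_amplitude(
                NSNR, LOADS, CONTACT, target_angle=0.001, at_time=0.2, bracket=(0.05, 0.2)
            )


class TestCsvOutput:
    def test_header_and_columns(self, tmp_path):
        result = step_response(NSNR, LOADS, CONTACT, NO_CONTROL, step_amplitude=0.05, duration=0.2)
        path = tmp_path / "run.csv"
        result.to_csv(path, header={"note": "unit-test"})
        text = path.read_text()
        assert text.startswith("# polecarry simulation result")
        assert "unit-test" in text
        import pandas as pd

        frame = pd.read_csv(path, comment="#")
        for col in ("t", "theta_deg", "Fh_N", "Fsx_N", "Fsy_N", "hs", "ds", "theta"):
            assert col in frame.columns
        assert len(frame) == len(result.t)
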