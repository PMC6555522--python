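"""Shoulder-motion inputs: steps, synthetic gait oscillations, measured files.

A :class:`ShoulderTrajectory` exposes position, velocity and acceleration of
the shoulder point as functions of time — analytically for synthetic signals,
via splines for measured data.  The horizontal step used in the step-response
protocol is represented impulse-free: the position series stays constant and
the offset is carried in :attr:`ShoulderTrajectory.ds_offset`, which the
simulation applies as an initial tangential offset of the pole (exactly
equivalent to a position step at level pitch).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .errors import InvalidParameterError, TrajectoryFormatError


class ShoulderTrajectory:
    """Planar shoulder motion with first and second derivatives.

    Construct via :meth:`from_callables` (analytic) or :meth:`from_arrays`
    (sampled, spline-differentiated).  Calling conventions accept scalar or
    array time; outside the stored grid the trajectory is clamped to its
    endpoint values (derivatives zero), so simulations may overrun slightly.
    """

    def __init__(self, t, x, y, fx, fy, dfx, dfy, ddfx, ddfy, ds_offset=0.0, meta=None):
        self.t = np.asarray(t, dtype=float)
        if self.t.ndim != 1 or len(self.t) < 2 or np.any(np.diff(self.t) <= 0):
            raise TrajectoryFormatError("time grid must be 1-D and strictly increasing")
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self._fx, self._fy = fx, fy
        self._dfx, self._dfy = dfx, dfy
        self._ddfx, self._ddfy = ddfx, ddfy
        self.ds_offset = float(ds_offset)
        self.meta = dict(meta or {})

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_callables(
        cls,
        duration: float,
        dt: float,
        fx: Callable,
        fy: Callable,
        dfx: Callable,
        dfy: Callable,
        ddfx: Callable,
        ddfy: Callable,
        ds_offset: float = 0.0,
        meta=None,
    ) -> "ShoulderTrajectory":
        if dt <= 0:
            raise InvalidParameterError(f"dt must be positive, got {dt!r}")
        if duration <= 0:
            raise InvalidParameterError(f"duration must be positive, got {duration!r}")
        n = int(round(duration / dt))
        t = np.linspace(0.0, n * dt, n + 1)
        return cls(t, fx(t), fy(t), fx, fy, dfx, dfy, ddfx, ddfy, ds_offset, meta)

    @classmethod
    def from_arrays(cls, t, x, y, smoothing: float | None = None, meta=None) -> "ShoulderTrajectory":
        """Build from sampled positions; derivatives come from splines.

        ``smoothing`` is the penalty ``lam`` of a smoothing spline; ``None``
        uses an interpolating cubic spline.
        """
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if smoothing is None:
            sx, sy = CubicSpline(t, x), CubicSpline(t, y)
        else:
            sx = make_smoothing_spline(t, x, lam=smoothing)
            sy = make_smoothing_spline(t, y, lam=smoothing)
        dsx, dsy = sx.derivative(), sy.derivative()
        ddsx, ddsy = dsx.derivative(), dsy.derivative()
        return cls(t, x, y, sx, sy, dsx, dsy, ddsx, ddsy, 0.0, meta)

    # -- evaluation --------------------------------------------------------

    @property
    def t_end(self) -> float:
        return float(self.t[-1])

    def _eval(self, fx, fy, t, clamp_value=None):
        t = np.asarray(t, dtype=float)
        tc = np.clip(t, self.t[0], self.t[-1])
        out = np.stack([np.asarray(fx(tc), dtype=float), np.asarray(fy(tc), dtype=float)], axis=-1)
        if clamp_value is not None:
            out = np.where((t < self.t[0]) | (t > self.t[-1]), clamp_value, out.T).T
        return out

    def position(self, t):
        return self._eval(self._fx, self._fy, t)

    def velocity(self, t):
        return self._eval(self._dfx, self._dfy, t, clamp_value=0.0)

    def acceleration(self, t):
        return self._eval(self._ddfx, self._ddfy, t, clamp_value=0.0)

    def acceleration_fn(self):
        """Scalar-time fast path for the integrator."""
        ddfx, ddfy = self._ddfx, self._ddfy
        t0, t1 = float(self.t[0]), float(self.t[-1])

        def accel(t: float):
            if t < t0 or t > t1:
                return (0.0, 0.0)
            return (float(ddfx(t)), float(ddfy(t)))

        return accel

    def derivative_consistency(self, rtol: float = 0.02) -> float:
        """Max RMS mismatch between spline velocity and FD of positions.

        Returns the worse of the two axes' relative RMS errors (useful as an
        invariant check on file-derived trajectories).
        """
        dt = np.diff(self.t)
        tm = 0.5 * (self.t[:-1] + self.t[1:])
        v = self.velocity(tm)
        fdx = np.diff(self.x) / dt
        fdy = np.diff(self.y) / dt
        errs = []
        for fd, vs in ((fdx, v[:, 0]), (fdy, v[:, 1])):
            scale = max(float(np.sqrt(np.mean(fd**2))), 1e-12)
            errs.append(float(np.sqrt(np.mean((fd - vs) ** 2))) / scale)
        return max(errs)


def make_step(
    amplitude: float, duration: float, dt: float = 1e-3, rise_time: float = 0.0
) -> ShoulderTrajectory:
    """Horizontal step of the shoulder.

    ``rise_time = 0`` gives the impulse-free convention: the position series
    stays constant, accelerations are identically zero, and the offset is
    carried in ``ds_offset`` for the simulation to apply as an initial
    tangential offset.  Note this drops the finite impulse the contact
    *damper* transmits during a real displacement; a positive ``rise_time``
    instead drives the shoulder through a half-cosine ramp of that duration,
    which is the realization used by the step-response protocol.
    """
    if amplitude < 0:
        raise InvalidParameterError(f"step amplitude must be nonnegative, got {amplitude!r}")
    if rise_time < 0:
        raise InvalidParameterError(f"rise_time must be nonnegative, got {rise_time!r}")
    meta = {"kind": "step", "amplitude": amplitude, "rise_time": rise_time}
    zero = lambda t: np.zeros_like(np.asarray(t, dtype=float))
    if rise_time == 0.0:
        return ShoulderTrajectory.from_callables(
            duration, dt, zero, zero, zero, zero, zero, zero,
            ds_offset=amplitude, meta=meta,
        )
    T = rise_time
    fx = lambda t: np.where(
        np.asarray(t) < T, amplitude * (1.0 - np.cos(np.pi * np.asarray(t) / T)) / 2.0, amplitude
    )
    dfx = lambda t: np.where(
        np.asarray(t) < T, amplitude * np.pi / (2.0 * T) * np.sin(np.pi * np.asarray(t) / T), 0.0
    )
    ddfx = lambda t: np.where(
        np.asarray(t) < T,
        amplitude * (np.pi / T) ** 2 / 2.0 * np.cos(np.pi * np.asarray(t) / T),
        0.0,
    )
    return ShoulderTrajectory.from_callables(duration, dt, fx, zero, dfx, zero, ddfx, zero, meta=meta)


#: low-frequency fore-aft drift band emulating step-to-step gait variability:
#: (frequency Hz, amplitude m, phase rad) per component.  Postural sway and
#: imperfect periodicity put centimeter-scale power below ~0.5 Hz in measured
#: shoulder trajectories; a pure sinusoid misses it entirely.
DEFAULT_VARIABILITY = (
    (0.13, 0.008, 0.9),
    (0.27, 0.008, 2.1),
    (0.38, 0.008, 4.0),
    (0.49, 0.008, 5.5),
)


def make_walking(
    speed: float = 1.2,
    step_freq: float = 1.8,
    Ax: float = 0.010,
    Ay: float = 0.025,
    phase: float = math.pi / 2,
    duration: float = 12.0,
    dt: float = 1e-3,
    treadmill: bool = True,
    vertical_freq: float | None = None,
    variability=DEFAULT_VARIABILITY,
) -> ShoulderTrajectory:
    """Gait-like shoulder motion standing in for a measured treadmill trial.

    The deterministic model is ``xo = Ax*sin(2*pi*f*t + phase) + drift`` and
    ``yo = Ay*sin(2*pi*fv*t)`` with ``fv`` defaulting to the step frequency
    and ``drift = speed*t`` in overground mode.  ``variability`` adds a
    multi-sine low-frequency fore-aft band (see
    :data:`DEFAULT_VARIABILITY`); pass an empty tuple for a pure sinusoid.
    Derivatives are analytic.  Amplitudes and frequency default to typical
    adult treadmill values at 1.2 m/s.
    """
    if step_freq <= 0:
        raise InvalidParameterError(f"step_freq must be positive, got {step_freq!r}")
    fv = vertical_freq if vertical_freq is not None else step_freq
    wx = 2.0 * math.pi * step_freq
    wy = 2.0 * math.pi * fv
    drift = 0.0 if treadmill else speed
    comps = tuple((2.0 * math.pi * f, a, ph) for f, a, ph in variability)

    def fx(t):
        t = np.asarray(t, dtype=float)
        out = Ax * np.sin(wx * t + phase) + drift * t
        for w, a, ph in comps:
            out = out + a * np.sin(w * t + ph)
        return out

    def dfx(t):
        t = np.asarray(t, dtype=float)
        out = Ax * wx * np.cos(wx * t + phase) + drift
        for w, a, ph in comps:
            out = out + a * w * np.cos(w * t + ph)
        return out

    def ddfx(t):
        t = np.asarray(t, dtype=float)
        out = -Ax * wx * wx * np.sin(wx * t + phase)
        for w, a, ph in comps:
            out = out - a * w * w * np.sin(w * t + ph)
        return out

    fy = lambda t: Ay * np.sin(wy * np.asarray(t))
    dfy = lambda t: Ay * wy * np.cos(wy * np.asarray(t))
    ddfy = lambda t: -Ay * wy * wy * np.sin(wy * np.asarray(t))
    meta = {
        "kind": "walking", "speed": speed, "step_freq": step_freq, "Ax": Ax, "Ay": Ay,
        "phase": phase, "treadmill": treadmill, "vertical_freq": fv,
        "variability": [list(c) for c in variability],
    }
    return ShoulderTrajectory.from_callables(duration, dt, fx, fy, dfx, dfy, ddfx, ddfy, meta=meta)


def read_trajectory(
    path,
    column_spec: dict | None = None,
    units: str | None = None,
    dt: float | None = None,
    smoothing: float | None = None,
    max_gap: int = 5,
) -> ShoulderTrajectory:
    """Read a measured two-column shoulder trajectory (CSV or XLSX).

    CSV files carry columns ``t,x,y`` (header row; lines starting with ``#``
    are comments, and a ``# units: mm`` directive switches input units).
    Spreadsheets are read through ``column_spec = {"sheet": ..., "t": "A",
    "x": "B", "y": "C"}`` style mappings (names or letters).

    The series is resampled to a uniform ``dt`` (default: median spacing) and
    differentiated by splines; NaN runs up to ``max_gap`` samples are
    interpolated, longer gaps raise :class:`TrajectoryFormatError`.
    """
    path = Path(path)
    spec = dict(column_spec or {})
    if path.suffix.lower() in (".xlsx", ".xls"):
        frame = pd.read_excel(path, sheet_name=spec.get("sheet", 0), engine="openpyxl")
    else:
        file_units = None
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if "units" in line:
                    file_units = line.split(":", 1)[1].strip().lower()
        frame = pd.read_csv(path, comment="#")
        if units is None:
            units = file_units

    def pick(role, default):
        sel = spec.get(role, default)
        if isinstance(sel, int):
            return frame.iloc[:, sel]
        if sel in frame.columns:
            return frame[sel]
        # spreadsheet letter -> positional
        if isinstance(sel, str) and len(sel) <= 2 and sel.isalpha():
            pos = 0
            for ch in sel.upper():
                pos = pos * 26 + (ord(ch) - ord("A") + 1)
            return frame.iloc[:, pos - 1]
        raise TrajectoryFormatError(f"missing column {sel!r} for {role!r} in {path.name}")

    t = pick("t", "t").to_numpy(dtype=float)
    x = pick("x", "x").to_numpy(dtype=float)
    y = pick("y", "y").to_numpy(dtype=float)
    if np.any(np.isnan(t)) or np.any(np.diff(t) <= 0):
        raise TrajectoryFormatError(f"{path.name}: time column must be strictly increasing")

    def degap(v, name):
        nan = np.isnan(v)
        if not nan.any():
            return v
        runs = np.diff(np.flatnonzero(np.diff(np.concatenate(([0], nan.view(np.int8), [0])))))
        if nan.all() or max(runs[::2], default=0) > max_gap:
            raise TrajectoryFormatError(
                f"{path.name}: NaN gap in {name!r} exceeds {max_gap} samples"
            )
        out = v.copy()
        out[nan] = np.interp(t[nan], t[~nan], v[~nan])
        return out

    x = degap(x, "x")
    y = degap(y, "y")
    scale = {"mm": 1e-3, "cm": 1e-2, "m": 1.0, None: 1.0}.get(units)
    if scale is None:
        raise TrajectoryFormatError(f"unknown units {units!r}")
    x, y = x * scale, y * scale

    if dt is None:
        dt = float(np.median(np.diff(t)))
    n = int(math.floor((t[-1] - t[0]) / dt + 1e-9))
    tu = np.minimum(t[0] + dt * np.arange(n + 1), t[-1])
    sx = CubicSpline(t, x)
    sy = CubicSpline(t, y)
    traj = ShoulderTrajectory.from_arrays(
        tu, sx(tu), sy(tu), smoothing=smoothing,
        meta={"kind": "measured", "source": str(path), "units": units or "m", "dt": dt},
    )
    return traj


def write_trajectory(traj: ShoulderTrajectory, path, units: str = "m") -> None:
    """Write a trajectory as a commented ``t,x,y`` CSV (native format)."""
    scale = {"m": 1.0, "mm": 1e3, "cm": 1e2}[units]
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n")
        fh.write("t,x,y\n")
        for ti, xi, yi in zip(traj.t, traj.x, traj.y):
            fh.write(f"{ti:.9g},{xi * scale:.12g},{yi * scale:.12g}\n")
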