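"""Execution of configured experiments and the named figure suites."""

from __future__ import annotations

import json
import math
from pathlib import Path

from .. import __version__
from ..errors import ConfigError
from ..model_core import NO_CONTROL
from ..simulate import (
    balance_metrics,
    calibrate_step_amplitude,
    integrate,
    step_response,
    walking_response,
)
from ..trajectories import DEFAULT_VARIABILITY, make_walking, read_trajectory
from .config import ExperimentConfig


def _walking_trajectory(cfg: ExperimentConfig):
    w = cfg.raw["walking"]
    if w["trajectory_file"]:
        return read_trajectory(
            w["trajectory_file"], units=w["units"], smoothing=w["smoothing"]
        )
    variability = w["variability"]
    if variability == "default":
        variability = DEFAULT_VARIABILITY
    elif variability in ("none", None):
        variability = ()
    return make_walking(
        step_freq=w["step_freq"], Ax=w["Ax"], Ay=w["Ay"], phase=w["phase"],
        duration=w["duration"], dt=w["dt"], treadmill=bool(w["treadmill"]),
        vertical_freq=w["vertical_freq"], variability=variability,
    )


def run_config(cfg: ExperimentConfig, step_amplitude: float | None = None):
    """Execute one (non-sweep) configuration; returns ``(result, metrics)``."""
    pole = cfg.build_pole()
    loads = cfg.build_loads()
    contact = cfg.build_contact()
    control = cfg.build_control()
    model = cfg.build_model()
    out = cfg.raw["output"]
    if cfg.raw["scenario"] == "step":
        st = cfg.raw["step"]
        amplitude = step_amplitude if step_amplitude is not None else st["amplitude"]
        if amplitude is None:
            amplitude = calibrate_step_amplitude(
                pole, loads, contact,
                target_angle=st["target_angle"], at_time=st["at_time"],
                rise_time=st["rise_time"], output_dt=out["dt"],
            )
        result = step_response(
            pole, loads, contact, control,
            step_amplitude=amplitude, duration=st["duration"],
            rise_time=st["rise_time"], output_dt=out["dt"], model=model,
        )
    else:
        trajectory = _walking_trajectory(cfg)
        result = walking_response(
            pole, loads, contact, control, trajectory, output_dt=out["dt"], model=model
        )
    window = out["window"]
    if window is None and cfg.raw["scenario"] == "walking":
        window = (result.t[-1] / 3.0, result.t[-1])
    metrics = balance_metrics(result, band=out["band_deg"], window=window)
    return result, metrics


def run(cfg: ExperimentConfig, out_dir, step_amplitude: float | None = None) -> dict:
    """Run a config (expanding sweeps) and write CSV/JSON artifacts.

    Returns ``{label: (result, metrics)}``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = {}
    summary = {}
    for label, sub in cfg.sweep_configs():
        result, metrics = run_config(sub, step_amplitude=step_amplitude)
        header = {"label": label, "polecarry_version": __version__, "config": sub.resolved()}
        result.to_csv(out_dir / f"{label}.csv", header=header)
        summary[label] = metrics.to_dict()
        results[label] = (result, metrics)
    cfg.dump(out_dir / "config.resolved.yaml")
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return results


# -- figure suites ---------------------------------------------------------

_BASE = {
    "loads": {"m1": 10.0, "m2": 10.0},
    "contact": {"kds": 500.0, "khs": 10000.0},
    "control": {"enabled": False},
    "scenario": "step",
    "step": {"duration": 1.0},
}


def _cfg(**over) -> dict:
    import copy

    data = copy.deepcopy(_BASE)
    for key, value in over.items():
        if isinstance(value, dict) and key in data:
            data[key].update(value)
        else:
            data[key] = value
    return data


#: named experiment suites mirroring the published figure sweeps
SUITES: dict[str, dict] = {
    "fig6a": _cfg(sweep={"param": "contact.kds", "values": [500, 2000, 4000]}),
    "fig6b": _cfg(sweep={"param": "contact.khs", "values": [1000, 5000, 10000]}),
    "fig6c": _cfg(sweep={"param": "pole.L", "values": [1.0, 1.4, 1.8]}),
    "fig6d": _cfg(
        variant="WSNR", pole={"k": 500.0},
        sweep={"param": "pole.k", "values": [500, 2000, 4000]},
    ),
    "fig6e": _cfg(
        variant="NSWR", pole={"Lr": 0.2},
        sweep={"param": "pole.Lr", "values": [0.2, 0.5, 1.0]},
    ),
    "fig7": _cfg(control={"enabled": True}, step={"duration": 10.0}),
    "fig8a": _cfg(
        control={"enabled": True}, step={"duration": 10.0},
        sweep={"param": "pole.L", "values": [1.0, 1.4, 1.8]},
    ),
    "fig8b": _cfg(
        variant="WSNR", pole={"k": 500.0}, control={"enabled": True},
        step={"duration": 20.0},
        sweep={"param": "pole.k", "values": [500, 2000, 4000]},
    ),
    "fig8c": _cfg(
        variant="NSWR", pole={"Lr": 0.2}, control={"enabled": True},
        step={"duration": 30.0},
        sweep={"param": "pole.Lr", "values": [0.2, 0.5, 1.0]},
    ),
    "fig9": _cfg(
        scenario="walking", control={"enabled": True},
        sweep={"param": "pole.L", "values": [1.4, 1.8]},
    ),
    "fig10": _cfg(variant="WSNR", scenario="walking", control={"enabled": True},
                  pole={"k": 500.0}),
    "fig11": _cfg(variant="NSWR", scenario="walking", control={"enabled": True},
                  pole={"Lr": 1.0}),
    "fig12": _cfg(variant="WSWR", scenario="walking", control={"enabled": True},
                  pole={"k": 500.0, "Lr": 1.0}),
    "fig13": _cfg(variant="WSWR", scenario="walking", control={"enabled": True},
                  pole={"k": 500.0, "Lr": 1.0}, contact={"kds": 4000.0}),
}

#: walking suites additionally run the rigid baseline for comparison
_BASELINE_FOR = {
    "fig6d": _cfg(),
    "fig6e": _cfg(),
    "fig8b": _cfg(control={"enabled": True}, step={"duration": 20.0}),
    "fig8c": _cfg(control={"enabled": True}, step={"duration": 30.0}),
    "fig10": _cfg(scenario="walking", control={"enabled": True}),
    "fig11": _cfg(scenario="walking", control={"enabled": True}),
    "fig12": _cfg(scenario="walking", control={"enabled": True}),
    "fig13": _cfg(scenario="walking", control={"enabled": True}, contact={"kds": 4000.0}),
}


def suite(
    name: str,
    out_dir,
    step_amplitude: float | None = None,
    duration: float | None = None,
) -> dict:
    """Run a named figure suite; writes per-run CSVs plus a metrics table.

    Step suites share one step amplitude (calibrated against the rigid
    baseline when not supplied); ``duration`` overrides every run's horizon
    (useful to shrink smoke tests).
    """
    if name not in SUITES:
        raise ConfigError(f"unknown suite {name!r}; choose from {sorted(SUITES)}")
    data = SUITES[name]
    cfg = ExperimentConfig.from_dict(data)
    if duration is not None:
        key = "step" if cfg.raw["scenario"] == "step" else "walking"
        data = dict(data)
        data[key] = dict(data.get(key, {}), duration=duration)
        cfg = ExperimentConfig.from_dict(data)
    if cfg.raw["scenario"] == "step" and step_amplitude is None:
        base = ExperimentConfig.from_dict(_cfg())
        step_amplitude = calibrate_step_amplitude(
            base.build_pole(), base.build_loads(), base.build_contact()
        )
    out_dir = Path(out_dir) / name
    results = run(cfg, out_dir, step_amplitude=step_amplitude)
    if name in _BASELINE_FOR:
        bdata = _BASELINE_FOR[name]
        if duration is not None:
            key = "step" if bdata.get("scenario", "step") == "step" else "walking"
            bdata = dict(bdata)
            bdata[key] = dict(bdata.get(key, {}), duration=duration)
        bcfg = ExperimentConfig.from_dict(bdata)
        results.update(
            {
                f"baseline_{k}": v
                for k, v in run(
                    bcfg, out_dir / "baseline", step_amplitude=step_amplitude
                ).items()
            }
        )
    _write_summary_table(results, out_dir / "summary.csv")
    return results


def _write_summary_table(results: dict, path) -> None:
    rows = ["label,theta_max_deg,settling_time_s,theta_amp,theta_period,Fsx_amp,Fsx_period,Fsy_amp,Fsy_period"]
    for label, (_, metrics) in results.items():
        s = metrics.signals

        def cell(sig, key):
            value = s.get(sig, {}).get(key)
            return "" if value is None else f"{value:.6g}"

        ts = metrics.settling_time
        rows.append(
            ",".join(
                [
                    label,
                    f"{metrics.theta_max:.6g}",
                    "not_settled" if ts is None else f"{ts:.6g}",
                    cell("theta_deg", "amplitude"), cell("theta_deg", "period"),
                    cell("Fsx_N", "amplitude"), cell("Fsx_N", "period"),
                    cell("Fsy_N", "amplitude"), cell("Fsy_N", "period"),
                ]
            )
        )
    Path(path).write_text("\n".join(rows) + "\n")
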