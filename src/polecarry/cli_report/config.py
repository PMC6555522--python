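"""Experiment configuration: schema, validation, parameter-object builders.

A config (YAML or JSON) describes one scenario — a step or walking run —
plus an optional one-parameter sweep.  Every run directory receives the
fully resolved configuration next to the results so outputs are
self-describing.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ..errors import ConfigError, InvalidParameterError, VariantMismatchError
from ..model_core import (
    ContactParams,
    ControlParams,
    LoadParams,
    PoleLoadModel,
    PoleParams,
    Variant,
)

_DEFAULTS: dict = {
    "variant": "NSNR",
    "pole": {
        "L": 1.4, "Lp1": None, "Lp2": None, "k": None, "k1": None, "k2": None,
        "c1": None, "c2": None, "Lr": 0.0, "Lr1": None, "Lr2": None,
        "m0": 1.0, "I0": None, "suspension_zeta": 0.01,
    },
    "loads": {"m1": 10.0, "m2": 10.0, "I1": 0.0, "I2": 0.0},
    "contact": {"kds": 500.0, "khs": 10000.0, "cds": None, "chs": None, "zeta": 0.25},
    "control": {"enabled": True, "Kp": 1000.0, "Kd": 500.0, "Dh": 0.3},
    "model": {"include_pole_weight": False, "contact_projection": "as_printed"},
    "scenario": "step",
    "step": {
        "amplitude": None, "duration": 10.0, "rise_time": 0.3,
        "target_angle": 15.0, "at_time": 1.0,
    },
    "walking": {
        "duration": 12.0, "dt": 0.001, "step_freq": 1.8, "Ax": 0.010, "Ay": 0.025,
        "phase": math.pi / 2, "treadmill": True, "vertical_freq": None,
        "variability": "default", "trajectory_file": None, "units": None,
        "smoothing": None,
    },
    "sweep": None,
    "output": {"dt": 0.001, "band_deg": 0.1, "window": None},
    "seed": 0,
}


def _merge(defaults, user, prefix=""):
    if user is None:
        return copy.deepcopy(defaults)
    if not isinstance(user, dict):
        raise ConfigError(f"section {prefix or '<root>'} must be a mapping", field=prefix)
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        path = f"{prefix}.{key}" if prefix else key
        if key not in defaults:
            raise ConfigError(f"unknown config field {path!r}", field=path)
        if isinstance(defaults[key], dict) and key != "sweep":
            out[key] = _merge(defaults[key], value, path)
        else:
            out[key] = copy.deepcopy(value)
    return out


@dataclass
class ExperimentConfig:
    """Validated experiment description with builders for the model objects."""

    raw: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULTS))

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        cfg = cls(_merge(_DEFAULTS, data))
        cfg.validate()
        return cfg

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return cls.from_dict(data or {})

    # -- builders ---------------------------------------------------------

    def build_pole(self) -> PoleParams:
        p = self.raw["pole"]
        variant = Variant(self.raw["variant"])
        Lp1 = p["Lp1"] if p["Lp1"] is not None else p["L"] / 2.0
        Lp2 = p["Lp2"] if p["Lp2"] is not None else p["L"] / 2.0
        k1 = p["k1"] if p["k1"] is not None else p["k"]
        k2 = p["k2"] if p["k2"] is not None else p["k"]
        Lr1 = p["Lr1"] if p["Lr1"] is not None else p["Lr"]
        Lr2 = p["Lr2"] if p["Lr2"] is not None else p["Lr"]
        if not variant.has_spring:
            k1 = k2 = math.inf
            c1 = c2 = 0.0
        else:
            if k1 is None or k2 is None:
                raise ConfigError(
                    f"variant {variant.value} needs pole.k (or k1/k2)", field="pole.k"
                )
            from ..model_core import damping_from_ratio

            m1 = self.raw["loads"]["m1"]
            m2 = self.raw["loads"]["m2"]
            zeta = p["suspension_zeta"]
            c1 = p["c1"] if p["c1"] is not None else damping_from_ratio(zeta, k1, m1)
            c2 = p["c2"] if p["c2"] is not None else damping_from_ratio(zeta, k2, m2)
        if not variant.has_rope:
            Lr1 = Lr2 = 0.0
        try:
            return PoleParams(
                Lp1=Lp1, Lp2=Lp2, variant=variant, k1=k1, k2=k2, c1=c1, c2=c2,
                Lr1=Lr1, Lr2=Lr2, m0=p["m0"], I0=p["I0"],
            )
        except (InvalidParameterError, VariantMismatchError) as exc:
            raise ConfigError(str(exc), field="pole") from exc

    def build_loads(self) -> LoadParams:
        lo = self.raw["loads"]
        try:
            return LoadParams(m1=lo["m1"], m2=lo["m2"], I1=lo["I1"], I2=lo["I2"])
        except InvalidParameterError as exc:
            raise ConfigError(str(exc), field="loads") from exc

    def build_contact(self) -> ContactParams:
        co = self.raw["contact"]
        lo = self.raw["loads"]
        try:
            if co["cds"] is None or co["chs"] is None:
                built = ContactParams.from_stiffness(
                    co["kds"], co["khs"], m_ref=lo["m1"] + lo["m2"], zeta=co["zeta"]
                )
                return ContactParams(
                    kds=co["kds"], khs=co["khs"],
                    cds=co["cds"] if co["cds"] is not None else built.cds,
                    chs=co["chs"] if co["chs"] is not None else built.chs,
                )
            return ContactParams(kds=co["kds"], khs=co["khs"], cds=co["cds"], chs=co["chs"])
        except InvalidParameterError as exc:
            raise ConfigError(str(exc), field="contact") from exc

    def build_control(self) -> ControlParams:
        ct = self.raw["control"]
        try:
            return ControlParams(
                Kp=ct["Kp"], Kd=ct["Kd"], Dh=ct["Dh"], enabled=bool(ct["enabled"])
            )
        except InvalidParameterError as exc:
            raise ConfigError(str(exc), field="control") from exc

    def build_model(self) -> PoleLoadModel:
        md = self.raw["model"]
        return PoleLoadModel(
            self.build_pole(), self.build_loads(), self.build_contact(), self.build_control(),
            include_pole_weight=bool(md["include_pole_weight"]),
            contact_projection=md["contact_projection"],
        )

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        if self.raw["scenario"] not in ("step", "walking"):
            raise ConfigError(
                f"scenario must be 'step' or 'walking', got {self.raw['scenario']!r}",
                field="scenario",
            )
        try:
            Variant(self.raw["variant"])
        except ValueError as exc:
            raise ConfigError(f"unknown variant {self.raw['variant']!r}", field="variant") from exc
        if self.raw["model"]["contact_projection"] not in ("as_printed", "tangential"):
            raise ConfigError(
                "model.contact_projection must be 'as_printed' or 'tangential'",
                field="model.contact_projection",
            )
        sweep = self.raw["sweep"]
        if sweep is not None:
            if not isinstance(sweep, dict) or "param" not in sweep or "values" not in sweep:
                raise ConfigError("sweep needs 'param' and 'values'", field="sweep")
        self.build_model()  # full parameter-level validation

    # -- sweep support ----------------------------------------------------

    def sweep_configs(self):
        """Yield ``(label, config)`` per sweep value (or this config once)."""
        sweep = self.raw["sweep"]
        if sweep is None:
            yield "run", self
            return
        param, values = sweep["param"], sweep["values"]
        for value in values:
            data = copy.deepcopy(self.raw)
            data["sweep"] = None
            node = data
            *parents, leaf = param.split(".")
            for part in parents:
                if part not in node:
                    raise ConfigError(f"unknown sweep param {param!r}", field="sweep.param")
                node = node[part]
            if leaf not in node:
                raise ConfigError(f"unknown sweep param {param!r}", field="sweep.param")
            node[leaf] = value
            label = f"{param.replace('.', '_')}_{value}"
            yield label, ExperimentConfig.from_dict(data)

    def resolved(self) -> dict:
        return copy.deepcopy(self.raw)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.resolved(), fh, sort_keys=False)
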