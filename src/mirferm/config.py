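"""Run configuration: schema-validated YAML with a frozen resolved copy.

The schema rejects unknown keys so typos fail loudly. ``RunConfig.to_domain``
converts the validated document into the simulation dataclasses; every
pipeline run writes back the fully-resolved config plus its SHA-256 hash so
outputs are reproducible bit-for-bit from the frozen copy.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import control, plant_sim
from .calibration import default_templates
from .errors import ConfigError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PlantSection(_Strict):
    mu: float = 0.25
    Xmax: float = 30.0
    X0: float = 0.1
    q_glc: float = 0.08
    q_glu: float = 0.05
    G0_glc: float = 45.0
    G0_glu: float = 30.0
    V0: float = 1.0
    dt: float = 1.0 / 60.0


class NoiseSection(_Strict):
    ref_cv: float = 0.10
    probe_cv: float = 0.02
    spectral_sd: float = 1e-4
    drift_AU_per_h: float = 0.0


class ControllerSection(_Strict):
    setpoint: float = 20.0
    Kp: float = Field(default=50.0, ge=0)
    Ki: float = Field(default=0.0, ge=0)
    Kd: float = Field(default=0.0, ge=0)
    base_rate: float = Field(default=0.0, ge=0)
    max_rate: float = Field(default=200.0, gt=0)
    interval: float = Field(default=5.0, gt=0)  # minutes


class RegimeSection(_Strict):
    mode: str = "auto"
    sample_times: list[float] = [8.0, 12.0, 16.0]
    semi_interval: float = 4.0


class TriggerSection(_Strict):
    threshold: float = Field(default=20.0, gt=0)
    direction: str = "falling"


class RunConfig(_Strict):
    plant: PlantSection = PlantSection()
    noise: NoiseSection = NoiseSection()
    controllers: dict[str, ControllerSection] = {
        "glucose": ControllerSection(),
        "glutamate": ControllerSection(),
    }
    regime: RegimeSection = RegimeSection()
    trigger: TriggerSection = TriggerSection()
    horizon_h: float = 48.0
    seed: int = 0
    output_dir: str = "mirferm_out"

    # -- conversions -------------------------------------------------------
    def to_plant(self) -> plant_sim.PlantParams:
        p = self.plant
        return plant_sim.PlantParams(
            mu=p.mu, Xmax=p.Xmax, X0=p.X0,
            q={"glucose": p.q_glc, "glutamate": p.q_glu},
            G0={"glucose": p.G0_glc, "glutamate": p.G0_glu},
            V0=p.V0, dt=p.dt,
        )

    def to_noise(self) -> plant_sim.NoiseModel:
        n = self.noise
        return plant_sim.NoiseModel(
            ref_cv=n.ref_cv, probe_cv=n.probe_cv, spectral_sd=n.spectral_sd,
            drift_AU_per_h=n.drift_AU_per_h, seed=self.seed,
        )

    def to_controllers(self) -> dict[str, control.ControllerConfig]:
        return {
            a: control.ControllerConfig(
                setpoint=c.setpoint, Kp=c.Kp, Ki=c.Ki, Kd=c.Kd,
                base_rate=c.base_rate, max_rate=c.max_rate, interval=c.interval)
            for a, c in self.controllers.items()
        }

    def to_regime(self) -> control.ControlRegime:
        r = self.regime
        return control.ControlRegime(
            mode=r.mode, sample_times=tuple(r.sample_times),
            semi_interval=r.semi_interval)

    def to_trigger(self) -> control.TriggerRule:
        return control.TriggerRule(
            threshold=self.trigger.threshold, direction=self.trigger.direction)

    def to_templates(self):
        return default_templates()

    # -- serialisation -----------------------------------------------------
    def resolved_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)

    def config_hash(self) -> str:
        """SHA-256 of the scientific configuration (output paths excluded)."""
        doc = self.model_dump(exclude={"output_dir"})
        return hashlib.sha256(
            yaml.safe_dump(doc, sort_keys=True).encode()).hexdigest()


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration file."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(doc)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from None


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(
        f"# config_sha256={cfg.config_hash()}\n{cfg.resolved_yaml()}")
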