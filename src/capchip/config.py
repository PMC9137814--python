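"""Shared configuration: schema-validated YAML for all modules.

One platform config file centralises electrode geometry, material stack,
readout constants, solver settings and extraction thresholds.  Unknown keys
are rejected, missing sections fall back to the documented defaults (an empty
file is a valid config), and the effective values are echoed to the log so a
run is reproducible from its log alone.
"""

from __future__ import annotations

import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .circuit_model import ElectrodeGeometry, MaterialStack
from .extraction import ExtractionSettings
from .field_solver import SolverSettings
from .readout_sim import ReadoutConfig
from .scenario_gen import ChamberLayout, Run, Scenario

log = logging.getLogger("capchip")

__all__ = ["PlatformConfig", "load_config", "save_config",
           "load_scenario", "save_scenario", "ConfigError"]


class ConfigError(ValueError):
    """A config file violates the schema."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometrySection(_Strict):
    n_fingers: int = 5
    finger_width: float = 12.0
    gap: float = 12.0
    finger_length: float = 228.0
    thickness: float = 0.9
    area: float = 7056.0
    perimeter: float | None = None
    coinciding_perimeter: float | None = None

    def build(self) -> ElectrodeGeometry:
        return ElectrodeGeometry(**self.model_dump())


class MaterialsSection(_Strict):
    eps_SiO2: float = 3.9
    eps_PL: float = 9.5
    eps_air: float = 1.0
    eps_cell: float = 20.0
    eps_water: float = 80.0
    d_PL: float = 0.010
    d_eff_air: float = 2.8686
    d_eff_cell: float = 5.0
    alpha1: float = 0.0
    alpha2: float = 0.0

    def build(self) -> MaterialStack:
        return MaterialStack(**self.model_dump())


class ReadoutSection(_Strict):
    c_ref_min: float = 200.0
    c_ref_max: float = 1270.0
    c_ref_step: float = 10.0
    c_internal: float = 400.0
    resolution: float = 0.416
    idr: float = 400.0
    counter_bits: int = 16
    n0: int | None = None
    gate_time: float = 1.0
    vdd: float = 3.3
    vth: float = 0.6
    noise_sd: float = 1.0
    n_average: int = 1
    seed: int = 0

    def build(self) -> ReadoutConfig:
        return ReadoutConfig(**self.model_dump())


class SolverSection(_Strict):
    resolution: float = 0.5
    tolerance: float = 1e-8
    margin_factor: float = 3.0
    max_spacing: float = 16.0
    growth: float = 1.3
    oxide_depth: float = 2.0
    v_drive: float = 2.7

    def build(self) -> SolverSettings:
        return SolverSettings(**self.model_dump())


class ExtractionSection(_Strict):
    drop_fraction: float = 0.10
    steady_window_s: float = 30.0
    steady_sd_fF: float = 1.0

    def build(self) -> ExtractionSettings:
        return ExtractionSettings(**self.model_dump())


class PlatformConfig(_Strict):
    """Validated top-level configuration."""

    geometry: GeometrySection = GeometrySection()
    materials: MaterialsSection = MaterialsSection()
    readout: ReadoutSection = ReadoutSection()
    solver: SolverSection = SolverSection()
    extraction: ExtractionSection = ExtractionSection()
    seed: int = 0

    def objects(self):
        """Instantiate the domain objects (geometry, stack, readout, solver,
        extraction settings)."""
        return (self.geometry.build(), self.materials.build(), self.readout.build(),
                self.solver.build(), self.extraction.build())


def load_config(path: str | Path | None = None) -> PlatformConfig:
    """Read and validate a YAML platform config; None/empty file -> defaults."""
    data = {}
    if path is not None:
        raw = Path(path).read_text()
        data = yaml.safe_load(raw) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    try:
        cfg = PlatformConfig(**data)
        cfg.objects()  # surface physical-domain violations at load time
    except (ValidationError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    log.info("effective config: %s", cfg.model_dump())
    return cfg


def save_config(cfg: PlatformConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))


# ---------------------------------------------------------------- scenarios

class RunSection(_Strict):
    t_deposit: float
    evap_duration: float = 240.0
    neutrophil_count: int = 1
    epithelial_count: int = 13
    water_start: float = 400.0
    water_end: float = 5.0


class ChamberSection(_Strict):
    width: float = 350.0
    height: float = 600.0
    electrode_size: tuple[float, float] = (228.0, 108.0)
    left_center: tuple[float, float] = (175.0, 175.0)
    right_center: tuple[float, float] = (175.0, 425.0)


class ScenarioFile(_Strict):
    duration: float = 600.0
    sweep_interval: float = 5.0
    runs: list[RunSection] = []
    wash_events: list[float] = []
    bubble_events: list[tuple[float, float, float]] = []
    droplet_volume: float = 1.0
    chamber: ChamberSection = ChamberSection()
    neutrophil_radius: float = 6.0
    epithelial_radius: float = 25.0
    wet_threshold: float = 1.0
    moist_excess: float = 20.0
    moist_tau: float = 10.0

    def build(self) -> Scenario:
        d = self.model_dump()
        d["runs"] = tuple(Run(**r) for r in self.model_dump()["runs"])
        d["wash_events"] = tuple(d["wash_events"])
        d["bubble_events"] = tuple(tuple(b) for b in d["bubble_events"])
        d["chamber"] = ChamberLayout(
            width=self.chamber.width, height=self.chamber.height,
            electrode_size=tuple(self.chamber.electrode_size),
            left_center=tuple(self.chamber.left_center),
            right_center=tuple(self.chamber.right_center),
        )
        return Scenario(**d)


def load_scenario(path: str | Path) -> Scenario:
    data = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return ScenarioFile(**data).build()
    except (ValidationError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    d = {
        "duration": scenario.duration,
        "sweep_interval": scenario.sweep_interval,
        "runs": [
            {"t_deposit": r.t_deposit, "evap_duration": r.evap_duration,
             "neutrophil_count": r.neutrophil_count,
             "epithelial_count": r.epithelial_count,
             "water_start": r.water_start, "water_end": r.water_end}
            for r in scenario.runs
        ],
        "wash_events": list(scenario.wash_events),
        "bubble_events": [list(b) for b in scenario.bubble_events],
        "droplet_volume": scenario.droplet_volume,
        "chamber": {
            "width": scenario.chamber.width, "height": scenario.chamber.height,
            "electrode_size": list(scenario.chamber.electrode_size),
            "left_center": list(scenario.chamber.left_center),
            "right_center": list(scenario.chamber.right_center),
        },
        "neutrophil_radius": scenario.neutrophil_radius,
        "epithelial_radius": scenario.epithelial_radius,
        "wet_threshold": scenario.wet_threshold,
        "moist_excess": scenario.moist_excess,
        "moist_tau": scenario.moist_tau,
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
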