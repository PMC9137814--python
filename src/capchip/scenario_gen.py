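"""Synthetic physical scenarios: droplets, evaporation, cell deposits, washes.

A :class:`Scenario` scripts what happens on the chip surface over time — a
1 µL droplet is pipetted on, saturates the readout while bulk water is
present, evaporates (water layer receding from 400 µm to 5 µm and then gone),
leaves cells behind whose electrode coverage raises the equivalent
capacitance, accumulates over consecutive unwashed runs, resets after a wash,
and optionally shows a bubble artifact (alternating output excursions).

Cell deposition is modelled as uniform random placement of disks over the
sample chamber (the hydrodynamics of droplet evaporation are not simulated);
the resulting *confluence* of each electrode is the covered fraction of its
metal area, computed from the exact union of the disks.  Default cell counts
follow the hemocytometer estimates for oral samples: about 7 neutrophils per
10 µL and about 13 epithelial cells per µL of sample (both printed unit
conventions kept verbatim as separate densities); radii default to 6 µm
(neutrophil) and 25 µm (epithelial) — plausible values, not measured ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Point, box
from shapely.ops import unary_union

from .circuit_model import (
    CellDeposit,
    ElectrodeGeometry,
    InvalidParameterError,
    MaterialStack,
    cell_equivalent,
)

__all__ = [
    "ChamberLayout",
    "Run",
    "Scenario",
    "DepositionOutcome",
    "place_cells",
    "capacitance_trace",
    "ground_truth_events",
    "make_preset",
    "PRESETS",
]

#: printed hemocytometer densities for the oral samples
NEUTROPHILS_PER_10UL = 7.0
EPITHELIAL_PER_UL = 13.0


@dataclass(frozen=True)
class ChamberLayout:
    """Sample chamber with the two electrodes it contains (µm)."""

    width: float = 350.0
    height: float = 600.0
    # electrode rectangles (finger_length × span), centred horizontally
    electrode_size: tuple[float, float] = (228.0, 108.0)
    left_center: tuple[float, float] = (175.0, 175.0)
    right_center: tuple[float, float] = (175.0, 425.0)

    def electrode_box(self, channel: str):
        cx, cy = self.left_center if channel == "left" else self.right_center
        w, h = self.electrode_size
        return box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


@dataclass(frozen=True)
class Run:
    """One droplet deposition followed by evaporation."""

    t_deposit: float  # s
    evap_duration: float = 240.0  # s, droplet lifetime on the chip
    neutrophil_count: int = 1
    epithelial_count: int = 13
    water_start: float = 400.0  # µm, initial water layer
    water_end: float = 5.0  # µm, thinnest resolved layer before dry-out

    def __post_init__(self) -> None:
        if self.neutrophil_count < 0 or self.epithelial_count < 0:
            raise InvalidParameterError("cell counts must be >= 0")
        if self.evap_duration <= 0:
            raise InvalidParameterError("evap_duration must be > 0")
        if not 0 < self.water_end <= self.water_start:
            raise InvalidParameterError("need 0 < water_end <= water_start")

    def water_thickness(self, t: float) -> float:
        """Water layer thickness at time t: linear recession, then gone."""
        if t < self.t_deposit:
            return 0.0
        if t >= self.t_deposit + self.evap_duration:
            return 0.0
        frac = (t - self.t_deposit) / self.evap_duration
        return self.water_start + (self.water_end - self.water_start) * frac


@dataclass(frozen=True)
class Scenario:
    """Scripted physical timeline of an experiment."""

    duration: float = 600.0  # s
    sweep_interval: float = 5.0  # s between bank sweeps
    runs: tuple[Run, ...] = ()
    wash_events: tuple[float, ...] = ()  # times (s) at which deposits reset
    bubble_events: tuple[tuple[float, float, float], ...] = ()  # (start, end, amp fF)
    droplet_volume: float = 1.0  # µL
    chamber: ChamberLayout = field(default_factory=ChamberLayout)
    neutrophil_radius: float = 6.0  # µm (assumption, not printed)
    epithelial_radius: float = 25.0  # µm (assumption, not printed)
    wet_threshold: float = 1.0  # µm of water above which the readout saturates
    moist_excess: float = 20.0  # fF, extra capacitance right after dry-out
    moist_tau: float = 10.0  # s, decay constant of the moist transient

    def __post_init__(self) -> None:
        if self.sweep_interval <= 0:
            raise InvalidParameterError("sweep_interval must be > 0")
        spans = sorted((r.t_deposit, r.t_deposit + r.evap_duration) for r in self.runs)
        for (a0, a1), (b0, b1) in zip(spans[:-1], spans[1:]):
            if b0 < a1:
                raise InvalidParameterError("runs must not overlap in time")

    def times(self) -> np.ndarray:
        return np.arange(0.0, self.duration + 1e-9, self.sweep_interval)


@dataclass(frozen=True)
class DepositionOutcome:
    """Where the cells landed and what they cover."""

    conf_left: float
    conf_right: float
    cell_positions: tuple[tuple[float, float, float, str], ...]  # x, y, r, type

    def __post_init__(self) -> None:
        for c in (self.conf_left, self.conf_right):
            if not 0.0 <= c <= 1.0:
                raise InvalidParameterError("confluence must lie in [0, 1]")


def _coverage(disks: list[tuple[float, float, float, str]], chamber: ChamberLayout,
              channel: str) -> float:
    if not disks:
        return 0.0
    elec = chamber.electrode_box(channel)
    union = unary_union([Point(x, y).buffer(r, quad_segs=32) for x, y, r, _ in disks])
    return min(1.0, union.intersection(elec).area / elec.area)


def place_cells(
    run: Run,
    geom: ElectrodeGeometry,
    seed: int,
    chamber: ChamberLayout | None = None,
    neutrophil_radius: float = 6.0,
    epithelial_radius: float = 25.0,
) -> DepositionOutcome:
    """Uniform random disk placement of one run's cells over the chamber.

    Confluence of each electrode is the exact covered fraction of its area
    (union of disks, overlap-aware).
    """
    chamber = chamber or ChamberLayout()
    rng = np.random.default_rng(seed)
    disks: list[tuple[float, float, float, str]] = []
    for count, radius, kind in (
        (run.neutrophil_count, neutrophil_radius, "neutrophil"),
        (run.epithelial_count, epithelial_radius, "epithelial"),
    ):
        xs = rng.uniform(0.0, chamber.width, count)
        ys = rng.uniform(0.0, chamber.height, count)
        disks.extend((float(x), float(y), radius, kind) for x, y in zip(xs, ys))
    return DepositionOutcome(
        conf_left=_coverage(disks, chamber, "left"),
        conf_right=_coverage(disks, chamber, "right"),
        cell_positions=tuple(disks),
    )


def capacitance_trace(
    scenario: Scenario,
    geom: ElectrodeGeometry,
    stack: MaterialStack,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Per-channel sensing capacitance over time.

    Returns ``{"left": df, "right": df}`` with columns
    ``time_s, c_sense_fF, wet``.  Dry phases evaluate the equivalent-circuit
    model at the cumulative confluence; droplet phases raise the wet flag
    (readout saturation); right after dry-out a decaying moist transient is
    superimposed (residual moisture on the freshly deposited cells); washes
    reset the deposit; bubbles alternate the output between two levels.
    """
    rng = np.random.default_rng(seed)
    times = scenario.times()
    # one placement per run, seeded reproducibly from the scenario seed
    run_seeds = rng.integers(0, 2**31 - 1, size=max(1, len(scenario.runs)))
    placements = [
        place_cells(run, geom, int(run_seeds[i]), scenario.chamber,
                    scenario.neutrophil_radius, scenario.epithelial_radius)
        for i, run in enumerate(scenario.runs)
    ]

    frames: dict[str, pd.DataFrame] = {}
    for channel in ("left", "right"):
        c_vals = np.empty(times.size)
        wet = np.zeros(times.size, dtype=bool)
        active_disks: list[tuple[float, float, float, str]] = []
        deposited: set[int] = set()
        conf = 0.0
        last_dryout: float | None = None
        wash_done: set[float] = set()
        for k, t in enumerate(times):
            for tw in scenario.wash_events:
                if t >= tw and tw not in wash_done:
                    active_disks = []
                    conf = 0.0
                    last_dryout = None
                    wash_done.add(tw)
            h = 0.0
            for i, run in enumerate(scenario.runs):
                h = max(h, run.water_thickness(t))
                t_dry = run.t_deposit + run.evap_duration
                if t >= t_dry and i not in deposited:
                    # the run's cells become part of the cumulative deposit
                    active_disks = active_disks + list(placements[i].cell_positions)
                    conf = _coverage(active_disks, scenario.chamber, channel)
                    deposited.add(i)
                    last_dryout = t_dry
            if h > scenario.wet_threshold:
                wet[k] = True
                c_vals[k] = np.nan  # saturated: capacitance not representable
                continue
            c = cell_equivalent(CellDeposit(conf1=conf, conf2=conf), geom, stack)
            if last_dryout is not None and t >= last_dryout:
                c += scenario.moist_excess * np.exp(-(t - last_dryout) / scenario.moist_tau)
            for (b0, b1, amp) in scenario.bubble_events:
                if b0 <= t < b1 and k % 2 == 0:
                    c += amp  # alternating bubble excursion
            c_vals[k] = c
        # deposition state is channel-independent bookkeeping; reset sets for
        # the second channel by recomputing from scratch
        frames[channel] = pd.DataFrame(
            {"time_s": times, "c_sense_fF": c_vals, "wet": wet}
        )
    return frames


def ground_truth_events(scenario: Scenario) -> list[dict[str, float]]:
    """Per-run nominal event times implied by the scenario script."""
    out = []
    for run in scenario.runs:
        t_dry = run.t_deposit + run.evap_duration
        out.append({
            "sample_introduced_at": run.t_deposit,
            "evaporation_onset_at": t_dry,
            "steady_state_from": t_dry + 5.0 * scenario.moist_tau,
        })
    return out


def _poisson_counts(rng: np.random.Generator, volume_ul: float) -> tuple[int, int]:
    neut = int(rng.poisson(NEUTROPHILS_PER_10UL / 10.0 * volume_ul))
    epi = int(rng.poisson(EPITHELIAL_PER_UL * volume_ul))
    return neut, epi


def make_preset(name: str, seed: int = 0) -> Scenario:
    """Canonical scenarios: single-run, four-run, two-run-accumulation, bubble."""
    rng = np.random.default_rng(seed)
    if name == "single-run":
        n, e = _poisson_counts(rng, 1.0)
        return Scenario(duration=600.0, runs=(
            Run(t_deposit=60.0, neutrophil_count=n, epithelial_count=e),
        ))
    if name == "two-run-accumulation":
        runs = []
        for t in (60.0, 600.0):
            n, e = _poisson_counts(rng, 1.0)
            runs.append(Run(t_deposit=t, neutrophil_count=n, epithelial_count=e))
        return Scenario(duration=1200.0, runs=tuple(runs))
    if name == "four-run":
        runs = []
        for t in (60.0, 600.0, 1140.0, 1680.0):
            n, e = _poisson_counts(rng, 1.0)
            runs.append(Run(t_deposit=t, neutrophil_count=n, epithelial_count=e))
        return Scenario(duration=2400.0, runs=tuple(runs),
                        wash_events=(2220.0,))
    if name == "bubble":
        return Scenario(duration=300.0, runs=(),
                        bubble_events=((60.0, 240.0, 30.0),))
    raise InvalidParameterError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")


PRESETS = ("single-run", "two-run-accumulation", "four-run", "bubble")
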