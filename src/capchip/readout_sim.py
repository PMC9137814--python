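"""Readout-chain simulator: differential capacitance -> pulse counts.

The on-chip chain converts the difference between the sensing-side capacitance
(a 400 fF internal capacitor, plus the IDE when its transmission gate is on)
and a programmable reference capacitor into a current, a current-controlled
oscillator frequency, and finally a gated pulse count.  The published
specification gives the bank range (200–1270 fF in 10 fF steps), the
resolution (416 aF per count) and the input dynamic range (±400 fF); the
unpublished gain/intercept constants are collapsed into a linear model

    N = clip( round(N0 + clip(C_sense - C_ref, -IDR, +IDR) / resolution),
              0, 2^bits - 1 )

with N0 at mid-scale of a 16-bit counter.  Sweeping the bank yields a 2D
curve per timestamp; stacking timestamps yields the 3D "footprint" that the
extraction algorithm consumes.  Bulk liquid on the non-passivated electrodes
saturates the chain; a saturated sweep is emitted at the clip rail across the
entire bank.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .circuit_model import InvalidParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .scenario_gen import Scenario

__all__ = ["ReadoutConfig", "Footprint3D", "pulses_from_capacitance",
           "sweep_reference", "simulate_experiment"]

CHANNELS = ("left", "right")


@dataclass(frozen=True)
class ReadoutConfig:
    """Reference bank, conversion constants and noise of the readout chain."""

    c_ref_min: float = 200.0  # fF
    c_ref_max: float = 1270.0  # fF
    c_ref_step: float = 10.0  # fF
    c_internal: float = 400.0  # fF, always-connected parallel capacitor
    resolution: float = 0.416  # fF per pulse (416 aF)
    idr: float = 400.0  # fF, differential clip range
    counter_bits: int = 16
    n0: int | None = None  # balance-point count; default mid-scale
    gate_time: float = 1.0  # s, pulse-count gate (collapsed into resolution)
    vdd: float = 3.3  # V
    vth: float = 0.6  # V
    noise_sd: float = 1.0  # pulses, additive Gaussian on counts
    n_average: int = 1  # sweeps averaged per timestamp
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.c_ref_min < self.c_ref_max:
            raise InvalidParameterError("c_ref_min must be < c_ref_max")
        n = (self.c_ref_max - self.c_ref_min) / self.c_ref_step
        if abs(n - round(n)) > 1e-9:
            raise InvalidParameterError("c_ref_step must divide the bank range")
        if self.resolution <= 0 or self.idr <= 0:
            raise InvalidParameterError("resolution and idr must be > 0")
        if self.counter_bits < 1:
            raise InvalidParameterError("counter_bits must be >= 1")
        if self.noise_sd < 0 or self.n_average < 1:
            raise InvalidParameterError("noise_sd >= 0 and n_average >= 1 required")

    @property
    def n_max(self) -> int:
        return 2**self.counter_bits - 1

    @property
    def balance_count(self) -> int:
        return self.n_max // 2 if self.n0 is None else self.n0

    @property
    def bank(self) -> np.ndarray:
        """Reference capacitor values, fF, strictly increasing."""
        n = int(round((self.c_ref_max - self.c_ref_min) / self.c_ref_step))
        return self.c_ref_min + self.c_ref_step * np.arange(n + 1)

    @property
    def drive_voltage(self) -> float:
        """Electrode bias: one threshold below the supply rail, V."""
        return self.vdd - self.vth

    @property
    def saturation_rail(self) -> int:
        """Pulse count emitted across the bank when the chain saturates (wet)."""
        return int(np.clip(round(self.balance_count - self.idr / self.resolution),
                           0, self.n_max))


@dataclass
class Footprint3D:
    """Chip output surface: pulse counts over time × reference value × channel.

    Stored long-form as a DataFrame with columns
    ``time_s, channel, gate, c_ref_fF, pulses, saturated``.
    """

    frame: pd.DataFrame

    COLUMNS = ["time_s", "channel", "gate", "c_ref_fF", "pulses", "saturated"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise InvalidParameterError(f"footprint frame missing columns: {missing}")

    def sweeps(self, channel: str, gate: str | None = "on"):
        """Yield (time, c_ref array, mean pulses array, all-saturated flag).

        Multiple sweeps recorded at one timestamp are averaged.
        """
        df = self.frame[self.frame["channel"] == channel]
        if gate is not None:
            df = df[df["gate"] == gate]
        for t, grp in df.groupby("time_s", sort=True):
            curve = grp.groupby("c_ref_fF", sort=True)["pulses"].mean()
            saturated = bool(grp["saturated"].all())
            yield float(t), curve.index.to_numpy(float), curve.to_numpy(float), saturated

    def times(self, channel: str) -> np.ndarray:
        df = self.frame[(self.frame["channel"] == channel) & (self.frame["gate"] == "on")]
        return np.sort(df["time_s"].unique())


def pulses_from_capacitance(
    c_sense: float, c_ref: float, cfg: ReadoutConfig, wet: bool = False
) -> int:
    """Counter output for one (sensing, reference) pair.

    ``c_sense`` is the total sensing-side capacitance presented to the
    converter (internal capacitor plus IDE when gated on).  ``wet`` forces the
    saturated rail regardless of the differential value.
    """
    bank = cfg.bank
    if c_ref < bank[0] - 1e-9 or c_ref > bank[-1] + 1e-9:
        raise InvalidParameterError(
            f"c_ref {c_ref} fF outside bank [{bank[0]}, {bank[-1]}]"
        )
    if wet:
        return cfg.saturation_rail
    diff = float(np.clip(c_sense - c_ref, -cfg.idr, cfg.idr))
    n = cfg.balance_count + diff / cfg.resolution
    return int(np.clip(round(n), 0, cfg.n_max))


def sweep_reference(
    c_sense: float,
    cfg: ReadoutConfig,
    gate_on: bool = True,
    wet: bool = False,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One bank sweep: columns c_ref_fF, pulses, saturated.

    ``c_sense`` here is the *IDE-side* capacitance (offset plus sample); the
    internal 400 fF capacitor is added inside, and with the transmission gate
    off only the internal capacitor is seen.  Gaussian pulse noise is applied
    when an ``rng`` is supplied.
    """
    total = cfg.c_internal + (c_sense if gate_on else 0.0)
    bank = cfg.bank
    pulses = np.array(
        [pulses_from_capacitance(total, cr, cfg, wet=wet) for cr in bank], dtype=float
    )
    if rng is not None and cfg.noise_sd > 0 and not wet:
        pulses = np.clip(np.round(pulses + rng.normal(0.0, cfg.noise_sd, pulses.size)),
                         0, cfg.n_max)
    return pd.DataFrame({
        "c_ref_fF": bank,
        "pulses": pulses.astype(int),
        "saturated": bool(wet),
    })


def simulate_experiment(
    scenario: "Scenario",
    cfg: ReadoutConfig,
    geom=None,
    stack=None,
    seed: int | None = None,
) -> Footprint3D:
    """Run a scripted physical timeline through the readout chain.

    For each sampling time the sensing capacitance of each electrode is taken
    from the scenario's capacitance trace (equivalent-circuit surrogate), the
    reference bank is swept (``n_average`` noisy sweeps per timestamp), and an
    initial gate-off sweep is emitted first so the extraction algorithm can
    determine the IDE offset.
    """
    from .circuit_model import ElectrodeGeometry, MaterialStack
    from .scenario_gen import capacitance_trace

    geom = geom or ElectrodeGeometry()
    stack = stack or MaterialStack()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    traces = capacitance_trace(scenario, geom, stack, seed=seed)
    rows: list[pd.DataFrame] = []
    for channel in CHANNELS:
        tr = traces[channel]
        t0 = float(tr["time_s"].iloc[0])
        for rep in range(cfg.n_average):
            sw = sweep_reference(0.0, cfg, gate_on=False, wet=False, rng=rng)
            sw.insert(0, "gate", "off")
            sw.insert(0, "channel", channel)
            sw.insert(0, "time_s", t0)
            rows.append(sw)
        for t, c_sense, wet in tr.itertuples(index=False):
            for rep in range(cfg.n_average):
                sw = sweep_reference(float(c_sense), cfg, gate_on=True,
                                     wet=bool(wet), rng=rng)
                sw.insert(0, "gate", "on")
                sw.insert(0, "channel", channel)
                sw.insert(0, "time_s", float(t))
                rows.append(sw)
    frame = pd.concat(rows, ignore_index=True)
    return Footprint3D(frame=frame)
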