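"""Calibration-free capacitance extraction from footprint curves.

The chip reports pulse counts versus a swept reference capacitance.  Because
the converter balances when the sensing side equals the reference side, any
extra capacitance on the sensing side translates the pulses-vs-C_ref curve to
the *right* along the reference axis.  The extraction therefore never needs a
gain calibration:

1. with the IDE disconnected (transmission gate off), read the curve of the
   bare internal capacitor and note its output level at C_ref = 400 fF;
2. reconnect the IDE and measure the rightward shift of the curve at that
   level — the shift *is* the IDE offset capacitance C_IDE;
3. for every later sweep, the further rightward shift at the level read at
   C_ref = 400 + C_IDE is the sample-induced capacitance change ΔC.

A sweep that sits on the rail across the whole bank (bulk liquid on the
electrodes) never attains the level; such sweeps are encoded as ΔC = 0 with a
saturation flag.  Sub-step positions are obtained by linear interpolation
between the 10 fF bank points, with the crossing searched on the maximal
monotone non-increasing segment and ties broken toward the lowest reference
value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit_model import InvalidParameterError
from .readout_sim import CHANNELS, Footprint3D, ReadoutConfig

__all__ = [
    "SaturatedSweepError",
    "ExtractionSettings",
    "ExtractionResult",
    "output_at",
    "rightward_shift",
    "extract_offset",
    "extract_delta",
    "time_resolved",
]


class SaturatedSweepError(RuntimeError):
    """The level is not attained: the sweep is saturated across the bank."""


@dataclass(frozen=True)
class ExtractionSettings:
    """Event-detection thresholds of the time-resolved extraction."""

    drop_fraction: float = 0.10  # "sharp drop": ΔC falls by >10% of the
    # saturation-adjacent value within one sweep interval
    steady_window_s: float = 30.0  # rolling window for steady-state detection
    steady_sd_fF: float = 1.0  # ΔC standard deviation below which it is steady


@dataclass
class ExtractionResult:
    """Offset capacitance, ΔC time series and detected events per channel."""

    c_ide: dict[str, float]
    delta_c: pd.DataFrame  # columns time_s, channel, delta_c_fF, saturated
    events: dict[str, dict[str, float | None]]


def output_at(c_ref: np.ndarray, pulses: np.ndarray, at: float) -> float:
    """Fractional pulse count at an arbitrary reference value (linear interp)."""
    c_ref = np.asarray(c_ref, dtype=float)
    pulses = np.asarray(pulses, dtype=float)
    if at < c_ref[0] - 1e-9 or at > c_ref[-1] + 1e-9:
        raise InvalidParameterError(
            f"reference value {at} fF outside curve domain [{c_ref[0]}, {c_ref[-1]}]"
        )
    return float(np.interp(at, c_ref, pulses))


def _first_crossing(c_ref: np.ndarray, pulses: np.ndarray, level: float) -> float | None:
    """Reference value where the curve first descends through ``level``.

    Scans the bank from low to high reference and returns the linearly
    interpolated crossing of the first strictly descending segment bracketing
    the level; ``None`` when the level is never attained (rail-flat sweep).
    """
    y = np.asarray(pulses, dtype=float)
    x = np.asarray(c_ref, dtype=float)
    for i in range(y.size - 1):
        if y[i] >= level >= y[i + 1] and y[i] > y[i + 1]:
            frac = (y[i] - level) / (y[i] - y[i + 1])
            return float(x[i] + frac * (x[i + 1] - x[i]))
        if y[i] == level == y[i + 1] and (i == 0 or y[i - 1] > level):
            return float(x[i])  # flat tie at the level: lowest reference wins
    return None


def rightward_shift(
    ref_curve: tuple[np.ndarray, np.ndarray],
    meas_curve: tuple[np.ndarray, np.ndarray],
    level: float,
) -> float:
    """Horizontal shift (fF) of ``meas_curve`` relative to ``ref_curve``.

    Both curves are located where they descend through ``level``; raises
    :class:`SaturatedSweepError` when either curve never attains it.
    """
    x_ref = _first_crossing(*ref_curve, level)
    x_meas = _first_crossing(*meas_curve, level)
    if x_ref is None or x_meas is None:
        raise SaturatedSweepError("level not attained by a monotone crossing")
    return x_meas - x_ref


def extract_offset(
    gate_off_curve: tuple[np.ndarray, np.ndarray],
    gate_on_curve: tuple[np.ndarray, np.ndarray],
    cfg: ReadoutConfig,
) -> float:
    """IDE offset capacitance from the gate-off/gate-on curve pair, fF."""
    level = output_at(*gate_off_curve, cfg.c_internal)
    return rightward_shift(gate_off_curve, gate_on_curve, level)


def extract_delta(
    baseline_curve: tuple[np.ndarray, np.ndarray],
    sample_curve: tuple[np.ndarray, np.ndarray],
    c_ide: float,
    cfg: ReadoutConfig,
) -> tuple[float, bool]:
    """Sample-induced capacitance change, fF, with its saturation flag.

    A saturated sample sweep is zero-encoded: returns ``(0.0, True)``.
    """
    level = output_at(*baseline_curve, cfg.c_internal + c_ide)
    try:
        delta = rightward_shift(baseline_curve, sample_curve, level)
    except SaturatedSweepError:
        return 0.0, True
    return max(delta, 0.0), False


def _detect_events(
    times: np.ndarray,
    deltas: np.ndarray,
    saturated: np.ndarray,
    sweep_interval: float,
    settings: ExtractionSettings,
) -> dict[str, float | None]:
    """Locate sample introduction, evaporation onset and steady state."""
    events: dict[str, float | None] = {
        "sample_introduced_at": None,
        "evaporation_onset_at": None,
        "steady_state_from": None,
    }
    sat_idx = np.flatnonzero(saturated)
    onset_i = None
    if sat_idx.size:
        events["sample_introduced_at"] = float(times[sat_idx[0]])
        # onset of evaporation: the first finite sweep after saturation is the
        # sharp drop from the rail; later finite-to-finite drops larger than
        # drop_fraction of the previous value also qualify, first one wins
        after = np.flatnonzero(~saturated & (np.arange(times.size) > sat_idx[0]))
        if after.size:
            onset_i = int(after[0])
            events["evaporation_onset_at"] = float(times[onset_i])
    window = max(2, int(round(settings.steady_window_s / sweep_interval)))
    start = onset_i if onset_i is not None else 0
    for k in range(start, times.size - window + 1):
        seg = deltas[k : k + window]
        if saturated[k : k + window].any():
            continue
        if np.std(seg) < settings.steady_sd_fF:
            events["steady_state_from"] = float(times[k])
            break
    return events


def time_resolved(
    footprint: Footprint3D,
    cfg: ReadoutConfig,
    settings: ExtractionSettings | None = None,
) -> ExtractionResult:
    """Run the extraction over every sweep of a footprint.

    Requires an initial gate-off sweep per channel (to determine C_IDE) and a
    non-saturated first gate-on sweep (the pre-sample baseline).
    """
    settings = settings or ExtractionSettings()
    c_ide: dict[str, float] = {}
    events: dict[str, dict[str, float | None]] = {}
    rows: list[dict] = []
    channels = [c for c in CHANNELS if (footprint.frame["channel"] == c).any()]
    for channel in channels:
        off_sweeps = list(footprint.sweeps(channel, gate="off"))
        if not off_sweeps:
            raise InvalidParameterError(
                f"footprint has no gate-off sweep for channel {channel!r}"
            )
        _, x_off, y_off, _ = off_sweeps[0]
        on_sweeps = list(footprint.sweeps(channel, gate="on"))
        if not on_sweeps:
            raise InvalidParameterError(f"no gate-on sweeps for channel {channel!r}")
        t0, x_base, y_base, sat0 = on_sweeps[0]
        if sat0:
            raise InvalidParameterError("pre-sample baseline sweep is saturated")
        c_ide[channel] = extract_offset((x_off, y_off), (x_base, y_base), cfg)

        times, deltas, sats = [], [], []
        for t, x, y, sat in on_sweeps:
            if sat:
                d, s = 0.0, True
            else:
                d, s = extract_delta((x_base, y_base), (x, y), c_ide[channel], cfg)
            times.append(t)
            deltas.append(d)
            sats.append(s)
            rows.append({"time_s": t, "channel": channel,
                         "delta_c_fF": d, "saturated": s})
        times_a = np.asarray(times)
        interval = float(np.median(np.diff(times_a))) if times_a.size > 1 else 1.0
        events[channel] = _detect_events(
            times_a, np.asarray(deltas), np.asarray(sats), interval, settings
        )
    return ExtractionResult(
        c_ide=c_ide,
        delta_c=pd.DataFrame(rows, columns=["time_s", "channel", "delta_c_fF", "saturated"]),
        events=events,
    )
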