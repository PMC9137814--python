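"""Footprint CSV dialect: the chip's 3D output surface on disk.

Long-form UTF-8 CSV with a mandatory header line
``time_s,channel,gate,c_ref_fF,pulses,saturated``, '.' decimal separator,
capacitance in fF with three decimals.  Human-inspectable and diff-able; the
reader is lossless with respect to pulses, flags and both axes.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .readout_sim import Footprint3D

__all__ = ["read_footprint", "write_footprint", "FootprintFormatError"]

_DTYPES = {"time_s": float, "channel": str, "gate": str,
           "c_ref_fF": float, "pulses": int, "saturated": bool}


class FootprintFormatError(ValueError):
    """Malformed footprint file (bad header or row)."""


def write_footprint(fp: Footprint3D, path: str | Path) -> None:
    df = fp.frame[Footprint3D.COLUMNS].copy()
    df["c_ref_fF"] = df["c_ref_fF"].map(lambda v: f"{v:.3f}")
    df["time_s"] = df["time_s"].map(lambda v: f"{v:.3f}")
    df["saturated"] = df["saturated"].astype(bool)
    df.to_csv(path, index=False)


def read_footprint(path: str | Path) -> Footprint3D:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise FootprintFormatError(f"{path}: {exc}") from exc
    expected = Footprint3D.COLUMNS
    if list(df.columns) != expected:
        raise FootprintFormatError(
            f"{path}: header must be {','.join(expected)}, got {','.join(df.columns)}"
        )
    out = {}
    for col, typ in _DTYPES.items():
        series = df[col]
        if typ is bool:
            bad = ~series.isin(["True", "False"])
            if bad.any():
                raise FootprintFormatError(
                    f"{path}: line {bad.idxmax() + 2}: invalid boolean in {col!r}"
                )
            out[col] = series == "True"
        elif typ is str:
            out[col] = series
        else:
            try:
                out[col] = series.astype(typ)
            except ValueError as exc:
                bad_line = None
                for i, v in enumerate(series):
                    try:
                        typ(v)
                    except ValueError:
                        bad_line = i + 2
                        break
                raise FootprintFormatError(
                    f"{path}: line {bad_line}: invalid {typ.__name__} in {col!r}"
                ) from exc
    return Footprint3D(frame=pd.DataFrame(out))
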