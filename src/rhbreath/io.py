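"""File and telemetry I/O.

Time series travel as plain CSV with a ``time_s,value`` header and an
optional ``# units: <tag>`` comment line. Raw sensor telemetry arrives as
newline-delimited 8-character hexadecimal frames, each a 32-bit IEEE-754
float.
"""

from __future__ import annotations

import math
import struct
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import CSVFormatError, DecodeError
from .signal import SampledSignal

__all__ = [
    "decode_ieee754_hex",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_config_yaml",
    "write_config_yaml",
]

_HEX_DIGITS = set("0123456789abcdefABCDEF")

#: Maximum relative jitter tolerated between consecutive CSV timestamps.
MAX_SPACING_JITTER = 0.005


def decode_ieee754_hex(
    frames: Sequence[str], byte_order: str = "big"
) -> np.ndarray:
    """Decode 8-hex-character telemetry frames as 32-bit IEEE-754 floats.

    Parameters
    ----------
    frames
        Sequence of strings, each exactly 8 hexadecimal characters.
    byte_order
        ``"big"`` (network order, the default) or ``"little"``.

    Returns
    -------
    numpy.ndarray
        One float per frame. NaN or infinite payloads are decoded
        faithfully and reported through a :class:`UserWarning` naming the
        frame indices.

    Raises
    ------
    DecodeError
        If a frame has the wrong length or a non-hex character; the message
        carries the frame index.
    """
    if byte_order not in ("big", "little"):
        raise ValueError(f"byte_order must be 'big' or 'little', got {byte_order!r}")
    fmt = ">f" if byte_order == "big" else "<f"
    out = np.empty(len(frames), dtype=float)
    flagged: list[int] = []
    for i, frame in enumerate(frames):
        if len(frame) != 8:
            raise DecodeError(
                f"frame {i}: expected 8 hex characters, got {len(frame)} ({frame!r})"
            )
        if not set(frame) <= _HEX_DIGITS:
            raise DecodeError(f"frame {i}: non-hexadecimal character in {frame!r}")
        (value,) = struct.unpack(fmt, bytes.fromhex(frame))
        if not math.isfinite(value):
            flagged.append(i)
        out[i] = value
    if flagged:
        warnings.warn(
            f"non-finite IEEE-754 payload(s) at frame index(es) {flagged}",
            UserWarning,
            stacklevel=2,
        )
    return out


def write_timeseries_csv(signal: SampledSignal, path: str | Path) -> None:
    """Write a signal as ``time_s,value`` CSV with a units comment line.

    Times are rendered from the index formula ``start + i/rate`` with 10
    significant digits, enough for a lossless round trip at the precision
    :func:`read_timeseries_csv` checks.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# units: {signal.units}\n")
        fh.write("time_s,value\n")
        times = signal.times()
        for t, v in zip(times, signal.values):
            fh.write(f"{t:.10g},{v:.10g}\n")


def read_timeseries_csv(path: str | Path, units: str | None = None) -> SampledSignal:
    """Read a ``time_s,value`` CSV and infer the sampling rate.

    The rate is the reciprocal of the median timestamp spacing; timestamps
    must be strictly increasing and uniform to within 0.5% jitter.

    Parameters
    ----------
    path
        CSV file with header ``time_s,value`` (a leading ``# units:`` comment
        is honoured).
    units
        Overrides the unit tag from the file; defaults to the sidecar
        comment, or ``a.u.`` if absent.

    Raises
    ------
    CSVFormatError
        Missing columns, non-monotone time, or excessive spacing jitter;
        the message names the first offending data row (1-based, excluding
        header lines).
    """
    path = Path(path)
    file_units = None
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#"):
        tag = first.lstrip("#").strip()
        if tag.lower().startswith("units:"):
            file_units = tag.split(":", 1)[1].strip()
    df = pd.read_csv(path, comment="#")
    missing = {"time_s", "value"} - set(df.columns)
    if missing:
        raise CSVFormatError(f"{path}: missing column(s) {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    v = df["value"].to_numpy(dtype=float)
    resolved_units = units or file_units or "a.u."
    if len(t) == 0:
        raise CSVFormatError(f"{path}: no data rows")
    if len(t) == 1:
        return SampledSignal(v, sample_rate_hz=1.0, start_time_s=t[0], units=resolved_units)
    dts = np.diff(t)
    bad = np.nonzero(dts <= 0)[0]
    if bad.size:
        raise CSVFormatError(
            f"{path}: non-monotone time at data row {bad[0] + 2} "
            f"(t={t[bad[0] + 1]!r} after t={t[bad[0]]!r})"
        )
    dt = float(np.median(dts))
    jitter = np.abs(dts - dt) / dt
    bad = np.nonzero(jitter > MAX_SPACING_JITTER)[0]
    if bad.size:
        raise CSVFormatError(
            f"{path}: non-uniform spacing at data row {bad[0] + 2} "
            f"(dt={dts[bad[0]]:.6g}, expected {dt:.6g})"
        )
    return SampledSignal(v, sample_rate_hz=1.0 / dt, start_time_s=float(t[0]), units=resolved_units)


def write_config_yaml(config: dict, path: str | Path) -> None:
    """Dump a configuration mapping as YAML (sorted keys, deterministic)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_config_yaml(path: str | Path) -> dict:
    """Load a YAML configuration mapping."""
    with Path(path).open("r", encoding="utf-8") as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise CSVFormatError(f"{path}: expected a YAML mapping")
    return out
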