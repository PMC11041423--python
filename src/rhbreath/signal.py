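"""Uniformly sampled physiological time series.

The central in-memory container is :class:`SampledSignal`: a 1-D array of
measurements taken at a fixed rate, together with the units of the samples.
Sample ``i`` is located at ``start_time_s + i / sample_rate_hz`` (0-based
indices throughout the package).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

__all__ = ["SampledSignal", "resample"]

#: Unit tags used across the package.
VALID_UNITS = ("%RH", "L/s", "L", "a.u.")


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled time series.

    Parameters
    ----------
    values
        1-D array of samples.
    sample_rate_hz
        Sampling rate, strictly positive.
    start_time_s
        Time of sample 0.
    units
        Unit tag, one of ``%RH``, ``L/s``, ``L`` or ``a.u.``.
    """

    values: np.ndarray
    sample_rate_hz: float
    start_time_s: float = 0.0
    units: str = "%RH"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValueError(f"values must be 1-D, got shape {arr.shape}")
        if not self.sample_rate_hz > 0:
            raise ValueError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return 1.0 / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        """Time span covered, ``n / rate`` (half-open convention)."""
        return len(self) / self.sample_rate_hz

    def times(self) -> np.ndarray:
        """Per-sample time stamps in seconds."""
        return self.start_time_s + np.arange(len(self)) / self.sample_rate_hz

    def time_to_index(self, t_s: float) -> int:
        """Index of the sample nearest to time ``t_s`` (clipped to range)."""
        i = int(round((t_s - self.start_time_s) * self.sample_rate_hz))
        return min(max(i, 0), max(len(self) - 1, 0))

    def with_values(self, values: np.ndarray) -> "SampledSignal":
        return replace(self, values=np.asarray(values, dtype=float))


def resample(signal: SampledSignal, target_rate_hz: float) -> SampledSignal:
    """Resample a signal onto a new uniform grid spanning the same interval.

    Downsampling applies an anti-aliasing FIR low-pass before decimation
    (polyphase); upsampling uses linear interpolation. Resampling to the
    signal's own rate returns the values unchanged.

    Parameters
    ----------
    signal
        Input signal.
    target_rate_hz
        Desired output rate, strictly positive.
    """
    if not target_rate_hz > 0:
        raise ValueError(f"target_rate_hz must be > 0, got {target_rate_hz}")
    if np.isclose(target_rate_hz, signal.sample_rate_hz):
        return signal
    if len(signal) == 0:
        return replace(signal, sample_rate_hz=float(target_rate_hz))

    if target_rate_hz < signal.sample_rate_hz:
        ratio = Fraction(target_rate_hz / signal.sample_rate_hz).limit_denominator(10000)
        up, down = ratio.numerator, ratio.denominator
        x = signal.values
        # odd reflection about the endpoints suppresses the FIR edge
        # transient while keeping DC and linear trends exact
        # pad by a multiple of the decimation factor so the output grid
        # stays aligned with the input's sample times
        pad = min((len(x) - 1) // down, 10) * down
        if pad > 0:
            ext = np.concatenate([2 * x[0] - x[pad:0:-1], x, 2 * x[-1] - x[-2:-pad - 2:-1]])
        else:
            ext = x
        y = sps.resample_poly(ext, up, down)
        offset = pad * up // down
        n_out = int(np.ceil(len(x) * up / down))
        out = y[offset : offset + n_out]
    else:
        n_out = int(round(len(signal) * target_rate_hz / signal.sample_rate_hz))
        t_new = np.arange(n_out) / target_rate_hz
        out = np.interp(t_new, signal.times() - signal.start_time_s, signal.values)
    return replace(signal, values=out, sample_rate_hz=float(target_rate_hz))
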