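"""Breath-cycle segmentation and respiratory-rate estimation.

A breath cycle is the interval between two consecutive signal minima with
the enclosed maximum as its peak. Deep breaths are flagged by amplitude
against a rolling median of cycle amplitudes, refined to the nearest
second-derivative sign change, and paired into (deep-inhale, deep-exhale)
events. Respiratory rate is the count of minima per non-overlapping window
scaled to breaths per minute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal import SampledSignal

__all__ = [
    "BreathCycle",
    "DeepEvent",
    "Segmentation",
    "smooth_signal",
    "find_breath_extrema",
    "segment_breath_cycles",
    "detect_deep_breaths",
    "respiratory_rate",
    "refine_extremum_times",
]

#: Default low-pass cutoff (Hz); breathing content sits below ~1 Hz.
DEFAULT_CUTOFF_HZ = 2.0
#: Default extremum prominence (%RH) and minimum separation (s).
DEFAULT_PROMINENCE = 1.0
DEFAULT_SEPARATION_S = 1.0
#: Default deep-breath amplitude multiplier and rolling-median width (cycles).
DEFAULT_AMPLITUDE_K = 1.5
DEFAULT_MEDIAN_WINDOW = 10


@dataclass(frozen=True)
class BreathCycle:
    """One breath delimited by consecutive minima, half-open ``[start, end)``."""

    start_idx: int
    peak_idx: int
    end_idx: int
    amplitude: float
    label: str = "normal"

    def __post_init__(self) -> None:
        if not self.start_idx < self.peak_idx < self.end_idx:
            raise ValueError(
                f"require start < peak < end, got {self.start_idx}, "
                f"{self.peak_idx}, {self.end_idx}"
            )


@dataclass(frozen=True)
class DeepEvent:
    """A deep inhale-exhale event: two adjacent cycles sharing the deep trough.

    ``start_idx``/``end_idx`` are the boundaries refined to the nearest
    second-derivative sign change; ``split_idx`` separates the inhale limb
    ``[start, split)`` from the exhale limb ``[split, end)``.
    """

    inhale_cycle: int
    exhale_cycle: int
    start_idx: int
    split_idx: int
    end_idx: int


@dataclass
class Segmentation:
    """Ordered breath cycles plus detected deep events."""

    cycles: list[BreathCycle]
    deep_events: list[DeepEvent] = field(default_factory=list)
    sample_rate_hz: float = 1.0

    def __post_init__(self) -> None:
        for a, b in zip(self.cycles, self.cycles[1:]):
            if a.end_idx > b.start_idx:
                raise ValueError("cycles must be ordered and non-overlapping")
        n = len(self.cycles)
        for ev in self.deep_events:
            if not (0 <= ev.inhale_cycle < n and 0 <= ev.exhale_cycle < n):
                raise ValueError("deep event references a cycle outside the segmentation")

    def __len__(self) -> int:
        return len(self.cycles)

    def labels(self) -> list[str]:
        return [c.label for c in self.cycles]

    def to_frame(self) -> pd.DataFrame:
        """Cycle table with times in seconds (`start_s,peak_s,end_s,amplitude,label`)."""
        dt = 1.0 / self.sample_rate_hz
        return pd.DataFrame(
            {
                "start_s": [c.start_idx * dt for c in self.cycles],
                "peak_s": [c.peak_idx * dt for c in self.cycles],
                "end_s": [c.end_idx * dt for c in self.cycles],
                "amplitude": [c.amplitude for c in self.cycles],
                "label": [c.label for c in self.cycles],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def smooth_signal(signal: SampledSignal, cutoff_hz: float = DEFAULT_CUTOFF_HZ,
                  order: int = 4) -> SampledSignal:
    """Zero-phase Butterworth low-pass; same length and rate, DC gain 1.

    Raises
    ------
    ValueError
        If ``cutoff_hz`` is not below the Nyquist frequency.
    """
    nyquist = signal.sample_rate_hz / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff_hz must be in (0, {nyquist}) Hz, got {cutoff_hz}")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=signal.sample_rate_hz, output="sos")
    out = sps.sosfiltfilt(sos, signal.values)
    return signal.with_values(out)


def _alternate(values: np.ndarray, minima: np.ndarray, maxima: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Enforce strict minima/maxima alternation.

    Runs of same-type extrema are collapsed to the most extreme member
    (earliest index on ties).
    """
    tagged = sorted(
        [(int(i), -1) for i in minima] + [(int(i), +1) for i in maxima]
    )
    keep_min, keep_max = [], []
    run: list[tuple[int, int]] = []
    for item in tagged + [(-1, 0)]:  # sentinel flushes the last run
        if run and item[1] != run[0][1]:
            idxs = np.array([i for i, _ in run])
            if run[0][1] < 0:
                keep_min.append(int(idxs[np.argmin(values[idxs])]))
            else:
                keep_max.append(int(idxs[np.argmax(values[idxs])]))
            run = []
        run.append(item)
    return np.array(sorted(keep_min), dtype=int), np.array(sorted(keep_max), dtype=int)


def find_breath_extrema(
    signal: SampledSignal,
    min_prominence: float = DEFAULT_PROMINENCE,
    min_separation_s: float = DEFAULT_SEPARATION_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Locate alternating breath minima and maxima.

    Every reported extremum has topographic prominence of at least
    ``min_prominence`` and is at least ``min_separation_s`` from its
    same-type neighbours; plateau ties resolve to the first sample of the
    plateau. Same-type runs left over after peak finding are collapsed to
    the most extreme member so the output strictly alternates.
    """
    x = signal.values
    if len(x) < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    distance = max(int(round(min_separation_s * signal.sample_rate_hz)), 1)
    kw = dict(prominence=min_prominence, distance=distance, plateau_size=(None, None))
    maxima, props_max = sps.find_peaks(x, **kw)
    minima, props_min = sps.find_peaks(-x, **kw)
    # first sample of any flat plateau
    maxima = props_max["left_edges"] if len(maxima) else maxima
    minima = props_min["left_edges"] if len(minima) else minima
    return _alternate(x, np.asarray(minima, dtype=int), np.asarray(maxima, dtype=int))


def segment_breath_cycles(
    signal: SampledSignal, minima: np.ndarray, maxima: np.ndarray
) -> Segmentation:
    """One cycle per consecutive-minima pair, peak at the enclosed maximum.

    Amplitude is the peak value minus the lower of the two bounding troughs.
    Fewer than two minima yields an empty segmentation.
    """
    minima = np.asarray(minima, dtype=int)
    maxima = np.asarray(maxima, dtype=int)
    x = signal.values
    cycles = []
    for a, b in zip(minima, minima[1:]):
        inside = maxima[(maxima > a) & (maxima < b)]
        if len(inside):
            peak = int(inside[np.argmax(x[inside])])
        else:
            if b - a < 2:
                continue
            peak = int(a + 1 + np.argmax(x[a + 1 : b]))
        amplitude = float(x[peak] - min(x[a], x[b]))
        cycles.append(BreathCycle(int(a), peak, int(b), amplitude))
    return Segmentation(cycles=cycles, sample_rate_hz=signal.sample_rate_hz)


def _second_difference_sign_changes(x: np.ndarray) -> np.ndarray:
    """Sample indices where the central second difference changes sign.

    The reported index is the first sample of each sign transition.
    """
    d2 = np.zeros_like(x)
    d2[1:-1] = x[:-2] - 2 * x[1:-1] + x[2:]
    s = np.sign(d2[1:-1])
    # carry the previous nonzero sign through exact zeros
    nz = s != 0
    if not nz.any():
        return np.array([], dtype=int)
    filled = np.where(nz, s, np.nan)
    filled = pd.Series(filled).ffill().bfill().to_numpy()
    change = np.nonzero(np.diff(filled) != 0)[0]
    return change + 1  # offset for the d2[1:-1] slice


def _snap(idx: int, anchors: np.ndarray, lo: int, hi: int) -> int:
    """Nearest anchor to ``idx`` within ``(lo, hi)``; falls back to ``idx``."""
    if len(anchors) == 0:
        return idx
    inside = anchors[(anchors > lo) & (anchors < hi)]
    if len(inside) == 0:
        return idx
    return int(inside[np.argmin(np.abs(inside - idx))])


def detect_deep_breaths(
    signal: SampledSignal,
    seg: Segmentation,
    amplitude_k: float = DEFAULT_AMPLITUDE_K,
    median_window: int = DEFAULT_MEDIAN_WINDOW,
    refine_window_s: float = 0.15,
) -> Segmentation:
    """Label deep breaths and pair them into inhale/exhale events.

    A cycle is a candidate when its amplitude exceeds ``amplitude_k`` times
    the rolling median amplitude (window of ``median_window`` cycles,
    centred; the median resists the deep breaths' own influence). Runs of
    consecutive candidates are paired in order into (deep-inhale,
    deep-exhale) events; an unpaired candidate becomes a single-cycle event
    split at its peak. Event boundaries are refined to the nearest
    second-derivative sign change of the (already smoothed) signal within
    ``refine_window_s`` of the trough — a localisation correction for
    noise-blurred minima; the tight window keeps the boundary from sliding
    onto the mid-limb inflection of the breath pulse itself.
    """
    if len(seg) == 0:
        return seg
    amps = np.array([c.amplitude for c in seg.cycles])
    rolling = (
        pd.Series(amps)
        .rolling(median_window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    candidate = amps > amplitude_k * rolling
    anchors = _second_difference_sign_changes(signal.values)
    w = max(int(round(refine_window_s * seg.sample_rate_hz)), 1)

    labels = ["normal"] * len(seg)
    events: list[DeepEvent] = []
    i = 0
    while i < len(seg):
        if not candidate[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(seg) and candidate[j + 1]:
            j += 1
        run = list(range(i, j + 1))
        for k in range(0, len(run) - 1, 2):
            a, b = run[k], run[k + 1]
            labels[a], labels[b] = "deep_inhale", "deep_exhale"
            ca, cb = seg.cycles[a], seg.cycles[b]
            start = _snap(ca.start_idx, anchors, ca.start_idx - w, min(ca.start_idx + w, ca.peak_idx))
            end = _snap(cb.end_idx, anchors, max(cb.end_idx - w, cb.peak_idx), cb.end_idx + w)
            events.append(DeepEvent(a, b, start, ca.end_idx, end))
        if len(run) % 2:
            c = seg.cycles[run[-1]]
            labels[run[-1]] = "deep_exhale"
            start = _snap(c.start_idx, anchors, c.start_idx - w, min(c.start_idx + w, c.peak_idx))
            end = _snap(c.end_idx, anchors, max(c.end_idx - w, c.peak_idx), c.end_idx + w)
            events.append(DeepEvent(run[-1], run[-1], start, c.peak_idx, end))
        i = j + 1

    cycles = [replace(c, label=lab) for c, lab in zip(seg.cycles, labels)]
    return Segmentation(cycles=cycles, deep_events=events, sample_rate_hz=seg.sample_rate_hz)


def refine_extremum_times(
    signal: SampledSignal, indices: np.ndarray, half_window_s: float = 0.2
) -> np.ndarray:
    """Sub-sample extremum times by a local least-squares parabola.

    A quadratic is fitted to the samples within ``half_window_s`` of each
    extremum and its vertex taken as the refined time (shift clipped to two
    samples). Averaging over the window suppresses the +/-1 sample jitter
    that measurement noise puts on the discrete argmin/argmax.
    """
    x = signal.values
    rate = signal.sample_rate_hz
    w = max(int(round(half_window_s * rate)), 1)
    out = np.empty(len(indices), dtype=float)
    for k, i in enumerate(np.asarray(indices, dtype=int)):
        lo, hi = max(i - w, 0), min(i + w + 1, len(x))
        tt = np.arange(lo, hi, dtype=float) - i
        a, b, _ = np.polyfit(tt, x[lo:hi], 2)
        delta = float(np.clip(-b / (2 * a), -2.0, 2.0)) if a != 0 else 0.0
        out[k] = signal.start_time_s + (i + delta) / rate
    return out


def respiratory_rate(
    signal: SampledSignal,
    minima: np.ndarray,
    window_s: float = 60.0,
    refine: bool = True,
) -> list[tuple[float, float]]:
    """Breaths per minute from minima counts in non-overlapping windows.

    For each left-aligned window, RR = (minima in window) * 60 / window_s;
    the final partial window is dropped. Extremum times are refined to
    sub-sample precision by default so window assignment near the edges is
    stable. A window longer than the recording degrades to a single
    full-duration window (with a warning).
    """
    if not window_s > 0:
        raise ValueError(f"window_s must be > 0, got {window_s}")
    duration = signal.duration_s
    if window_s > duration:
        warnings.warn(
            f"window ({window_s} s) exceeds the recording ({duration:.6g} s); "
            "using a single full-duration window",
            UserWarning,
            stacklevel=2,
        )
        window_s = duration
    minima = np.asarray(minima, dtype=int)
    if refine and len(minima):
        times = refine_extremum_times(signal, minima)
    else:
        times = signal.start_time_s + minima.astype(float) / signal.sample_rate_hz
    # tolerate float rounding in rates inferred from file timestamps
    n_windows = int(np.floor(duration / window_s + 1e-9))
    out = []
    for k in range(n_windows):
        t0 = signal.start_time_s + k * window_s
        count = int(np.count_nonzero((times >= t0) & (times < t0 + window_s)))
        out.append((t0, count * 60.0 / window_s))
    return out
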