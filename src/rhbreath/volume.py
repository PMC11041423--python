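"""Per-cycle areas under the curve and derived lung-volume proxies.

All volumetric parameters come from the rectangle method: a left-endpoint
Riemann sum of the baseline-subtracted signal, ``area = sum_i max(f(x_i) -
baseline, 0) * dt``, in units of (signal units x seconds). Tidal volume
(TV) is the area of a normal cycle between consecutive minima; the
inspiratory and expiratory reserve volumes (IRV, ERV) are the areas of the
deep-inhale and deep-exhale limbs of a deep event, and the vital capacity
is VC = IRV + ERV. The deep-breathing area (DBA) is the area over the
closed event from deep-inhalation onset to deep-exhalation end. A triangle
approximation (three vertices: trough, peak, trough) is provided only for
method comparison; areas convert to litres through an affine calibration
against reference volumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import SingularFitError
from .segment import BreathCycle, DeepEvent, Segmentation
from .signal import SampledSignal

__all__ = [
    "CalibrationModel",
    "RespiratoryParameters",
    "rectangle_area",
    "triangle_area",
    "estimate_baseline",
    "compute_volumes",
    "deep_breathing_area",
    "fit_calibration",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Affine map from rectangle-method area (%RH.s) to litres."""

    gain: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError(f"calibration gain must be > 0, got {self.gain}")

    def __call__(self, area: np.ndarray | float) -> np.ndarray | float:
        return self.gain * np.asarray(area, dtype=float) + self.offset


@dataclass
class RespiratoryParameters:
    """Per-recording volume proxies.

    ``tv`` holds one value per normal cycle; ``irv``/``erv``/``vc``/``dba``
    one per deep event (empty arrays when no deep events were detected).
    ``units`` is ``%RH.s`` for raw areas or ``L`` after calibration.
    ``vc = irv + erv`` exactly for every event.
    """

    tv: np.ndarray
    irv: np.ndarray
    erv: np.ndarray
    vc: np.ndarray
    dba: np.ndarray
    units: str
    normal_cycle_indices: np.ndarray
    baseline: float
    rr_series: list[tuple[float, float]] | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: `cycle_idx,kind,value,units`."""
        rows = [
            {"cycle_idx": int(i), "kind": "tv", "value": float(v), "units": self.units}
            for i, v in zip(self.normal_cycle_indices, self.tv)
        ]
        for k, (a, b, c, d) in enumerate(zip(self.irv, self.erv, self.vc, self.dba)):
            for kind, v in (("irv", a), ("erv", b), ("vc", c), ("dba", d)):
                rows.append({"cycle_idx": k, "kind": kind, "value": float(v), "units": self.units})
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def rectangle_area(
    signal: SampledSignal, start_idx: int, end_idx: int, baseline: float = 0.0
) -> float:
    """Left-endpoint Riemann sum of the clamped signal over ``[start, end)``.

    Raises
    ------
    ValueError
        If the interval is empty or out of range.
    """
    m = len(signal)
    if not 0 <= start_idx < end_idx <= m:
        raise ValueError(
            f"invalid interval [{start_idx}, {end_idx}) for a signal of {m} samples"
        )
    seg = signal.values[start_idx:end_idx]
    return float(np.sum(np.maximum(seg - baseline, 0.0)) * signal.dt)


def triangle_area(
    signal: SampledSignal, cycle: BreathCycle, baseline: float = 0.0
) -> float:
    """Area of the trough-peak-trough triangle above the baseline.

    Shoelace formula on the three vertices ``(t, f - baseline)``; collinear
    vertices give area 0. Provided only for the rectangle-vs-triangle
    method comparison.
    """
    dt = signal.dt
    xs = np.array([cycle.start_idx, cycle.peak_idx, cycle.end_idx], dtype=float) * dt
    ys = signal.values[[cycle.start_idx, cycle.peak_idx, cycle.end_idx]] - baseline
    return float(
        0.5
        * abs(
            xs[0] * (ys[1] - ys[2])
            + xs[1] * (ys[2] - ys[0])
            + xs[2] * (ys[0] - ys[1])
        )
    )


def estimate_baseline(
    signal: SampledSignal,
    minima: np.ndarray | None = None,
    method: str = "minima_median",
    percentile: float = 5.0,
) -> float:
    """Estimate the integration baseline (trough floor) of a recording.

    ``minima_median`` (default) takes the median of the signal values at
    the detected minima, which is robust to the deep-inhale troughs that
    dip far below the normal floor. ``percentile`` uses a global value
    percentile instead.
    """
    if method == "minima_median":
        if minima is None or len(minima) == 0:
            raise ValueError("minima_median baseline requires detected minima")
        return float(np.median(signal.values[np.asarray(minima, dtype=int)]))
    if method == "percentile":
        return float(np.percentile(signal.values, percentile))
    raise ValueError(f"unknown baseline method {method!r}")


def deep_breathing_area(
    signal: SampledSignal, event: DeepEvent, baseline: float = 0.0
) -> float:
    """Rectangle-method area over the closed deep event ``[start, end)``.

    Raises
    ------
    ValueError
        If the event boundaries fall outside the signal.
    """
    if not 0 <= event.start_idx < event.end_idx <= len(signal):
        raise ValueError(
            f"event boundaries [{event.start_idx}, {event.end_idx}) outside "
            f"signal of {len(signal)} samples"
        )
    return rectangle_area(signal, event.start_idx, event.end_idx, baseline)


def compute_volumes(
    signal: SampledSignal,
    seg: Segmentation,
    calibration: CalibrationModel | None = None,
    baseline: float = 0.0,
    rr_series: list[tuple[float, float]] | None = None,
) -> RespiratoryParameters:
    """Derive TV, IRV, ERV, VC and DBA from a segmented signal.

    TV is the rectangle area of each normal cycle; IRV/ERV are the areas of
    the inhale/exhale limbs of each deep event (refined boundaries);
    VC = IRV + ERV and DBA is the area over the closed event span. With a
    ``calibration``, areas are mapped to litres (VC is re-derived as
    IRV + ERV after mapping so the identity stays exact).
    """
    normal_idx = [i for i, c in enumerate(seg.cycles) if c.label == "normal"]
    tv = np.array(
        [rectangle_area(signal, seg.cycles[i].start_idx, seg.cycles[i].end_idx, baseline)
         for i in normal_idx]
    )
    irv, erv, dba = [], [], []
    for ev in seg.deep_events:
        irv.append(rectangle_area(signal, ev.start_idx, ev.split_idx, baseline))
        erv.append(rectangle_area(signal, ev.split_idx, ev.end_idx, baseline))
        dba.append(deep_breathing_area(signal, ev, baseline))
    irv, erv, dba = np.array(irv), np.array(erv), np.array(dba)

    units = "%RH.s" if signal.units == "%RH" else f"{signal.units}.s"
    if calibration is not None:
        tv, irv, erv, dba = (np.asarray(calibration(a)) for a in (tv, irv, erv, dba))
        units = "L"
    vc = irv + erv
    return RespiratoryParameters(
        tv=tv,
        irv=irv,
        erv=erv,
        vc=vc,
        dba=dba,
        units=units,
        normal_cycle_indices=np.array(normal_idx, dtype=int),
        baseline=float(baseline),
        rr_series=rr_series,
    )


def fit_calibration(
    estimated_areas: Sequence[float], reference_volumes: Sequence[float]
) -> CalibrationModel:
    """Least-squares affine fit from areas (%RH.s) to litres.

    Raises
    ------
    SingularFitError
        Fewer than two pairs, (near-)constant areas, or a non-positive
        fitted gain.
    """
    a = np.asarray(estimated_areas, dtype=float)
    v = np.asarray(reference_volumes, dtype=float)
    if a.shape != v.shape or a.ndim != 1:
        raise ValueError("estimated_areas and reference_volumes must be 1-D and paired")
    if len(a) < 2:
        raise SingularFitError(f"need at least 2 paired points, got {len(a)}")
    spread = np.ptp(a)
    if spread == 0 or spread < 1e-12 * max(np.max(np.abs(a)), 1.0):
        raise SingularFitError("areas are constant; the affine fit is singular")
    gain, offset = np.polyfit(a, v, 1)
    if gain <= 0:
        raise SingularFitError(f"fitted gain is non-positive ({gain:.3g})")
    return CalibrationModel(gain=float(gain), offset=float(offset))
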