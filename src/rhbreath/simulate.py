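"""Synthetic paired humidity / reference-flow breathing recordings.

The generator emulates a 15-minute seated breathing protocol recorded by two
synchronized devices: a relative-humidity sensor mounted in a face mask and a
reference pneumotachograph measuring airflow. Each breath is a smooth
raised-cosine pulse of relative humidity: inhalation pulls the signal down to
the mask's humid trough floor, exhalation drives it up to a plateau near
water-vapour saturation. Every ``deep_breath_period_s`` seconds the subject
takes one maximal breath, modelled as two adjacent cycles sharing a deep
trough: a deep inhalation that flushes drier air through the mask (the trough
dips well below the floor) followed by a deep exhalation that saturates the
sensor. The paired flow channel is a per-cycle sinusoid whose inhaled volume
integrates exactly to the ground-truth volume of that cycle.

The ground truth (cycle boundaries, labels, per-cycle volumes, per-minute
respiratory rate) is recorded alongside the waveforms so every downstream
stage can be validated without participant data.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .exceptions import ConfigurationError
from .io import write_config_yaml, write_timeseries_csv
from .signal import SampledSignal

__all__ = [
    "SubjectConfig",
    "GroundTruth",
    "SyntheticRecording",
    "simulate_subject",
    "inject_anomaly",
    "simulate_population",
    "save_recording",
]

#: Supported anomaly kinds for :func:`inject_anomaly`.
ANOMALY_KINDS = ("saccade", "missing_recovery")

# SD of a raised-cosine oscillation equals amplitude / (2*sqrt(2)); used to
# translate the whole-trace level statistics into trough/peak levels.
_COS_SD_FACTOR = 1.0 / (2.0 * np.sqrt(2.0))


@dataclass(frozen=True)
class SubjectConfig:
    """Parameters of one simulated subject.

    ``envelope_mean_rh_pct`` / ``envelope_sd_rh_pct`` describe the overall
    level of the oscillating humidity trace (mean and SD of the whole
    recording), not the per-breath peak distribution. From them the
    generator derives a trough floor ``mean - sqrt(2)*sd`` and a nominal
    exhalation peak ``mean + sqrt(2)*sd`` (capped at saturation), which for
    the defaults puts normal breathing between ~78 %RH and ~100 %RH. An
    explicit ``baseline_rh_pct`` overrides the derived trough floor.
    """

    duration_s: float = 900.0
    rr_mean_bpm: float = 17.6
    rr_sd_bpm: float = 1.0
    deep_breath_period_s: float = 30.0
    baseline_rh_pct: float | None = None
    envelope_mean_rh_pct: float = 89.0
    envelope_sd_rh_pct: float = 7.8
    exhale_saturation_rh_pct: float = 100.0
    deep_amplitude_factor: float = 2.0
    plateau_fraction: float = 0.15
    peak_jitter_rh_pct: float = 0.5
    noise_sd_rh_pct: float = 0.02
    drift_rh_pct_per_min: float = 0.05
    rh_sample_rate_hz: float = 5000.0
    flow_sample_rate_hz: float = 1000.0
    volume_gain_l_per_rhs: float = 0.012
    flow_noise_sd_lps: float = 0.005
    seed: int = 0

    # ---- derived levels -------------------------------------------------
    @property
    def trough_rh_pct(self) -> float:
        """Inhalation trough floor (mask micro-climate)."""
        if self.baseline_rh_pct is not None:
            return float(self.baseline_rh_pct)
        return self.envelope_mean_rh_pct - self.envelope_sd_rh_pct / (2 * _COS_SD_FACTOR)

    @property
    def peak_rh_pct(self) -> float:
        """Nominal exhalation peak level, capped at saturation."""
        nominal = 2 * self.envelope_mean_rh_pct - self.trough_rh_pct
        return min(nominal, self.exhale_saturation_rh_pct)

    @property
    def amplitude_rh_pct(self) -> float:
        """Nominal peak-to-trough amplitude of a normal breath."""
        return self.peak_rh_pct - self.trough_rh_pct

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the first violated bound."""
        checks = [
            (self.duration_s > 0, f"duration_s must be > 0, got {self.duration_s}"),
            (self.rr_mean_bpm > 0, f"rr_mean_bpm must be > 0, got {self.rr_mean_bpm}"),
            (self.rr_sd_bpm >= 0, f"rr_sd_bpm must be >= 0, got {self.rr_sd_bpm}"),
            (
                self.deep_breath_period_s > 60.0 / self.rr_mean_bpm,
                "deep_breath_period_s must exceed one breath period "
                f"({60.0 / self.rr_mean_bpm:.3g} s), got {self.deep_breath_period_s}",
            ),
            (
                0.0 <= self.trough_rh_pct < self.envelope_mean_rh_pct,
                "trough floor must satisfy 0 <= trough < envelope mean, got "
                f"trough={self.trough_rh_pct:.3g}, mean={self.envelope_mean_rh_pct}",
            ),
            (
                self.envelope_mean_rh_pct <= 100.0,
                f"envelope_mean_rh_pct must be <= 100, got {self.envelope_mean_rh_pct}",
            ),
            (
                0 < self.exhale_saturation_rh_pct <= 100.0,
                "exhale_saturation_rh_pct must be in (0, 100], got "
                f"{self.exhale_saturation_rh_pct}",
            ),
            (
                self.deep_amplitude_factor > 1.0,
                f"deep_amplitude_factor must be > 1, got {self.deep_amplitude_factor}",
            ),
            (
                self.deep_amplitude_factor * self.amplitude_rh_pct
                <= self.exhale_saturation_rh_pct,
                "deep amplitude exceeds the physical range: "
                f"{self.deep_amplitude_factor} x {self.amplitude_rh_pct:.3g} "
                f"> {self.exhale_saturation_rh_pct}",
            ),
            (
                0.0 <= self.plateau_fraction < 0.5,
                f"plateau_fraction must be in [0, 0.5), got {self.plateau_fraction}",
            ),
            (self.noise_sd_rh_pct >= 0, f"noise_sd_rh_pct must be >= 0, got {self.noise_sd_rh_pct}"),
            (self.peak_jitter_rh_pct >= 0, f"peak_jitter_rh_pct must be >= 0, got {self.peak_jitter_rh_pct}"),
            (self.rh_sample_rate_hz > 0, f"rh_sample_rate_hz must be > 0, got {self.rh_sample_rate_hz}"),
            (self.flow_sample_rate_hz > 0, f"flow_sample_rate_hz must be > 0, got {self.flow_sample_rate_hz}"),
            (self.volume_gain_l_per_rhs > 0, f"volume_gain_l_per_rhs must be > 0, got {self.volume_gain_l_per_rhs}"),
            (self.flow_noise_sd_lps >= 0, f"flow_noise_sd_lps must be >= 0, got {self.flow_noise_sd_lps}"),
        ]
        for ok, message in checks:
            if not ok:
                raise ConfigurationError(message)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Known truth of a synthetic recording.

    ``boundary_times_s`` has one entry per cycle boundary (n_cycles + 1,
    strictly increasing); cycle ``i`` spans ``[boundary[i], boundary[i+1])``.
    Labels are ``normal``, ``deep_inhale`` or ``deep_exhale``; each deep
    event is an ``(inhale_cycle_index, exhale_cycle_index)`` pair of
    adjacent cycles. Volumes are litres; areas are %RH·s of the noiseless
    waveform clamped above the trough floor.
    """

    boundary_times_s: np.ndarray
    boundary_indices: np.ndarray
    labels: list[str]
    peak_indices: np.ndarray
    true_areas_rhs: np.ndarray
    true_volumes_l: np.ndarray
    deep_events: list[tuple[int, int]]
    rr_window_s: float
    true_rr_bpm_per_minute: np.ndarray
    anomalies: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        b = np.asarray(self.boundary_times_s, dtype=float)
        if not np.all(np.diff(b) > 0):
            raise ValueError("cycle boundaries must be strictly increasing")
        if len(self.labels) != len(b) - 1:
            raise ValueError("need exactly one label per cycle")

    @property
    def n_cycles(self) -> int:
        return len(self.labels)

    @property
    def normal_indices(self) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels) if l == "normal"], dtype=int)

    @property
    def true_tv_l(self) -> np.ndarray:
        """True tidal volume of each normal cycle (L)."""
        return self.true_volumes_l[self.normal_indices]

    @property
    def true_irv_l(self) -> np.ndarray:
        """True inspiratory-reserve volume per deep event (L)."""
        return np.array([self.true_volumes_l[i] for i, _ in self.deep_events])

    @property
    def true_erv_l(self) -> np.ndarray:
        """True expiratory-reserve volume per deep event (L)."""
        return np.array([self.true_volumes_l[j] for _, j in self.deep_events])

    @property
    def true_vc_l(self) -> np.ndarray:
        """True vital capacity per deep event: IRV + ERV."""
        return self.true_irv_l + self.true_erv_l

    @property
    def true_dba_l(self) -> np.ndarray:
        """True deep-breathing area per event (equals VC by construction)."""
        return self.true_vc_l


@dataclass
class SyntheticRecording:
    """Paired humidity and flow channels plus ground truth."""

    rh: SampledSignal
    flow: SampledSignal
    truth: GroundTruth
    config: SubjectConfig


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws truncated at +/- 3 SD (resampling rejection)."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = np.abs(out - mean) > 3 * sd
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    return np.clip(out, mean - 3 * sd, mean + 3 * sd)


def _plan_cycles(config: SubjectConfig, rng: np.random.Generator) -> dict:
    """Draw the per-cycle plan: periods, deep schedule, levels, plateaus."""
    mean_period = 60.0 / config.rr_mean_bpm
    n_guess = int(config.duration_s / mean_period * 1.5) + 16
    rr_draws = _truncated_normal(rng, config.rr_mean_bpm, config.rr_sd_bpm, n_guess)
    rr_draws = np.maximum(rr_draws, config.rr_mean_bpm * 0.2)
    periods = 60.0 / rr_draws
    starts = np.concatenate([[0.0], np.cumsum(periods)])

    # complete cycles fit in the recording; one extra partial cycle fills the tail
    n_complete = int(np.searchsorted(starts, config.duration_s + 1e-9) - 1)
    n_total = min(n_complete + 1, len(periods))

    trough = config.trough_rh_pct
    sat = config.exhale_saturation_rh_pct
    deep_amp = config.deep_amplitude_factor * config.amplitude_rh_pct
    deep_peak = min(trough + deep_amp, sat)
    deep_trough = deep_peak - deep_amp

    # deep-exhale cycles scheduled every deep_breath_period_s; the preceding
    # cycle becomes the deep inhalation (its falling limb dips to the deep
    # trough), so the first schedule slot is taken by cycle index 1.
    labels = ["normal"] * n_total
    next_deep = 0.0
    for i in range(1, n_complete):
        if labels[i - 1] != "normal":
            continue
        if starts[i - 1] >= next_deep - 1e-9:
            labels[i - 1] = "deep_inhale"
            labels[i] = "deep_exhale"
            next_deep += config.deep_breath_period_s

    peaks = np.clip(
        config.peak_rh_pct + rng.normal(0.0, config.peak_jitter_rh_pct, n_total),
        trough + 0.5 * config.amplitude_rh_pct,
        sat,
    )
    plateaus = config.plateau_fraction * rng.uniform(1 / 3, 5 / 3, n_total)
    plateaus = np.clip(plateaus, 0.0, 0.45)

    # boundary level at the START of each cycle (+ final boundary)
    start_levels = np.full(n_total + 1, trough)
    for i, lab in enumerate(labels):
        if lab == "deep_exhale":
            start_levels[i] = deep_trough
            peaks[i] = deep_peak
    return {
        "starts": starts[: n_total + 1],
        "labels": labels,
        "peaks": peaks,
        "plateaus": plateaus,
        "start_levels": start_levels,
        "n_complete": n_complete,
    }


def _render_rh(plan: dict, config: SubjectConfig, n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Render the noiseless humidity waveform and per-cycle peak indices."""
    rate = config.rh_sample_rate_hz
    out = np.full(n_samples, config.trough_rh_pct)
    starts = plan["starts"]
    peak_idx = np.zeros(len(plan["labels"]), dtype=int)
    for i in range(len(plan["labels"])):
        t0, t1 = starts[i], starts[i + 1]
        i0 = int(round(t0 * rate))
        i1 = min(int(round(t1 * rate)), n_samples)
        if i1 <= i0:
            continue
        T = t1 - t0
        q = plan["plateaus"][i]
        half = (1.0 - q) * T / 2.0
        s0, p, s1 = plan["start_levels"][i], plan["peaks"][i], plan["start_levels"][i + 1]
        tau = np.arange(i0, i1) / rate - t0
        rise = s0 + (p - s0) * 0.5 * (1 - np.cos(np.pi * np.minimum(tau, half) / half))
        seg = np.where(tau < half + q * T, np.where(tau < half, rise, p), 0.0)
        fall_tau = np.maximum(tau - half - q * T, 0.0)
        fall = p + (s1 - p) * 0.5 * (1 - np.cos(np.pi * np.minimum(fall_tau, half) / half))
        seg = np.where(tau >= half + q * T, fall, seg)
        out[i0:i1] = seg
        peak_idx[i] = min(i0 + int(round((half + q * T / 2.0) * rate)), n_samples - 1)
    return out, peak_idx


def _cycle_areas(noiseless: np.ndarray, boundaries: np.ndarray, floor: float, dt: float) -> np.ndarray:
    """Rectangle-rule area of each cycle, clamped above the trough floor."""
    clamped = np.maximum(noiseless - floor, 0.0)
    b = np.clip(boundaries, 0, len(noiseless))
    sums = np.add.reduceat(clamped, b[:-1])
    # reduceat includes the tail beyond the final boundary for the last slice
    if b[-1] < len(noiseless):
        sums[-1] -= np.add.reduce(clamped[b[-1]:])
    return sums * dt


def _render_flow(plan: dict, truth_volumes: np.ndarray, config: SubjectConfig,
                 n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Per-cycle sinusoidal flow whose inhaled volume equals the true volume."""
    rate = config.flow_sample_rate_hz
    out = np.zeros(n_samples)
    starts = plan["starts"]
    for i in range(len(truth_volumes)):
        t0, t1 = starts[i], starts[i + 1]
        i0 = int(round(t0 * rate))
        i1 = min(int(round(t1 * rate)), n_samples)
        if i1 <= i0:
            continue
        T = t1 - t0
        tau = np.arange(i0, i1) / rate - t0
        out[i0:i1] = (np.pi * truth_volumes[i] / T) * np.sin(2 * np.pi * tau / T)
    if config.flow_noise_sd_lps > 0:
        out = out + rng.normal(0.0, config.flow_noise_sd_lps, n_samples)
    return out


def simulate_subject(config: SubjectConfig | None = None, **overrides) -> SyntheticRecording:
    """Generate one synthetic paired recording with ground truth.

    Same ``config.seed`` gives a bit-identical recording. Keyword overrides
    are applied on top of ``config`` (or the defaults).

    Raises
    ------
    ConfigurationError
        If the configuration violates one of its bounds; the message names
        the violated bound.
    """
    if config is None:
        config = SubjectConfig()
    if overrides:
        config = dataclasses.replace(config, **overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)

    plan = _plan_cycles(config, rng)
    n_rh = int(round(config.duration_s * config.rh_sample_rate_hz))
    n_flow = int(round(config.duration_s * config.flow_sample_rate_hz))

    noiseless, peak_indices = _render_rh(plan, config, n_rh)

    n_cycles = plan["n_complete"]
    boundaries_t = plan["starts"][: n_cycles + 1]
    boundaries_i = np.round(boundaries_t * config.rh_sample_rate_hz).astype(int)
    labels = plan["labels"][:n_cycles]

    areas = _cycle_areas(noiseless, boundaries_i, config.trough_rh_pct,
                         1.0 / config.rh_sample_rate_hz)
    volumes = config.volume_gain_l_per_rhs * areas

    deep_events = [
        (i, i + 1)
        for i in range(n_cycles - 1)
        if labels[i] == "deep_inhale" and labels[i + 1] == "deep_exhale"
    ]

    # per-minute RR truth: interior boundary minima per non-overlapping window
    window = 60.0
    n_windows = int(np.floor(config.duration_s / window + 1e-9))
    interior = boundaries_t[1:]
    interior = interior[interior < config.duration_s - 1.0 / config.rh_sample_rate_hz]
    counts = np.histogram(interior, bins=np.arange(n_windows + 1) * window)[0]
    true_rr = counts * (60.0 / window)

    truth = GroundTruth(
        boundary_times_s=boundaries_t,
        boundary_indices=boundaries_i,
        labels=list(labels),
        peak_indices=peak_indices[:n_cycles],
        true_areas_rhs=areas,
        true_volumes_l=volumes,
        deep_events=deep_events,
        rr_window_s=window,
        true_rr_bpm_per_minute=true_rr,
    )

    rh_vals = noiseless.copy()
    if config.drift_rh_pct_per_min != 0:
        t = np.arange(n_rh) / config.rh_sample_rate_hz
        rh_vals = rh_vals + config.drift_rh_pct_per_min * t / 60.0
    if config.noise_sd_rh_pct > 0:
        rh_vals = rh_vals + rng.normal(0.0, config.noise_sd_rh_pct, n_rh)
    rh_vals = np.clip(rh_vals, 0.0, 100.0)

    # volumes of the partial tail cycle (if any) extend the flow channel
    all_volumes = volumes
    if len(plan["labels"]) > n_cycles and boundaries_i[-1] < n_rh:
        tail_area = _cycle_areas(
            noiseless,
            np.array([boundaries_i[-1], n_rh]),
            config.trough_rh_pct,
            1.0 / config.rh_sample_rate_hz,
        )
        all_volumes = np.concatenate([volumes, config.volume_gain_l_per_rhs * tail_area])
    flow_vals = _render_flow(plan, all_volumes, config, n_flow, rng)

    rh = SampledSignal(rh_vals, config.rh_sample_rate_hz, 0.0, "%RH")
    flow = SampledSignal(flow_vals, config.flow_sample_rate_hz, 0.0, "L/s")
    return SyntheticRecording(rh=rh, flow=flow, truth=truth, config=config)


def inject_anomaly(
    rec: SyntheticRecording,
    kind: str,
    at_s: float,
    *,
    width_s: float = 2.0,
    saccade_amplitude_rh_pct: float = 2.0,
    saccade_freq_hz: float = 3.0,
    recovery_offset_rh_pct: float = 5.0,
) -> SyntheticRecording:
    """Return a copy of ``rec`` with a local breathing anomaly.

    ``saccade`` superimposes a short mid-cycle oscillation; ``missing_recovery``
    suppresses the return to the trough floor after an exhalation, so the
    affected cycle's minimum sits above its neighbours'. The anomaly window is
    appended to ``truth.anomalies``.
    """
    if kind not in ANOMALY_KINDS:
        raise ValueError(f"unknown anomaly kind {kind!r}; supported kinds: {ANOMALY_KINDS}")
    duration = rec.rh.duration_s
    if not 0.0 <= at_s <= duration:
        raise ValueError(f"at_s={at_s} outside the recording [0, {duration:.6g}] s")

    out = copy.deepcopy(rec)
    rate = out.rh.sample_rate_hz
    vals = out.rh.values

    if kind == "saccade":
        t0, t1 = at_s - width_s / 2.0, at_s + width_s / 2.0
        i0 = max(int(np.ceil(t0 * rate)), 0)
        i1 = min(int(np.floor(t1 * rate)) + 1, len(vals))
        tau = np.arange(i0, i1) / rate - at_s
        window = 0.5 * (1 + np.cos(2 * np.pi * tau / (2 * width_s / 2.0)))
        vals[i0:i1] += saccade_amplitude_rh_pct * np.sin(
            2 * np.pi * saccade_freq_hz * tau
        ) * window
        span = (max(t0, 0.0), min(t1, duration))
    else:  # missing_recovery: raise the trough ending the containing cycle
        b = out.truth.boundary_times_s
        cycle = int(np.clip(np.searchsorted(b, at_s, side="right") - 1, 0, out.truth.n_cycles - 1))
        trough_t = b[cycle + 1]
        half = max(width_s, (b[cycle + 1] - b[cycle]) * 0.6)
        t0, t1 = trough_t - half / 2.0, trough_t + half / 2.0
        i0 = max(int(np.ceil(t0 * rate)), 0)
        i1 = min(int(np.floor(t1 * rate)) + 1, len(vals))
        tau = np.arange(i0, i1) / rate - trough_t
        bump = recovery_offset_rh_pct * 0.5 * (1 + np.cos(2 * np.pi * tau / half))
        vals[i0:i1] += bump
        span = (max(t0, 0.0), min(t1, duration))

    np.clip(vals, 0.0, 100.0, out=vals)
    out.truth.anomalies.append({"kind": kind, "start_s": float(span[0]), "end_s": float(span[1])})
    return out


def simulate_population(
    n: int,
    base_config: SubjectConfig | None = None,
    variation: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> list[SyntheticRecording]:
    """Simulate ``n`` subjects with per-subject parameters drawn from
    normal distributions.

    Parameters
    ----------
    n
        Number of subjects (>= 1).
    base_config
        Template configuration; fields not listed in ``variation`` are taken
        from it verbatim.
    variation
        Mapping ``field -> (mean, sd)``; per-subject values are normal draws
        truncated at +/- 3 SD.
    seed
        Study seed; subject ``i`` uses an RNG stream derived from
        ``(seed, i)``, so populations are reproducible element-wise.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    base = base_config or SubjectConfig()
    variation = dict(variation or {})
    recordings = []
    for i in range(n):
        ss = np.random.SeedSequence([int(seed), i])
        param_rng = np.random.default_rng(ss)
        fields = {}
        for name, (mean, sd) in sorted(variation.items()):
            fields[name] = float(_truncated_normal(param_rng, mean, sd, 1)[0])
        fields["seed"] = int(ss.generate_state(2)[1] % (2**31))
        cfg = dataclasses.replace(base, **fields)
        recordings.append(simulate_subject(cfg))
    return recordings


def save_recording(rec: SyntheticRecording, outdir: str | Path) -> None:
    """Write a recording as rh.csv, flow.csv, annotations.csv and config.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_timeseries_csv(rec.rh, outdir / "rh.csv")
    write_timeseries_csv(rec.flow, outdir / "flow.csv")
    b = rec.truth.boundary_times_s
    with (outdir / "annotations.csv").open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("cycle_start_s,cycle_end_s,label,volume_l\n")
        for i, lab in enumerate(rec.truth.labels):
            fh.write(f"{b[i]:.6f},{b[i + 1]:.6f},{lab},{rec.truth.true_volumes_l[i]:.6f}\n")
    cfg = rec.config.to_dict()
    write_config_yaml(cfg, outdir / "config.yaml")
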