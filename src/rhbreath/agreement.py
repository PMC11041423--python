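"""Method-comparison statistics: Bland-Altman, one-way ANOVA, RMSE, box summaries.

The Bland-Altman estimator quantifies agreement between a device and a
reference from paired measurements: the bias is the mean difference and the
95% limits of agreement (LoA) are ``bias +/- 1.96 * SD(differences)``
(sample SD, n-1). Differences may be taken in the measurement units or as a
percentage of the pair mean, optionally after normalising each subject by
its own mean level. The one-way ANOVA partitions total variance into
between-group and within-group sums of squares and tests the group-mean
equality with an F statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementReport",
    "AnovaTable",
    "BoxSummary",
    "BlandAltman",
    "bland_altman",
    "one_way_anova",
    "anova_from_summary",
    "rmse_and_correlation",
    "box_summary",
]

#: Normal-theory multiplier bounding ~95% of differences.
LOA_MULTIPLIER = 1.96


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Result of a paired-agreement analysis.

    ``mode`` is ``unit`` (differences in measurement units) or ``percent``
    (100 * difference / pair mean). ``loa_method`` records how the limits
    were computed (``normal``, ``log`` or ``mixed``).
    """

    bias: float
    loa_lower: float
    loa_upper: float
    diffs: np.ndarray
    means: np.ndarray
    mode: str
    rmse: float
    pearson_r: float
    n: int
    loa_method: str = "normal"
    subject_variance: float | None = None

    def __post_init__(self) -> None:
        if not self.loa_lower <= self.bias <= self.loa_upper:
            raise ValueError("limits of agreement must bracket the bias")

    def summary(self) -> str:
        lines = [
            "Bland-Altman agreement",
            f"  n pairs        : {self.n}",
            f"  mode           : {self.mode} ({self.loa_method} limits)",
            f"  bias           : {self.bias:.4g}",
            f"  LoA (lower)    : {self.loa_lower:.4g}",
            f"  LoA (upper)    : {self.loa_upper:.4g}",
            f"  RMSE           : {self.rmse:.4g}",
            f"  Pearson r      : {self.pearson_r:.4g}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "bias": float(self.bias),
            "loa_lower": float(self.loa_lower),
            "loa_upper": float(self.loa_upper),
            "mode": self.mode,
            "loa_method": self.loa_method,
            "rmse": float(self.rmse),
            "pearson_r": float(self.pearson_r),
            "n": int(self.n),
        }


class BlandAltman:
    """Bland-Altman agreement model for paired device/reference values.

    Parameters
    ----------
    a, b
        Paired measurements (device, reference), equal length >= 2.
    mode
        ``"unit"`` or ``"percent"``.
    normalize
        ``None`` or ``"per_subject_mean"`` — divide each pair by its
        subject's mean pair level first (requires ``subjects``).
    subjects
        Optional per-pair subject identifiers.
    loa_method
        ``"normal"`` (default), ``"log"`` (limits computed on log
        differences and mapped back) or ``"mixed"`` (random subject
        intercept; the subject variance component is dropped when it fails
        to improve AIC by more than 2).
    """

    def __init__(
        self,
        a: Sequence[float],
        b: Sequence[float],
        mode: str = "unit",
        normalize: str | None = None,
        subjects: Sequence | None = None,
        loa_method: str = "normal",
    ) -> None:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError(f"paired inputs must be 1-D of equal length, got {a.shape} vs {b.shape}")
        if len(a) < 2:
            raise ValueError(f"need at least 2 pairs, got {len(a)}")
        if mode not in ("unit", "percent"):
            raise ValueError(f"mode must be 'unit' or 'percent', got {mode!r}")
        if normalize not in (None, "per_subject_mean"):
            raise ValueError(f"normalize must be None or 'per_subject_mean', got {normalize!r}")
        if loa_method not in ("normal", "log", "mixed"):
            raise ValueError(f"loa_method must be 'normal', 'log' or 'mixed', got {loa_method!r}")
        if (normalize or loa_method == "mixed") and subjects is None:
            raise ValueError("per-subject normalisation / mixed limits require subjects")
        self.a, self.b = a, b
        self.mode = mode
        self.normalize = normalize
        self.subjects = None if subjects is None else np.asarray(subjects)
        self.loa_method = loa_method

    def fit(self) -> AgreementReport:
        a, b = self.a, self.b
        if self.normalize == "per_subject_mean":
            scale = np.empty_like(a)
            for s in np.unique(self.subjects):
                mask = self.subjects == s
                level = np.mean((a[mask] + b[mask]) / 2.0)
                if level == 0:
                    raise ValueError(f"subject {s!r} has zero mean level; cannot normalise")
                scale[mask] = level
            a, b = a / scale, b / scale

        means = (a + b) / 2.0
        if self.mode == "percent":
            zero = np.nonzero(means == 0)[0]
            if zero.size:
                raise ValueError(f"zero pair mean at pair index {zero[0]}; percent mode undefined")
            diffs = 100.0 * (a - b) / means
        else:
            diffs = a - b

        rmse = float(np.sqrt(np.mean((a - b) ** 2)))
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            pearson = float("nan")
            warnings.warn("constant input; Pearson r undefined", UserWarning, stacklevel=2)
        else:
            pearson = float(np.corrcoef(a, b)[0, 1])

        subject_variance = None
        if self.loa_method == "log":
            bias, lo, hi = self._log_limits(a, b, diffs)
        elif self.loa_method == "mixed":
            bias, lo, hi, subject_variance = self._mixed_limits(diffs)
        else:
            bias = float(np.mean(diffs))
            sd = float(np.std(diffs, ddof=1))
            lo, hi = bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd

        return AgreementReport(
            bias=bias,
            loa_lower=lo,
            loa_upper=hi,
            diffs=diffs,
            means=means,
            mode=self.mode,
            rmse=rmse,
            pearson_r=pearson,
            n=len(a),
            loa_method=self.loa_method,
            subject_variance=subject_variance,
        )

    @staticmethod
    def _log_limits(a: np.ndarray, b: np.ndarray, diffs: np.ndarray) -> tuple[float, float, float]:
        """Limits from log-transformed values, mapped back to differences.

        The ratio a/b is modelled as log-normal; the back-transformed limits
        are asymmetric around the bias, which suits positive, skewed data.
        """
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("log limits require strictly positive measurements")
        logd = np.log(a) - np.log(b)
        mu, sd = float(np.mean(logd)), float(np.std(logd, ddof=1))
        bias = float(np.mean(diffs))
        geo = np.sqrt(a * b)
        scale = float(np.mean(geo))
        lo = scale * (np.exp(mu - LOA_MULTIPLIER * sd) - 1.0)
        hi = scale * (np.exp(mu + LOA_MULTIPLIER * sd) - 1.0)
        return bias, min(lo, bias), max(hi, bias)

    def _mixed_limits(self, diffs: np.ndarray) -> tuple[float, float, float, float]:
        """Random-subject-intercept limits with an AIC-based zeroing rule.

        The subject variance component is kept only when the mixed model
        improves AIC by more than 2 points over the pooled normal model.
        """
        import statsmodels.api as sm

        bias = float(np.mean(diffs))
        sd_pooled = float(np.std(diffs, ddof=1))
        n = len(diffs)
        # pooled-normal AIC (2 parameters: mean, variance)
        resid = diffs - bias
        sigma2 = float(np.mean(resid**2))
        llf_pooled = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        aic_pooled = 2 * 2 - 2 * llf_pooled

        subject_variance = 0.0
        sd_total = sd_pooled
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(diffs, np.ones((n, 1)), groups=self.subjects)
                res = model.fit(reml=False)
            aic_mixed = 2 * 3 - 2 * float(res.llf)
            if aic_mixed < aic_pooled - 2.0:
                subject_variance = float(np.asarray(res.cov_re).ravel()[0])
                sd_total = float(np.sqrt(subject_variance + res.scale))
                bias = float(res.params[0])
        except Exception:  # singular fits fall back to the pooled estimator
            pass
        lo = bias - LOA_MULTIPLIER * sd_total
        hi = bias + LOA_MULTIPLIER * sd_total
        return bias, lo, hi, subject_variance


def bland_altman(
    a: Sequence[float],
    b: Sequence[float],
    mode: str = "unit",
    normalize: str | None = None,
    subjects: Sequence | None = None,
    loa_method: str = "normal",
) -> AgreementReport:
    """Fit a :class:`BlandAltman` model and return its report."""
    return BlandAltman(a, b, mode=mode, normalize=normalize, subjects=subjects,
                       loa_method=loa_method).fit()


# ---------------------------------------------------------------------------
# One-way ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaTable:
    """Between/within variance decomposition with F test.

    Invariants: ``ss_total = ss_between + ss_within`` and
    ``f = ms_between / ms_within``. ``degenerate`` flags a zero
    within-group variance with non-zero between-group variance.
    """

    ss_between: float
    df_between: int
    ss_within: float
    df_within: int
    f: float
    p: float
    degenerate: bool = False

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within

    @property
    def df_total(self) -> int:
        return self.df_between + self.df_within

    @property
    def ms_between(self) -> float:
        return self.ss_between / self.df_between

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["between", "within", "total"],
                "ss": [self.ss_between, self.ss_within, self.ss_total],
                "df": [self.df_between, self.df_within, self.df_total],
                "ms": [self.ms_between, self.ms_within, np.nan],
                "f": [self.f, np.nan, np.nan],
                "p": [self.p, np.nan, np.nan],
            }
        )

    def summary(self) -> str:
        """Human-readable table; P shown to 2 decimals, full precision kept."""
        df = self.to_frame()
        lines = ["One-way ANOVA", "  source     SS        df    MS        F        P"]
        for _, r in df.iterrows():
            ms = f"{r['ms']:<9.4g}" if np.isfinite(r["ms"]) else "-        "
            fv = f"{r['f']:<8.4g}" if np.isfinite(r["f"]) else "-       "
            pv = f"{r['p']:.2f}" if np.isfinite(r["p"]) else "-"
            lines.append(
                f"  {r['source']:<9}{r['ss']:<10.4g}{int(r['df']):<6d}{ms}{fv}{pv}"
            )
        if self.degenerate:
            lines.append("  [degenerate: zero within-group variance]")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "ss_between": float(self.ss_between),
            "df_between": int(self.df_between),
            "ss_within": float(self.ss_within),
            "df_within": int(self.df_within),
            "ms_between": float(self.ms_between),
            "ms_within": float(self.ms_within),
            "f": float(self.f),
            "p": float(self.p),
            "degenerate": bool(self.degenerate),
        }


def _finish_anova(ssb: float, dfb: int, ssw: float, dfw: int) -> AnovaTable:
    degenerate = False
    if ssw <= 0:
        if ssb <= 1e-12 * max(ssw + ssb, 1.0):
            return AnovaTable(ssb, dfb, ssw, dfw, f=0.0, p=1.0)
        degenerate = True
        return AnovaTable(ssb, dfb, ssw, dfw, f=float("inf"), p=0.0, degenerate=degenerate)
    msb, msw = ssb / dfb, ssw / dfw
    f = msb / msw
    p = float(stats.f.sf(f, dfb, dfw))
    return AnovaTable(ssb, dfb, ssw, dfw, f=float(f), p=p)


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaTable:
    """Standard between/within decomposition over two or more groups.

    Raises
    ------
    ValueError
        Fewer than 2 groups, an empty group, or no residual degrees of
        freedom.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError(f"need at least 2 groups, got {len(gs)}")
    if any(len(g) == 0 for g in gs):
        raise ValueError("every group needs at least one value")
    n_total = sum(len(g) for g in gs)
    if n_total <= len(gs):
        raise ValueError("total sample size must exceed the number of groups")
    grand = np.mean(np.concatenate(gs))
    ssb = float(sum(len(g) * (np.mean(g) - grand) ** 2 for g in gs))
    ssw = float(sum(np.sum((g - np.mean(g)) ** 2) for g in gs))
    return _finish_anova(ssb, len(gs) - 1, ssw, n_total - len(gs))


def anova_from_summary(
    ss_between: float, df_between: int, ss_within: float, df_within: int
) -> AnovaTable:
    """Rebuild MS, F and P from a printed sum-of-squares decomposition."""
    for name, df in (("df_between", df_between), ("df_within", df_within)):
        if df != int(df) or df <= 0:
            raise ValueError(f"{name} must be a positive integer, got {df}")
    if ss_between < 0 or ss_within < 0:
        raise ValueError("sums of squares must be non-negative")
    return _finish_anova(float(ss_between), int(df_between), float(ss_within), int(df_within))


# ---------------------------------------------------------------------------
# RMSE / correlation and box summaries
# ---------------------------------------------------------------------------

def rmse_and_correlation(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Root-mean-square error and Pearson correlation of paired values.

    Constant input makes the correlation undefined: RMSE is still returned,
    with ``nan`` for r and a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired 1-D inputs of equal length >= 2 required")
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant input; Pearson r undefined", UserWarning, stacklevel=2)
        return rmse, float("nan")
    return rmse, float(np.corrcoef(a, b)[0, 1])


@dataclass(frozen=True)
class BoxSummary:
    """Five-number box-plot summary with 1.5*IQR whiskers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    def to_dict(self) -> dict:
        return {
            "median": float(self.median),
            "q1": float(self.q1),
            "q3": float(self.q3),
            "iqr": float(self.iqr),
            "whisker_low": float(self.whisker_low),
            "whisker_high": float(self.whisker_high),
            "n_outliers": int(len(self.outliers)),
        }


def box_summary(values: Sequence[float]) -> BoxSummary:
    """Quartiles by linear interpolation; whiskers at the most extreme
    points within 1.5*IQR of the quartiles; points beyond are outliers.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("box_summary requires at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=np.sort(outliers),
    )
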