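"""Plotting helpers: Bland-Altman scatter and device box plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402

from .agreement import AgreementReport

__all__ = ["plot_bland_altman", "plot_device_boxes"]


def plot_bland_altman(report: AgreementReport, ax=None, title: str | None = None,
                      path: str | Path | None = None):
    """Scatter of pairwise differences against pairwise means with the bias
    line and the limits of agreement."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(report.means, report.diffs, s=12, alpha=0.6)
    ax.axhline(report.bias, color="tab:blue", label=f"bias = {report.bias:.3g}")
    for y, lab in ((report.loa_lower, "LoA"), (report.loa_upper, None)):
        ax.axhline(y, color="tab:gray", linestyle="--", label=lab)
    ax.set_xlabel("pair mean")
    ax.set_ylabel("difference" if report.mode == "unit" else "difference (%)")
    if title:
        ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_device_boxes(values: dict[str, list], ax=None, ylabel: str = "",
                      path: str | Path | None = None):
    """Side-by-side box plots of per-device value distributions."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    labels = list(values)
    ax.boxplot([values[k] for k in labels], tick_labels=labels)
    ax.set_ylabel(ylabel)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
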