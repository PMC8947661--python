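"""Levey-Jennings style control limits for batch positive-control analytes.

Each monitored analyte (a fusion transcript's internal-control-normalized
read level, or a CNA fold change) accumulates one value per baseline run;
QC limits are the baseline mean +/- 3 sample standard deviations, and later
runs are classified against the closed interval [lower, upper].
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .qc import InternalControlPanel

__all__ = [
    "PointStatus",
    "ControlSeries",
    "ControlLimits",
    "normalize_to_internal_controls",
    "derive_limits",
    "evaluate_point",
    "recover_mean_sd",
    "plot_control_chart",
]


class PointStatus(str, enum.Enum):
    IN_CONTROL = "in_control"
    OUT_OF_CONTROL_LOW = "out_of_control_low"
    OUT_OF_CONTROL_HIGH = "out_of_control_high"


@dataclass(frozen=True)
class ControlSeries:
    """Baseline measurements of one control analyte, one value per run."""

    analyte_id: str
    kind: str  # "fusion_reads" or "cna_fold_change"
    values: tuple[float, ...]
    run_dates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("fusion_reads", "cna_fold_change"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        if self.run_dates and len(self.run_dates) != len(self.values):
            raise ValueError("run_dates must match values in length")


@dataclass(frozen=True)
class ControlLimits:
    analyte_id: str
    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def normalize_to_internal_controls(
    fusion_reads: float, controls: InternalControlPanel, scale: float = 1.0
) -> float:
    """Fusion read level relative to the average internal-control count.

    Divides by the arithmetic mean of the four process-control counts (TBP,
    HMBS, MET E6-E7, MET E11-E12), optionally rescaled by ``scale`` — the
    plotted chart units are a lab convention, so the constant is
    configurable (default 1).
    """
    mean_control = float(np.mean(controls.as_tuple()))
    if mean_control == 0:
        raise ZeroDivisionError(
            "all four internal controls are zero; normalization undefined"
        )
    return scale * fusion_reads / mean_control


def derive_limits(series: ControlSeries) -> ControlLimits:
    """Mean +/- 3 sample SD (n-1 denominator) of the baseline values."""
    if len(series.values) < 2:
        raise ValueError(
            f"analyte {series.analyte_id!r}: need >= 2 baseline values to derive limits, "
            f"got {len(series.values)}"
        )
    values = np.asarray(series.values, dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return ControlLimits(
        analyte_id=series.analyte_id,
        mean=mean,
        sd=sd,
        lower=mean - 3 * sd,
        upper=mean + 3 * sd,
    )


def evaluate_point(value: float, limits: ControlLimits) -> PointStatus:
    """Classify one run's value against [lower, upper], boundaries inclusive."""
    if value < limits.lower:
        return PointStatus.OUT_OF_CONTROL_LOW
    if value > limits.upper:
        return PointStatus.OUT_OF_CONTROL_HIGH
    return PointStatus.IN_CONTROL


def recover_mean_sd(limits: ControlLimits) -> tuple[float, float]:
    """Invert a +/- 3 SD band: mean = midpoint, sd = width / 6."""
    if limits.upper < limits.lower:
        raise ValueError("upper must be >= lower")
    return ((limits.lower + limits.upper) / 2, (limits.upper - limits.lower) / 6)


def limits_from_range(analyte_id: str, lower: float, upper: float) -> ControlLimits:
    """Build ControlLimits from a published (lower, upper) band."""
    mean, sd = recover_mean_sd(
        ControlLimits(analyte_id=analyte_id, mean=0.0, sd=0.0, lower=lower, upper=upper)
    )
    return ControlLimits(analyte_id=analyte_id, mean=mean, sd=sd, lower=lower, upper=upper)


def plot_control_chart(
    series: ControlSeries, limits: ControlLimits, path: str
) -> None:  # pragma: no cover - cosmetic
    """Render one analyte's chart (values vs run, mean and +/-3 SD lines)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(1, len(series.values) + 1)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(x, series.values, "o-", color="tab:blue")
    for y, style, label in (
        (limits.mean, "-", "mean"),
        (limits.lower, "--", "-3 SD"),
        (limits.upper, "--", "+3 SD"),
    ):
        ax.axhline(y, linestyle=style, color="tab:gray", linewidth=1)
        ax.annotate(label, xy=(x[-1], y), fontsize=8, color="tab:gray")
    ax.set_xlabel("run")
    ax.set_ylabel(series.kind.replace("_", " "))
    ax.set_title(series.analyte_id)
    ax.set_xticks(x)
    if series.run_dates:
        ax.set_xticklabels(series.run_dates, rotation=45, ha="right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
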