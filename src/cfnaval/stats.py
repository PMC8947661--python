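"""Analytic-sensitivity, specificity and precision statistics.

These are the summary statistics of a clinical-laboratory validation study:

* dilution-series detection rates and the limit of detection (LOD), defined
  as the lowest analyte concentration still detected in 100% of QC-valid
  replicates;
* negative-cohort specificity, per donor and pooled over the cohort;
* repeatability (within-run) and intermediate-precision (between-run,
  within-lab) coefficients of variation, plus the hit rate of expected
  variants across a multi-run study design.

Conventions that matter for reproducing printed validation tables: standard
deviations use the n-1 (sample) denominator, CV% = 100 * sd / mean, and
display rounding is half-away-from-zero (so a 600.5-copy average prints as
601, not the banker's 600).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .qc import Call

__all__ = [
    "round_half_away",
    "ReplicateSummary",
    "replicate_summary",
    "DilutionSeries",
    "DetectionRate",
    "detection_rate_by_dilution",
    "LODResult",
    "determine_lod",
    "verify_at_lod",
    "SpecificityResult",
    "specificity",
    "hit_rate",
    "PrecisionResult",
    "precision_analysis",
]


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round with ties going away from zero (0.5 -> 1, -0.5 -> -1).

    Python's built-in ``round`` is half-to-even; lab reports round half up
    in magnitude, and the difference is visible on two-replicate averages.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# --- replicate summaries ----------------------------------------------------


@dataclass(frozen=True)
class ReplicateSummary:
    n: int
    mean: float
    sd: float
    cv_percent: float
    display_mean: str
    display_cv: str


def replicate_summary(
    values: Sequence[float], mean_decimals: int = 0, cv_decimals: int = 1
) -> ReplicateSummary:
    """Mean, sample SD and CV% of one replicate group, with display strings.

    ``sd`` and hence ``cv_percent`` use the n-1 denominator and require at
    least two values (a single value yields sd = cv = NaN). A zero mean with
    nonzero values makes CV undefined and raises.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("replicate_summary needs at least one value")
    mean = float(arr.mean())
    if arr.size >= 2:
        sd = float(arr.std(ddof=1))
        if mean == 0:
            if sd > 0:
                raise ValueError("CV undefined: replicate mean is 0 with nonzero spread")
            cv = 0.0
        else:
            cv = 100.0 * sd / mean
    else:
        sd = float("nan")
        cv = float("nan")
    disp_mean = f"{round_half_away(mean, mean_decimals):.{mean_decimals}f}"
    disp_cv = "" if math.isnan(cv) else f"{round_half_away(cv, cv_decimals):.{cv_decimals}f}%"
    return ReplicateSummary(
        n=int(arr.size),
        mean=mean,
        sd=sd,
        cv_percent=cv,
        display_mean=disp_mean,
        display_cv=disp_cv,
    )


# --- dilution series and LOD ------------------------------------------------


@dataclass
class DilutionSeries:
    """Replicate measurements across an ordered dilution ladder.

    ``rows`` is a tidy frame with columns ``dilution`` (labels ordered most
    concentrated first, e.g. D1..D5), ``replicate``, ``measurement`` (NaN
    when the caller reported nothing) and ``call`` (detected / not_detected
    / invalid strings). ``dilution_order`` preserves the ladder ordering
    independent of row order.
    """

    variant_kind: str
    target_id: str
    rows: pd.DataFrame
    dilution_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.variant_kind not in ("fusion", "cna"):
            raise ValueError(f"unknown variant_kind {self.variant_kind!r}")
        missing = {"dilution", "replicate", "measurement", "call"} - set(self.rows.columns)
        if missing:
            raise ValueError(f"dilution series rows missing columns {sorted(missing)}")
        extra = set(self.rows["dilution"]) - set(self.dilution_order)
        if extra:
            raise ValueError(f"rows reference dilutions not in dilution_order: {sorted(extra)}")


@dataclass(frozen=True)
class DetectionRate:
    detected: int
    valid_total: int
    fraction: float  # NaN when no valid replicates


def detection_rate_by_dilution(series: DilutionSeries) -> dict[str, DetectionRate]:
    """Per-dilution detection fraction among QC-valid replicates.

    Invalid calls are excluded from the denominator; a dilution left with
    zero valid replicates gets fraction NaN and a warning.
    """
    if series.rows.empty:
        raise ValueError("dilution series has no rows")
    out: dict[str, DetectionRate] = {}
    for label in series.dilution_order:
        sub = series.rows[series.rows["dilution"] == label]
        valid = sub[sub["call"] != Call.INVALID.value]
        detected = int((valid["call"] == Call.DETECTED.value).sum())
        n_valid = int(len(valid))
        if n_valid == 0:
            warnings.warn(
                f"dilution {label}: no QC-valid replicates; detection rate undefined",
                stacklevel=2,
            )
            frac = float("nan")
        else:
            frac = detected / n_valid
        out[label] = DetectionRate(detected=detected, valid_total=n_valid, fraction=frac)
    return out


@dataclass
class LODResult:
    lod_dilution: str | None
    lod_value: float
    detection_rate_by_dilution: dict[str, DetectionRate]


def determine_lod(series: DilutionSeries) -> LODResult:
    """Limit of detection from a dilution ladder.

    The LOD dilution is the lowest concentration still detected in 100% of
    QC-valid replicates, scanning from the most concentrated end and
    stopping at the first dilution that breaks the streak (detection must be
    consistent down to the LOD). The LOD value is the mean measurement of
    the detected replicates at that dilution. If even the most concentrated
    dilution misses, the LOD is undefined (None, NaN) and a warning is
    issued.
    """
    if len(series.dilution_order) < 2:
        raise ValueError("need >= 2 dilutions to determine an LOD")
    rates = detection_rate_by_dilution(series)
    lod_label: str | None = None
    for label in series.dilution_order:
        rate = rates[label]
        if rate.valid_total > 0 and rate.fraction == 1.0:
            lod_label = label
        else:
            break
    if lod_label is None:
        warnings.warn("no dilution reached 100% detection; LOD undefined", stacklevel=2)
        return LODResult(lod_dilution=None, lod_value=float("nan"), detection_rate_by_dilution=rates)
    sub = series.rows[
        (series.rows["dilution"] == lod_label)
        & (series.rows["call"] == Call.DETECTED.value)
    ]
    lod_value = float(np.asarray(sub["measurement"], dtype=float).mean())
    return LODResult(lod_dilution=lod_label, lod_value=lod_value, detection_rate_by_dilution=rates)


def verify_at_lod(
    calls: Sequence[tuple[str, str | Call]], expected: Sequence[str]
) -> tuple[float, bool]:
    """LOD verification panel: fraction of expected targets detected, pass iff all."""
    if not expected:
        raise ValueError("expected target list must be nonempty")
    observed = {t: (c.value if isinstance(c, Call) else c) for t, c in calls}
    detected = sum(1 for t in expected if observed.get(t) == Call.DETECTED.value)
    fraction = detected / len(expected)
    return fraction, fraction == 1.0


# --- specificity ------------------------------------------------------------


@dataclass
class SpecificityResult:
    variant_kind: str
    per_sample: list[tuple[str, int, int, float]]  # (sample_id, assayed, detected, spec%)
    overall_assayed: int
    overall_detected: int
    overall_specificity_percent: float


def specificity(
    cohort_calls: pd.DataFrame,
    variant_kind: str,
    qc_failed_samples: Sequence[str] = (),
) -> SpecificityResult:
    """Negative-cohort specificity for one variant kind.

    ``cohort_calls`` is a tidy call table (columns ``sample_id,
    variant_kind, call``); every row of the requested kind counts as one
    assayed target. Samples named in ``qc_failed_samples`` are excluded with
    a warning — specificity is only meaningful on QC-passing specimens.
    Specificity per sample is 100 * (assayed - detected) / assayed; the
    overall figures are sums over samples.
    """
    if qc_failed_samples:
        warnings.warn(
            f"excluding QC-failed samples from specificity: {sorted(qc_failed_samples)}",
            stacklevel=2,
        )
        cohort_calls = cohort_calls[~cohort_calls["sample_id"].isin(qc_failed_samples)]
    sub = cohort_calls[cohort_calls["variant_kind"] == variant_kind]
    if sub.empty:
        raise ValueError(f"no {variant_kind!r} rows in cohort call table")
    per_sample: list[tuple[str, int, int, float]] = []
    for sample_id, grp in sub.groupby("sample_id", sort=True):
        assayed = int(len(grp))
        detected = int((grp["call"] == Call.DETECTED.value).sum())
        per_sample.append((str(sample_id), assayed, detected, 100.0 * (assayed - detected) / assayed))
    overall_assayed = sum(a for _, a, _, _ in per_sample)
    overall_detected = sum(d for _, _, d, _ in per_sample)
    return SpecificityResult(
        variant_kind=variant_kind,
        per_sample=per_sample,
        overall_assayed=overall_assayed,
        overall_detected=overall_detected,
        overall_specificity_percent=100.0 * (overall_assayed - overall_detected) / overall_assayed,
    )


# --- precision --------------------------------------------------------------


def hit_rate(detected: int, expected: int) -> float:
    """Percent of expected variant events detected, rounded to 1 decimal."""
    if expected < 1:
        raise ValueError("expected must be >= 1")
    if detected > expected:
        raise ValueError("detected cannot exceed expected")
    return round_half_away(100.0 * detected / expected, 1)


@dataclass
class PrecisionResult:
    hit_rate_detected: int
    hit_rate_expected: int
    hit_rate_percent: float
    cv_by_variant: dict[str, float]
    average_cv: float
    cv_range: tuple[float, float]
    grouping: str


_GROUP_FACTOR = {"by_day": "day", "by_operator": "operator", "by_instrument": "instrument"}


def _cv(values: np.ndarray) -> float:
    mean = values.mean()
    if mean == 0:
        return float("nan")
    return 100.0 * values.std(ddof=1) / mean


def precision_analysis(study: pd.DataFrame, grouping: str = "repeatability") -> PrecisionResult:
    """Hit rate and CVs of a multi-run precision study, per variant.

    ``study`` is the long-format design table (columns ``target_id, run,
    day, operator, instrument, replicate, measurement, call``). The hit rate
    counts every QC-valid row as one detection opportunity: rows with call
    ``invalid`` (specimen censored for that run after failing QC on run and
    rerun) are excluded from the denominator, while ``not_detected`` rows
    count as misses; misses and censored rows never enter a CV.

    Groupings:

    * ``repeatability`` — CV of the within-run replicates, per variant, over
      every run holding >= 2 detected replicates;
    * ``intermediate`` — CV of the per-run mean measurements across runs,
      per variant (the within-laboratory, between-run precision);
    * ``by_day`` / ``by_operator`` / ``by_instrument`` — CV of per-level
      mean measurements across the levels of that single factor.

    A variant whose grouping leaves fewer than two values has its CV
    skipped with a warning.
    """
    required = {"target_id", "run", "day", "operator", "instrument", "replicate", "measurement", "call"}
    missing = required - set(study.columns)
    if missing:
        raise ValueError(f"study table missing columns {sorted(missing)}")
    if grouping not in ("repeatability", "intermediate", *_GROUP_FACTOR):
        raise ValueError(f"unknown grouping {grouping!r}")

    valid = study[study["call"] != Call.INVALID.value]
    expected = int(len(valid))
    detected_mask = valid["call"] == Call.DETECTED.value
    detected = int(detected_mask.sum())
    measured = valid[detected_mask]

    cv_by_variant: dict[str, float] = {}
    for target, grp in measured.groupby("target_id", sort=True):
        values = np.asarray(grp["measurement"], dtype=float)
        if grouping == "repeatability":
            run_cvs = [
                _cv(np.asarray(g["measurement"], dtype=float))
                for _, g in grp.groupby("run")
                if len(g) >= 2
            ]
            if not run_cvs:
                warnings.warn(
                    f"{target}: no run with >= 2 replicates; repeatability CV skipped",
                    stacklevel=2,
                )
                continue
            cv_by_variant[str(target)] = float(np.mean(run_cvs))
            continue
        factor = "run" if grouping == "intermediate" else _GROUP_FACTOR[grouping]
        level_means = grp.groupby(factor)["measurement"].mean().to_numpy(dtype=float)
        if len(level_means) < 2:
            warnings.warn(
                f"{target}: fewer than 2 {factor} levels with data; CV skipped", stacklevel=2
            )
            continue
        cv_by_variant[str(target)] = float(_cv(level_means))

    cvs = np.array(list(cv_by_variant.values()), dtype=float)
    return PrecisionResult(
        hit_rate_detected=detected,
        hit_rate_expected=expected,
        hit_rate_percent=hit_rate(detected, expected),
        cv_by_variant=cv_by_variant,
        average_cv=float(cvs.mean()) if cvs.size else float("nan"),
        cv_range=(float(cvs.min()), float(cvs.max())) if cvs.size else (float("nan"), float("nan")),
        grouping=grouping,
    )
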