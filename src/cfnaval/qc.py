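"""Three-tier QC decision engine for a cfNA panel.

The assay reports two variant classes with different call semantics:

* fusion / exon-skipping events, measured as UMI-deduplicated molecular
  copies and gated against a minimum copy count, with per-sample validity
  certified by four internal process controls (TBP, HMBS and the two MET
  wild-type exon junctions E6-E7 / E11-E12);
* copy-number amplifications (CNA), measured as a fold-change ratio with an
  accompanying caller p-value, gated jointly on both, with per-sample
  validity certified by the MAPD noise metric.

On top of the per-observation calls sit sample-level sequencing gates
(mapped reads, uniformity, molecular coverage, read length, AQ20) and
batch-level acceptance: every batch must carry exactly one positive control
(all expected variants detected) and one no-template control (low signal and
zero detected variants).

All thresholds live in :class:`QCThresholds`; nothing is hard-coded at call
sites.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Call",
    "SampleQCMetrics",
    "QCThresholds",
    "InternalControlPanel",
    "FusionObservation",
    "CNAObservation",
    "BatchVerdict",
    "evaluate_sample_qc",
    "fusion_sample_valid",
    "call_fusion",
    "call_cna",
    "evaluate_ntc",
    "evaluate_positive_control",
    "evaluate_batch",
    "call_observation_table",
]


class Call(str, enum.Enum):
    """Tri-state outcome of a variant-level call."""

    DETECTED = "detected"
    NOT_DETECTED = "not_detected"
    INVALID = "invalid"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SampleQCMetrics:
    """Per-sample sequencing and molecular-coverage metrics.

    Percent-valued fields are on the 0-100 scale; ``mapd`` is the median
    absolute pairwise difference of adjacent copy-number ratios (a noise
    metric, lower is better).
    """

    total_mapped_reads: float
    coverage_uniformity: float
    median_molecular_coverage: float
    molecular_uniformity: float
    mean_read_length: float
    aq20_fraction: float
    mapd: float

    def __post_init__(self) -> None:
        for name in ("coverage_uniformity", "molecular_uniformity", "aq20_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name} must be a percent in [0, 100], got {v!r}")
        if self.mapd < 0:
            raise ValueError(f"mapd must be non-negative, got {self.mapd!r}")


@dataclass(frozen=True)
class QCThresholds:
    """All gate thresholds of the assay, overridable via config.

    Sample-level gates use >= / <= semantics exactly at the boundary except
    MAPD, which is a strict ``< max_mapd`` rule, and the CNA p-value, which
    is a strict ``< cna_max_p`` rule. The CNA ratio gate is inclusive
    (``>= cna_min_ratio``).
    """

    min_mapped_reads: float = 10_000_000
    min_coverage_uniformity: float = 95.0
    min_median_mol_cov: float = 1500
    min_mol_uniformity: float = 80.0
    min_mean_read_length: float = 80.0
    min_aq20: float = 80.0
    max_mapd: float = 0.4
    cna_min_ratio: float = 1.15
    cna_max_p: float = 1e-5
    fusion_min_copies: int = 3
    internal_control_min_copies: int = 3
    ntc_max_reads: float = 6_000_000
    ntc_max_read_length: float = 45.0

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be positive")


@dataclass(frozen=True)
class InternalControlPanel:
    """Molecular counts of the four internal process controls."""

    tbp: int
    hmbs: int
    met_e6_e7: int
    met_e11_e12: int

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"control count {f.name} must be >= 0")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.tbp, self.hmbs, self.met_e6_e7, self.met_e11_e12)


@dataclass
class FusionObservation:
    """One fusion/skipping target in one sample."""

    target_id: str
    molecular_copies: int
    call: Call = Call.NOT_DETECTED


@dataclass
class CNAObservation:
    """One copy-number-amplification target in one sample."""

    target_id: str
    fold_change: float
    p_value: float
    call: Call = Call.NOT_DETECTED

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must be in (0, 1]")


@dataclass
class BatchVerdict:
    positive_control_pass: bool
    ntc_pass: bool
    batch_pass: bool
    reasons: list[str] = field(default_factory=list)


# --- sample-level gates -----------------------------------------------------

#: gate name -> (metric attribute, threshold attribute, comparison)
_SAMPLE_GATES: tuple[tuple[str, str, str, str], ...] = (
    ("mapped_reads", "total_mapped_reads", "min_mapped_reads", "ge"),
    ("coverage_uniformity", "coverage_uniformity", "min_coverage_uniformity", "ge"),
    ("median_molecular_coverage", "median_molecular_coverage", "min_median_mol_cov", "ge"),
    ("molecular_uniformity", "molecular_uniformity", "min_mol_uniformity", "ge"),
    ("mean_read_length", "mean_read_length", "min_mean_read_length", "ge"),
    ("aq20", "aq20_fraction", "min_aq20", "ge"),
    ("mapd", "mapd", "max_mapd", "lt"),
)


def evaluate_sample_qc(
    metrics: SampleQCMetrics, thresholds: QCThresholds | None = None
) -> tuple[bool, list[str]]:
    """Apply every sample-level gate; return (pass, names of failed gates).

    Boundary semantics: all minimum gates are inclusive (a sample exactly at
    10 M reads passes); the MAPD gate is strict (a sample at exactly 0.4
    fails). A missing (None / NaN) metric raises rather than silently
    passing.
    """
    thresholds = thresholds or QCThresholds()
    failed: list[str] = []
    for gate, metric_attr, thr_attr, op in _SAMPLE_GATES:
        value = getattr(metrics, metric_attr)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise ValueError(f"metric {metric_attr!r} is missing; cannot evaluate gate {gate!r}")
        threshold = getattr(thresholds, thr_attr)
        ok = value >= threshold if op == "ge" else value < threshold
        if not ok:
            failed.append(gate)
    return (not failed, failed)


def fusion_sample_valid(
    controls: InternalControlPanel, thresholds: QCThresholds | None = None
) -> bool:
    """Internal-control validity gate for the fusion/skipping class.

    At least one expression control (TBP or HMBS) *and* at least one MET
    wild-type exon junction (E6-E7 or E11-E12) must each reach the minimum
    molecular count.
    """
    thresholds = thresholds or QCThresholds()
    m = thresholds.internal_control_min_copies
    return max(controls.tbp, controls.hmbs) >= m and max(
        controls.met_e6_e7, controls.met_e11_e12
    ) >= m


def call_fusion(
    copies: int,
    controls: InternalControlPanel,
    thresholds: QCThresholds | None = None,
) -> Call:
    """Call one fusion/skipping target: invalid sample -> INVALID, else
    DETECTED iff the molecular count reaches ``fusion_min_copies``."""
    thresholds = thresholds or QCThresholds()
    if copies < 0:
        raise ValueError("molecular copies must be >= 0")
    if not fusion_sample_valid(controls, thresholds):
        return Call.INVALID
    return Call.DETECTED if copies >= thresholds.fusion_min_copies else Call.NOT_DETECTED


def call_cna(
    fold_change: float,
    p_value: float,
    mapd: float,
    thresholds: QCThresholds | None = None,
) -> Call:
    """Call one CNA target.

    The sample-level MAPD gate invalidates the call outright (mapd >= 0.4
    by default); otherwise detection requires the joint gate
    ``fold_change >= cna_min_ratio`` and ``p_value < cna_max_p``.
    """
    thresholds = thresholds or QCThresholds()
    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    if mapd >= thresholds.max_mapd:
        return Call.INVALID
    detected = fold_change >= thresholds.cna_min_ratio and p_value < thresholds.cna_max_p
    return Call.DETECTED if detected else Call.NOT_DETECTED


def evaluate_ntc(
    metrics: SampleQCMetrics,
    detected_variant_count: int,
    thresholds: QCThresholds | None = None,
) -> bool:
    """No-template-control acceptance.

    The NTC passes when it shows negligible library signal — low total
    mapped reads *or* short mean read length — and carries zero detected
    variants. The metric disjunction is deliberate: either symptom of an
    empty library suffices, but variant-freedom is always required.
    """
    thresholds = thresholds or QCThresholds()
    low_signal = (
        metrics.total_mapped_reads <= thresholds.ntc_max_reads
        or metrics.mean_read_length <= thresholds.ntc_max_read_length
    )
    return low_signal and detected_variant_count == 0


def evaluate_positive_control(
    expected_variants: Sequence[str],
    observed_calls: Iterable[tuple[str, Call]],
) -> tuple[bool, list[str]]:
    """Batch positive control: every expected target must be DETECTED.

    A target absent from the observations counts as not positive (with a
    reason naming it), never as an error.
    """
    if not expected_variants:
        raise ValueError("expected_variants must be nonempty")
    calls = {t: c for t, c in observed_calls}
    reasons: list[str] = []
    for target in expected_variants:
        call = calls.get(target)
        if call is None:
            reasons.append(f"positive control target {target!r} missing from call table")
        elif call is not Call.DETECTED:
            reasons.append(f"positive control target {target!r} was {call.value}")
    return (not reasons, reasons)


def _sample_calls(sample, thresholds: QCThresholds) -> list[tuple[str, Call]]:
    """(Re-)call every observation of one sample against the gates."""
    out: list[tuple[str, Call]] = []
    for obs in sample.fusion_rows:
        out.append((obs.target_id, call_fusion(obs.molecular_copies, sample.controls, thresholds)))
    for obs in sample.cna_rows:
        out.append(
            (obs.target_id, call_cna(obs.fold_change, obs.p_value, sample.metrics.mapd, thresholds))
        )
    return out


def evaluate_batch(
    samples: Sequence,
    thresholds: QCThresholds | None = None,
    expected_positive_targets: Sequence[str] | None = None,
) -> BatchVerdict:
    """Batch-level acceptance: positive control AND no-template control.

    ``samples`` are :class:`~cfnaval.synthetic.SimulatedSample` objects or
    any duck-typed equivalent carrying ``role``, ``metrics``,
    ``fusion_rows``, ``cna_rows`` and ``controls``. The batch must contain
    exactly one ``positive_control`` and one ``ntc`` role.

    When ``expected_positive_targets`` is omitted, every target present in
    the positive control's call table is expected to be detected.
    """
    thresholds = thresholds or QCThresholds()
    pcs = [s for s in samples if s.role == "positive_control"]
    ntcs = [s for s in samples if s.role == "ntc"]
    if len(pcs) != 1:
        raise ValueError(f"batch must contain exactly one positive control, found {len(pcs)}")
    if len(ntcs) != 1:
        raise ValueError(f"batch must contain exactly one NTC, found {len(ntcs)}")
    pc, ntc = pcs[0], ntcs[0]

    pc_calls = _sample_calls(pc, thresholds)
    expected = (
        list(expected_positive_targets)
        if expected_positive_targets is not None
        else [t for t, _ in pc_calls]
    )
    pc_pass, reasons = evaluate_positive_control(expected, pc_calls)

    ntc_detected = sum(1 for _, c in _sample_calls(ntc, thresholds) if c is Call.DETECTED)
    ntc_pass = evaluate_ntc(ntc.metrics, ntc_detected, thresholds)
    if not ntc_pass:
        reasons.append(
            "NTC failed: "
            f"{ntc.metrics.total_mapped_reads:.0f} mapped reads, "
            f"{ntc.metrics.mean_read_length:.0f} bp mean read length, "
            f"{ntc_detected} detected variant(s) "
            f"(limits: <= {thresholds.ntc_max_reads:.0f} reads or "
            f"<= {thresholds.ntc_max_read_length:.0f} bp, and 0 variants)"
        )

    return BatchVerdict(
        positive_control_pass=pc_pass,
        ntc_pass=ntc_pass,
        batch_pass=pc_pass and ntc_pass,
        reasons=reasons,
    )


# --- tabular interface ------------------------------------------------------

_CONTROL_COLUMNS = ("tbp", "hmbs", "met_e6_e7", "met_e11_e12")


def call_observation_table(
    calls: pd.DataFrame,
    metrics: pd.DataFrame | None = None,
    thresholds: QCThresholds | None = None,
) -> pd.DataFrame:
    """Apply the call gates to a tidy observation table.

    ``calls`` needs columns ``sample_id, target_id, variant_kind,
    measurement`` plus ``p_value`` and the four internal-control count
    columns (``tbp, hmbs, met_e6_e7, met_e11_e12``) where the corresponding
    variant kind appears. ``metrics`` (one row per sample, with a ``mapd``
    column) supplies the CNA validity gate; omit it to treat every sample's
    MAPD as passing. Returns a copy with a ``call`` column.
    """
    thresholds = thresholds or QCThresholds()
    out = calls.copy()
    mapd_by_sample: dict[str, float] = {}
    if metrics is not None:
        mapd_by_sample = dict(zip(metrics["sample_id"], metrics["mapd"]))

    result: list[str] = []
    for row in out.itertuples(index=False):
        kind = row.variant_kind
        if kind == "fusion":
            controls = InternalControlPanel(
                *(int(getattr(row, c)) for c in _CONTROL_COLUMNS)
            )
            call = call_fusion(int(row.measurement), controls, thresholds)
        elif kind == "cna":
            mapd = mapd_by_sample.get(row.sample_id, 0.0)
            if math.isnan(row.measurement):
                call = Call.NOT_DETECTED if mapd < thresholds.max_mapd else Call.INVALID
            else:
                call = call_cna(float(row.measurement), float(row.p_value), mapd, thresholds)
        else:
            raise ValueError(f"unknown variant_kind {kind!r}")
        result.append(call.value)
    out["call"] = result
    return out
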