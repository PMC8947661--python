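"""Synthetic assay-output generator.

Real validation data for this kind of cfNA panel are not publicly
deposited, so every downstream stage (QC gating, control charting, LOD /
specificity / precision statistics) is exercised against simulated caller
output with the statistical structure the validation assumes:

* fusion/skipping targets yield UMI molecular-family counts whose mean
  scales linearly with the dilution factor of the spiked cell-line
  material; counts are negative-binomial (dispersion 0 degenerates to
  Poisson), because observed replicate CVs at these means exceed pure
  Poisson noise;
* CNA targets yield fold changes 1 + (true_gain - 1) * tumor_fraction plus
  Gaussian measurement noise, attenuating toward 1.0 as the dilution
  removes tumor material, with a one-sided normal-tail p-value computed
  from the standardized excess over 1.0 (the vendor caller's p-value is
  opaque, so the simulator owns this documented stand-in);
* internal process controls (TBP, HMBS, MET E6-E7, MET E11-E12) and
  sample-level run metrics are drawn at levels that pass QC for ordinary
  specimens and fail appropriately for no-template controls.

The unit of simulation is the post-caller molecular count / ratio; no
read-level (FASTQ/BAM) simulation is attempted. Randomness flows through an
explicit ``numpy.random.Generator``; every entry point accepts ``rng`` and
falls back to ``default_rng(profile.seed)``, so identical seed + profile
gives bitwise-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .qc import (
    Call,
    CNAObservation,
    FusionObservation,
    InternalControlPanel,
    QCThresholds,
    SampleQCMetrics,
    call_cna,
    call_fusion,
)
from .stats import DilutionSeries

__all__ = [
    "AssayProfile",
    "PrecisionDesign",
    "SimulatedSample",
    "cna_p_value",
    "simulate_fusion_counts",
    "simulate_cna_ratio",
    "simulate_sample_metrics",
    "simulate_internal_controls",
    "make_dilution_series",
    "make_negative_cohort",
    "make_precision_study",
    "make_batch",
    "cohort_call_table",
    "metrics_table",
]

_P_FLOOR = 1e-300  # p-values live in (0, 1]


@dataclass(frozen=True)
class AssayProfile:
    """Calibration of the generator to the assay's observed behaviour.

    The dilution ladder defaults reproduce the validated five-point series:
    fusion molecular-count means 601, 293, 157, 82 and 42 copies, and CNA
    fold-change means 5.36, 2.30 and 1.40 at dilutions 1-3 with dilutions
    4-5 attenuated below the 1.15-fold call threshold.
    """

    fusion_count_mean_at_neat: float = 601.0
    dilution_factors: tuple[float, ...] = (1.0, 293 / 601, 157 / 601, 82 / 601, 42 / 601)
    #: negative-binomial dispersion a with var = m + a*m^2; 0 means Poisson
    count_dispersion: float = 0.015
    #: TBP, HMBS, MET E6-E7, MET E11-E12 mean molecular counts
    control_count_means: tuple[float, float, float, float] = (1500.0, 1200.0, 800.0, 600.0)
    cna_true_gain: float = 5.36
    tumor_fraction_per_dilution: tuple[float, ...] = (
        1.0,
        1.30 / 4.36,  # -> mean fold change 2.30
        0.40 / 4.36,  # -> mean fold change 1.40 (the CNA LOD)
        0.011,        # -> ~1.05, below the 1.15 call threshold
        0.0046,       # -> ~1.02
    )
    ratio_noise_sd: float = 0.02
    fold_change_floor: float = 0.01
    mapd_mean: float = 0.2
    #: per-target background molecular-count mean in variant-free specimens
    background_fusion_mean: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fusion_count_mean_at_neat <= 0:
            raise ValueError("fusion_count_mean_at_neat must be positive")
        factors = self.dilution_factors
        if not factors or any(not (0 < f <= 1) for f in factors):
            raise ValueError("dilution_factors must lie in (0, 1]")
        if any(not (b < a) for a, b in zip(factors, factors[1:])):
            raise ValueError("dilution_factors must be strictly decreasing")
        if self.count_dispersion < 0:
            raise ValueError("count_dispersion must be >= 0")
        if len(self.tumor_fraction_per_dilution) != len(factors):
            raise ValueError("tumor_fraction_per_dilution must match dilution_factors in length")
        tf = self.tumor_fraction_per_dilution
        if any(not (0 <= t <= 1) for t in tf):
            raise ValueError("tumor fractions must lie in [0, 1]")
        if any(b > a for a, b in zip(tf, tf[1:])):
            raise ValueError("tumor_fraction_per_dilution must be non-increasing")
        if self.ratio_noise_sd < 0 or self.mapd_mean <= 0:
            raise ValueError("ratio_noise_sd must be >= 0 and mapd_mean > 0")
        if self.cna_true_gain < 1:
            raise ValueError("cna_true_gain must be >= 1")
        if any(c <= 0 for c in self.control_count_means):
            raise ValueError("control_count_means must be positive")

    @property
    def n_dilutions(self) -> int:
        return len(self.dilution_factors)

    def _check_index(self, dilution_index: int) -> None:
        if not (0 <= dilution_index < self.n_dilutions):
            raise IndexError(
                f"dilution_index {dilution_index} out of range 0..{self.n_dilutions - 1}"
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class PrecisionDesign:
    """Run layout of the repeatability / intermediate-precision study.

    Three single-fusion specimens (high, medium, low concentration) and two
    CNA specimens carrying five amplification events between them (two
    high-, three low-frequency). Run 1 is the repeatability run with
    within-run triplicates; the remaining runs contribute one replicate
    each, on different days with alternating operators and instruments —
    so the four runs together supply both the within-run and the
    between-run arms, e.g. 3 fusion specimens x (3 + 3) = 18 detection
    opportunities.
    """

    n_fusion_specimens: int = 3
    n_cna_events: int = 5
    repeat_replicates: int = 3
    n_runs: int = 4
    n_operators: int = 2
    n_instruments: int = 2
    #: fusion specimen mean molecular counts, high / medium / low
    fusion_specimen_means: tuple[float, ...] = (601.0, 157.0, 42.0)
    fusion_targets: tuple[str, ...] = ("SLC34A2-ROS1", "EML4-ALK", "TPM3-NTRK1")
    #: CNA event -> (specimen, mean fold change); two high + three low
    cna_events: tuple[tuple[str, str, float], ...] = (
        ("ERBB2", "CNA-S1", 5.36),
        ("CDK6", "CNA-S1", 1.40),
        ("EGFR", "CNA-S1", 1.40),
        ("MET", "CNA-S2", 2.30),
        ("MYC", "CNA-S2", 1.40),
    )
    fusion_within_run_cv: float = 0.205
    fusion_between_run_cv: float = 0.035
    cna_within_run_cv: float = 0.0185
    cna_between_run_cv: float = 0.063
    fusion_days: tuple[int, ...] = (2, 3, 4, 5)
    cna_days: tuple[int, ...] = (1, 3, 4, 5)

    def __post_init__(self) -> None:
        for name in (
            "n_fusion_specimens",
            "n_cna_events",
            "repeat_replicates",
            "n_runs",
            "n_operators",
            "n_instruments",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.fusion_specimen_means) < self.n_fusion_specimens:
            raise ValueError("need a mean for every fusion specimen")
        if len(self.cna_events) < self.n_cna_events:
            raise ValueError("need an event definition for every CNA event")


@dataclass
class SimulatedSample:
    """One simulated specimen: run metrics, internal controls and call rows."""

    sample_id: str
    role: str  # clinical | positive_control | ntc | nhd
    metrics: SampleQCMetrics
    fusion_rows: list[FusionObservation] = field(default_factory=list)
    cna_rows: list[CNAObservation] = field(default_factory=list)
    controls: InternalControlPanel = InternalControlPanel(0, 0, 0, 0)


# --- elementary draws -------------------------------------------------------


def _draw_counts(
    rng: np.random.Generator, mean: float, dispersion: float, n: int
) -> np.ndarray:
    """Negative-binomial counts with var = mean + dispersion * mean^2."""
    if mean <= 0:
        return np.zeros(n, dtype=int)
    if dispersion == 0:
        return rng.poisson(mean, n)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, n)


def cna_p_value(fold_change: np.ndarray | float, noise_sd: float) -> np.ndarray | float:
    """One-sided tail probability of the standardized excess over 1.0.

    p = P(Z > (fc - 1) / noise_sd) under a standard normal; with zero noise
    the limit is taken (1.0 for fc <= 1, the floor otherwise). Clipped into
    (0, 1] so downstream strict-inequality gates stay well defined.
    """
    fc = np.asarray(fold_change, dtype=float)
    if noise_sd <= 0:
        p = np.where(fc > 1.0, _P_FLOOR, 1.0)
    else:
        p = sp_stats.norm.sf((fc - 1.0) / noise_sd)
        p = np.clip(p, _P_FLOOR, 1.0)
    return float(p) if np.isscalar(fold_change) else p


def simulate_fusion_counts(
    profile: AssayProfile,
    dilution_index: int,
    n_replicates: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Molecular-family counts for one dilution of the fusion ladder."""
    profile._check_index(dilution_index)
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = rng if rng is not None else profile.rng()
    mean = profile.fusion_count_mean_at_neat * profile.dilution_factors[dilution_index]
    return _draw_counts(rng, mean, profile.count_dispersion, n_replicates)


def simulate_cna_ratio(
    profile: AssayProfile,
    dilution_index: int,
    n_replicates: int,
    rng: np.random.Generator | None = None,
) -> list[tuple[float, float]]:
    """(fold_change, p_value) pairs for one dilution of the CNA ladder."""
    profile._check_index(dilution_index)
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = rng if rng is not None else profile.rng()
    tf = profile.tumor_fraction_per_dilution[dilution_index]
    mean_fc = 1.0 + (profile.cna_true_gain - 1.0) * tf
    fc = mean_fc + rng.normal(0.0, profile.ratio_noise_sd, n_replicates)
    fc = np.maximum(fc, profile.fold_change_floor)
    p = np.atleast_1d(cna_p_value(fc, profile.ratio_noise_sd))
    return list(zip(fc.tolist(), p.tolist()))


def simulate_internal_controls(
    profile: AssayProfile, rng: np.random.Generator | None = None
) -> InternalControlPanel:
    rng = rng if rng is not None else profile.rng()
    counts = [
        int(_draw_counts(rng, m, profile.count_dispersion, 1)[0])
        for m in profile.control_count_means
    ]
    return InternalControlPanel(*counts)


def simulate_sample_metrics(
    profile: AssayProfile, role: str = "clinical", rng: np.random.Generator | None = None
) -> SampleQCMetrics:
    """Run metrics at QC-passing levels; NTCs get the empty-library signature."""
    rng = rng if rng is not None else profile.rng()
    if role == "ntc":
        return SampleQCMetrics(
            total_mapped_reads=float(max(rng.normal(1.2e6, 2e5), 0.0)),
            coverage_uniformity=float(np.clip(rng.normal(50, 10), 0, 100)),
            median_molecular_coverage=float(max(rng.normal(20, 5), 0.0)),
            molecular_uniformity=float(np.clip(rng.normal(40, 10), 0, 100)),
            mean_read_length=float(max(rng.normal(38, 3), 1.0)),
            aq20_fraction=float(np.clip(rng.normal(85, 3), 0, 100)),
            mapd=float(max(rng.normal(1.0, 0.2), 0.0)),
        )
    return SampleQCMetrics(
        total_mapped_reads=float(rng.normal(13e6, 8e5)),
        coverage_uniformity=float(np.clip(rng.normal(97.5, 0.7), 0, 100)),
        median_molecular_coverage=float(rng.normal(2600, 250)),
        molecular_uniformity=float(np.clip(rng.normal(91, 2.0), 0, 100)),
        mean_read_length=float(rng.normal(98, 4)),
        aq20_fraction=float(np.clip(rng.normal(90, 1.5), 0, 100)),
        mapd=float(np.clip(rng.normal(profile.mapd_mean, 0.03), 0.01, None)),
    )


# --- study-level builders ---------------------------------------------------


def make_dilution_series(
    profile: AssayProfile,
    variant_kind: str,
    replicates_per_dilution: Sequence[int],
    target_id: str | None = None,
    thresholds: QCThresholds | None = None,
    rng: np.random.Generator | None = None,
) -> DilutionSeries:
    """Simulate a full dilution ladder and call every replicate.

    Each replicate is an independent library: it draws its own internal
    controls (fusion) or MAPD (CNA) before the call gates are applied.
    """
    if variant_kind not in ("fusion", "cna"):
        raise ValueError(f"variant_kind must be 'fusion' or 'cna', got {variant_kind!r}")
    if len(replicates_per_dilution) != profile.n_dilutions:
        raise ValueError("replicates_per_dilution must list one count per dilution")
    if sum(replicates_per_dilution) == 0:
        raise ValueError("empty dilution series: all replicate counts are zero")
    thresholds = thresholds or QCThresholds()
    rng = rng if rng is not None else profile.rng()
    target = target_id or ("SLC34A2-ROS1" if variant_kind == "fusion" else "ERBB2")

    records: list[dict] = []
    for i, n_rep in enumerate(replicates_per_dilution):
        if n_rep == 0:
            continue
        label = f"D{i + 1}"
        if variant_kind == "fusion":
            counts = simulate_fusion_counts(profile, i, n_rep, rng)
            for r, c in enumerate(counts, start=1):
                controls = simulate_internal_controls(profile, rng)
                call = call_fusion(int(c), controls, thresholds)
                records.append(
                    dict(
                        dilution=label,
                        replicate=f"R{r}",
                        measurement=float(c),
                        p_value=float("nan"),
                        call=call.value,
                    )
                )
        else:
            pairs = simulate_cna_ratio(profile, i, n_rep, rng)
            for r, (fc, p) in enumerate(pairs, start=1):
                mapd = float(np.clip(rng.normal(profile.mapd_mean, 0.03), 0.01, None))
                call = call_cna(fc, p, mapd, thresholds)
                records.append(
                    dict(
                        dilution=label,
                        replicate=f"R{r}",
                        measurement=fc,
                        p_value=p,
                        call=call.value,
                    )
                )
    rows = pd.DataFrame.from_records(records)
    order = tuple(
        f"D{i + 1}" for i in range(profile.n_dilutions) if replicates_per_dilution[i] > 0
    )
    return DilutionSeries(
        variant_kind=variant_kind, target_id=target, rows=rows, dilution_order=order
    )


def make_negative_cohort(
    n_samples: int,
    n_fusion_targets: int,
    n_cna_targets: int,
    profile: AssayProfile,
    thresholds: QCThresholds | None = None,
    rng: np.random.Generator | None = None,
) -> list[SimulatedSample]:
    """Normal-healthy-donor cohort: valid QC, background-only signal.

    Fusion targets carry only background molecular counts (mean well below
    one copy), CNA targets only measurement noise around fold change 1.0, so
    no target should pass the call gates at the configured noise.
    """
    if min(n_samples, n_fusion_targets, n_cna_targets) < 1:
        raise ValueError("all counts must be >= 1")
    thresholds = thresholds or QCThresholds()
    rng = rng if rng is not None else profile.rng()
    samples: list[SimulatedSample] = []
    for s in range(1, n_samples + 1):
        metrics = simulate_sample_metrics(profile, "clinical", rng)
        controls = simulate_internal_controls(profile, rng)
        counts = _draw_counts(rng, profile.background_fusion_mean, 0.0, n_fusion_targets)
        fusion_rows = [
            FusionObservation(
                target_id=f"FUS{t + 1:03d}",
                molecular_copies=int(c),
                call=call_fusion(int(c), controls, thresholds),
            )
            for t, c in enumerate(counts)
        ]
        fc = np.maximum(
            1.0 + rng.normal(0.0, profile.ratio_noise_sd, n_cna_targets),
            profile.fold_change_floor,
        )
        pvals = np.atleast_1d(cna_p_value(fc, profile.ratio_noise_sd))
        cna_rows = [
            CNAObservation(
                target_id=f"CNA{t + 1:02d}",
                fold_change=float(f),
                p_value=float(p),
                call=call_cna(float(f), float(p), metrics.mapd, thresholds),
            )
            for t, (f, p) in enumerate(zip(fc, pvals))
        ]
        samples.append(
            SimulatedSample(
                sample_id=f"NHD{s}",
                role="nhd",
                metrics=metrics,
                fusion_rows=fusion_rows,
                cna_rows=cna_rows,
                controls=controls,
            )
        )
    return samples


def make_precision_study(
    profile: AssayProfile,
    design: PrecisionDesign | None = None,
    thresholds: QCThresholds | None = None,
    rng: np.random.Generator | None = None,
    censor: Sequence[tuple[str, int]] = (),
    force_subthreshold: Sequence[tuple[str, int]] = (),
) -> pd.DataFrame:
    """Long-format repeatability / intermediate-precision study table.

    Measurements are specimen mean x multiplicative between-run effect x
    within-run noise (both Gaussian on the CV scale). ``censor`` marks
    (target_id, run) cells whose specimen failed QC on run and rerun —
    those rows come back ``invalid`` and drop out of both hit rate and CVs.
    ``force_subthreshold`` pins a CNA event's fold change just below the
    call threshold in one run, producing a clean miss.
    """
    design = design or PrecisionDesign()
    thresholds = thresholds or QCThresholds()
    rng = rng if rng is not None else profile.rng()
    censor_set = {(t, r) for t, r in censor}
    force_set = {(t, r) for t, r in force_subthreshold}

    operators = [f"OP{(r % design.n_operators) + 1}" for r in range(design.n_runs)]
    instruments = [
        f"INST{((r // 2) % design.n_instruments) + 1}" for r in range(design.n_runs)
    ]

    records: list[dict] = []

    def run_rows(kind: str, specimen: str, target: str, mean: float, days: Sequence[int]) -> None:
        within_cv = design.fusion_within_run_cv if kind == "fusion" else design.cna_within_run_cv
        between_cv = (
            design.fusion_between_run_cv if kind == "fusion" else design.cna_between_run_cv
        )
        for run in range(1, design.n_runs + 1):
            run_mean = mean * max(1.0 + rng.normal(0.0, between_cv), 0.05)
            n_rep = design.repeat_replicates if run == 1 else 1
            for rep in range(1, n_rep + 1):
                value = run_mean * max(1.0 + rng.normal(0.0, within_cv), 0.0)
                if kind == "fusion":
                    value = float(max(round(value), 0))
                    p = float("nan")
                    call = call_fusion(
                        int(value), simulate_internal_controls(profile, rng), thresholds
                    )
                else:
                    if (target, run) in force_set:
                        # pinned just under the ratio gate: a clean miss
                        value = thresholds.cna_min_ratio - 0.05
                    value = float(max(value, profile.fold_change_floor))
                    p = float(cna_p_value(value, profile.ratio_noise_sd))
                    mapd = float(np.clip(rng.normal(profile.mapd_mean, 0.03), 0.01, None))
                    call = call_cna(value, p, mapd, thresholds)
                if (target, run) in censor_set:
                    call = Call.INVALID
                records.append(
                    dict(
                        specimen_id=specimen,
                        variant_kind=kind,
                        target_id=target,
                        run=run,
                        day=days[run - 1] if run - 1 < len(days) else run,
                        operator=operators[run - 1],
                        instrument=instruments[run - 1],
                        replicate=rep,
                        measurement=value,
                        p_value=p,
                        call=call.value,
                    )
                )

    levels = ("high", "medium", "low")
    for i in range(design.n_fusion_specimens):
        mean = design.fusion_specimen_means[i]
        target = design.fusion_targets[i % len(design.fusion_targets)]
        specimen = f"FUS-{levels[i % 3].upper()}"
        run_rows("fusion", specimen, target, mean, design.fusion_days)
    for gene, specimen, mean in design.cna_events[: design.n_cna_events]:
        run_rows("cna", specimen, gene, mean, design.cna_days)

    return pd.DataFrame.from_records(records)


def make_batch(
    profile: AssayProfile,
    n_clinical: int = 3,
    thresholds: QCThresholds | None = None,
    rng: np.random.Generator | None = None,
    fail_positive_control: bool = False,
    contaminate_ntc: bool = False,
) -> list[SimulatedSample]:
    """One sequencing batch: positive control + NTC + clinical specimens.

    The positive control carries the three monitored fusion transcripts and
    one CNA gain at comfortably detectable levels; the failure switches
    exist so batch-rejection paths are testable.
    """
    thresholds = thresholds or QCThresholds()
    rng = rng if rng is not None else profile.rng()
    samples: list[SimulatedSample] = []

    pc_metrics = simulate_sample_metrics(profile, "clinical", rng)
    pc_controls = simulate_internal_controls(profile, rng)
    pc_fusions = []
    for target, mean in (("EML4-ALK", 500.0), ("CCDC6-RET", 300.0), ("CD74-ROS1", 200.0)):
        copies = int(_draw_counts(rng, mean, profile.count_dispersion, 1)[0])
        if fail_positive_control and target == "CD74-ROS1":
            copies = 0
        pc_fusions.append(
            FusionObservation(target, copies, call_fusion(copies, pc_controls, thresholds))
        )
    fc = float(max(2.9 + rng.normal(0.0, profile.ratio_noise_sd), profile.fold_change_floor))
    p = float(cna_p_value(fc, profile.ratio_noise_sd))
    pc_cna = [CNAObservation("ERBB2", fc, p, call_cna(fc, p, pc_metrics.mapd, thresholds))]
    samples.append(
        SimulatedSample("PC", "positive_control", pc_metrics, pc_fusions, pc_cna, pc_controls)
    )

    ntc_metrics = simulate_sample_metrics(profile, "ntc", rng)
    ntc_controls = InternalControlPanel(0, 0, 0, 0)
    ntc_copies = 5 if contaminate_ntc else 0
    ntc_fusions = [
        FusionObservation(
            "EML4-ALK",
            ntc_copies,
            call_fusion(
                ntc_copies,
                InternalControlPanel(10, 10, 10, 10) if contaminate_ntc else ntc_controls,
                thresholds,
            ),
        )
    ]
    samples.append(
        SimulatedSample(
            "NTC",
            "ntc",
            ntc_metrics,
            ntc_fusions,
            [],
            InternalControlPanel(10, 10, 10, 10) if contaminate_ntc else ntc_controls,
        )
    )

    for i in range(1, n_clinical + 1):
        metrics = simulate_sample_metrics(profile, "clinical", rng)
        controls = simulate_internal_controls(profile, rng)
        copies = int(_draw_counts(rng, 40.0, profile.count_dispersion, 1)[0])
        fusions = [
            FusionObservation("SLC34A2-ROS1", copies, call_fusion(copies, controls, thresholds))
        ]
        samples.append(SimulatedSample(f"CL{i}", "clinical", metrics, fusions, [], controls))
    return samples


def cohort_call_table(samples: Sequence[SimulatedSample]) -> pd.DataFrame:
    """Flatten simulated samples into the tidy call-table schema.

    Columns: sample_id, target_id, variant_kind, measurement, p_value, call,
    plus the four internal-control counts repeated per row.
    """
    records: list[dict] = []
    for s in samples:
        tbp, hmbs, met67, met1112 = s.controls.as_tuple()
        base = dict(
            sample_id=s.sample_id, tbp=tbp, hmbs=hmbs, met_e6_e7=met67, met_e11_e12=met1112
        )
        for obs in s.fusion_rows:
            records.append(
                dict(
                    base,
                    target_id=obs.target_id,
                    variant_kind="fusion",
                    measurement=float(obs.molecular_copies),
                    p_value=float("nan"),
                    call=obs.call.value,
                )
            )
        for obs in s.cna_rows:
            records.append(
                dict(
                    base,
                    target_id=obs.target_id,
                    variant_kind="cna",
                    measurement=obs.fold_change,
                    p_value=obs.p_value,
                    call=obs.call.value,
                )
            )
    cols = [
        "sample_id",
        "target_id",
        "variant_kind",
        "measurement",
        "p_value",
        "call",
        "tbp",
        "hmbs",
        "met_e6_e7",
        "met_e11_e12",
    ]
    return pd.DataFrame.from_records(records, columns=cols)


def metrics_table(samples: Sequence[SimulatedSample]) -> pd.DataFrame:
    """One row of run metrics per sample, with its role."""
    return pd.DataFrame.from_records(
        [
            dict(
                sample_id=s.sample_id,
                role=s.role,
                total_mapped_reads=s.metrics.total_mapped_reads,
                coverage_uniformity=s.metrics.coverage_uniformity,
                median_molecular_coverage=s.metrics.median_molecular_coverage,
                molecular_uniformity=s.metrics.molecular_uniformity,
                mean_read_length=s.metrics.mean_read_length,
                aq20_fraction=s.metrics.aq20_fraction,
                mapd=s.metrics.mapd,
            )
            for s in samples
        ]
    )
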