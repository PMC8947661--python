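# Methods

## Scope and data model

`cfnaval` operates downstream of the sequencing vendor's variant caller:
its unit of analysis is the summarized caller output — a UMI-deduplicated
molecular-family count per fusion/skipping target, a (fold change,
p-value) pair per CNA target, the four internal-process-control counts
(TBP, HMBS, MET E6-E7, MET E11-E12) per sample, and per-sample run metrics
(mapped reads, uniformity, molecular coverage, read length, AQ20 fraction,
MAPD). It does not re-implement molecular-family deduplication, CNA
segmentation, or anything at the read level (no FASTQ/BAM), and it does
not model SNV/INDEL calling.

## QC decision procedure

Three tiers, all thresholds collected in one overridable `QCThresholds`
object:

1. **Sample gates.** Minimum gates are inclusive (a sample exactly at
   10 M mapped reads passes); the MAPD noise gate is strict (< 0.4, so
   exactly 0.4 fails). A missing metric raises instead of silently
   passing.
2. **Variant calls.** Every observation ends in exactly one of
   {detected, not_detected, invalid}. Fusion/skipping: invalid when the
   internal-control rule fails (need ≥3 copies in at least one of
   {TBP, HMBS} *and* one of {MET E6-E7, MET E11-E12}), else detected at
   ≥3 molecular copies. CNA: invalid when the sample MAPD gate fails,
   else detected when fold change ≥ 1.15 *and* p < 10⁻⁵ (ratio gate
   inclusive, p gate strict). The assay literature is not perfectly
   consistent about whether the ratio cutoff is ">1.15" or "≥1.15" (and
   one passage even says "≥1.5-fold", which is inconsistent with every
   reported call table and is treated as a typographical artifact); we
   use ≥ 1.15, the reading under which the reported call tables are
   self-consistent. The caller's p-value definition (one- vs two-sided)
   is unknown; the engine treats it as an opaque number to threshold.
3. **Batch acceptance.** Exactly one positive control and one NTC per
   batch. The positive control must detect *all* expected variants; the
   NTC must look like an empty library (≤6 M mapped reads *or* ≤45 bp
   mean read length — either symptom suffices) *and* carry zero detected
   variants. The conjunction with variant-freedom is fixed; only the two
   metric criteria are disjunctive.

Raising any minimum threshold can only demote a call (detected →
not_detected/invalid), a monotonicity property the test suite checks.

## Control charts

Each monitored positive-control analyte accumulates one value per baseline
run: CNA analytes use the fold change directly; fusion analytes use reads
normalized to the arithmetic mean of the four internal-control counts,
times a configurable scale constant (the plotted units are a lab
convention; default 1). Limits are mean ± 3 sample SD (n−1); at least two
baseline runs are required, and classification is closed-interval (a value
exactly on a limit is in control — the convention is not dictated by the
source material, so we chose the inclusive reading and made it explicit).
Negative lower limits are not floored. No Westgard multi-rules (1-2s,
2-2s, R-4s, …) are applied — only the single ±3 SD rule. The
`recover_mean_sd` inverse (mean = midpoint, sd = width/6) exists so
published QC ranges can be turned back into working limits; derive →
recover round-trips to 1e-9.

## Validation statistics

* **Replicate summaries.** Mean, sample SD (n−1) and CV% = 100·s/x̄.
  The n−1 convention is decisive for matching printed validation tables:
  on a triplicate such as (66, 98, 81) the population SD would print a
  16.0% CV where the sample SD prints 19.6%, and on two-replicate rows
  the discrepancy is larger still. Display rounding is half-away-from-zero
  (600.5 → 601, where half-to-even would give 600); decimals are
  configurable per table (0 for molecular counts, 2 for fold changes, 1
  for CVs).
* **Detection rates and LOD.** Per dilution, invalid calls leave the
  denominator; a dilution with no valid replicate is flagged, not
  averaged. The LOD is the lowest concentration still detected in 100% of
  QC-valid replicates, scanning from the most concentrated dilution and
  stopping at the first break — detection must be consistent down to the
  LOD. The LOD value is the mean measurement of the detected replicates
  at that dilution. A probit-style LOD95 fit is deliberately out of
  scope; the validation design asks for the consistent-detection rule.
* **Specificity.** Per donor, 100·(assayed − detected)/assayed; pooled
  values are sums over donors (so pooled assayed/detected always equal
  the column sums). QC-failed samples are excluded with a warning.
* **Precision.** The study design runs each specimen in triplicate within
  one run (repeatability) and across four runs on different days with two
  operators and two instruments (intermediate precision), the triplicate
  run being one of the four — which is why three single-fusion specimens
  yield 3 × (3 + 3) = 18 detection opportunities. Hit rate counts every
  QC-valid row as one opportunity: a specimen-run censored after failing
  QC on run and rerun leaves the denominator entirely; a sub-threshold
  event counts as a miss. Misses and censored rows never enter a CV.
  Repeatability CV is the CV of within-run replicates per variant;
  intermediate CV is the CV of per-run mean measurements across runs —
  a simple pooled CV, not an ANOVA variance-component decomposition
  (the validation reports single CVs; components would be a natural
  extension). Whether intermediate precision should pool raw replicates
  instead of per-run means is genuinely open; per-run means are the
  default, and the single-factor groupings (`by_day`, `by_operator`,
  `by_instrument`) use the same level-mean construction.

## Synthetic-data generator

No raw validation data for this class of assay are publicly deposited, so
the generator emulates the caller-output patterns the statistics consume.

* **Fusion counts:** negative binomial with var = m + α·m², α = 0
  degenerating to Poisson. Overdispersion is configurable because
  observed replicate CVs at means of 42–601 copies (8.6–23%) exceed pure
  Poisson CV at those means; the default α = 0.015 sits inside that band.
  No distributional form is given by the assay documentation — NB is a
  modeling choice.
* **Dilution ladder:** count mean = neat mean × dilution factor. The
  default calibration reproduces the validated series means 601, 293,
  157, 82, 42 copies.
* **CNA fold change:** 1 + (true gain − 1)·tumor fraction + N(0, σ),
  floored at a small positive constant. Defaults put dilutions 1–3 at
  5.36, 2.30, 1.40 and dilutions 4–5 near 1.05 and 1.02, below the
  1.15-fold gate. σ defaults to 0.02, the noise scale implied by the
  1.4% CV observed at the 1.40-fold LOD level (a single constant σ cannot
  simultaneously match the larger absolute spread at high fold changes;
  the LOD neighborhood is where the noise scale matters for calling).
* **CNA p-value:** the caller's p-value is opaque, so the simulator owns
  a documented stand-in: the one-sided normal tail of the standardized
  excess, p = P(Z > (fc − 1)/σ), clipped into (0, 1]; with σ = 0 the
  limit is taken (1 for fc ≤ 1). Under the defaults the p-gate is
  essentially implied by the ratio gate, which matches how the two gates
  co-fire in practice.
* **Negative cohorts:** background-only signal — per-target Poisson
  counts with mean 0.01 (so a ≥3-copy call is a ~10⁻⁷ event per target)
  and null fold changes 1 + N(0, σ). With the defaults, a hundred
  simulated cohorts produce zero detected calls.
* **Precision studies:** measurement = specimen mean × (1 + between-run
  noise) × (1 + within-run noise), both Gaussian on the CV scale; fusion
  values rounded to integer counts. Default noise levels are set to the
  validated assay's reported precision (fusion ≈ 20.5% within-run with a
  small between-run component topping up to ≈ 20.8%; CNA 1.85% / 6.59%),
  as the study conditions being emulated. `censor` and
  `force_subthreshold` hooks reproduce the two real-world blemishes of a
  precision study: a specimen-run removed for QC and a low-level event
  falling under the call threshold.
* **Run metrics / internal controls** are drawn at comfortably passing
  levels for ordinary samples and at empty-library levels for NTCs; they
  exercise the gates' plumbing, not the physics of sequencing.

Randomness flows through an explicit `numpy.random.Generator`; every
entry point accepts `rng` and falls back to `default_rng(profile.seed)`,
so identical seed + profile reproduces tables bitwise.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing-level failure modes (adapter dimers,
barcode hopping, strand bias), correlated noise across targets within a
library, matrix effects of real plasma, pre-analytic degradation, and any
SNV/INDEL biology. Passing tests demonstrate that the decision logic and
statistics are correct for caller output with the assumed structure, not
that the wet-lab assay performs to specification.

## Numerical choices and degenerate inputs

* Sample SD everywhere (n−1); CV undefined (error) when the mean is 0
  with nonzero spread; a single replicate yields NaN SD/CV rather than 0.
* Display rounding half-away-from-zero via decimal arithmetic, never
  float tricks.
* Control-limit round-trip tolerance 1e-9 relative to the band scale.
* Empty dilution series, all-invalid dilutions, batches without exactly
  one PC and one NTC, all-zero internal controls, and missing metrics all
  raise or warn explicitly — never a silent pass.
* p-values are clipped to ≥1e-300 so strict-inequality gates never see 0.

## Problem sizes

The shipped study sizes mirror the validation design they emulate: a
five-point ladder with (2, 3, 3, 3, 3) replicates, a 12-donor × (95 + 12)-
target negative cohort, and a 4-run precision study with 18 fusion and 30
CNA opportunity rows. Monte-Carlo calibration checks use 1000 replicates
per dilution and 200 simulated precision studies, at which sizes the 3-SE
recovery criteria are sharp enough to catch a miscalibrated mean or CV.

## Known limitations

* Intermediate precision is a pooled CV, not variance components; with
  one replicate per non-repeatability run, operator and instrument
  effects are aliased with days and cannot be separated.
* The published ±3 SD QC ranges of the five chart analytes cannot be
  recomputed without the underlying 7-day baseline values, which are not
  public; the chart module is therefore validated by closed-form
  round-trip and classification properties, plus ranges back-solved from
  the published bands.
* The generator's NB/Gaussian noise families are assumptions; real caller
  output may be heavier-tailed.
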