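"""Validation-statistics tests: replicate summaries, LOD, specificity, precision."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfnaval.stats import (
    determine_lod,
    detection_rate_by_dilution,
    hit_rate,
    precision_analysis,
    replicate_summary,
    round_half_away,
    specificity,
    verify_at_lod,
)
from cfnaval.synthetic import AssayProfile, cohort_call_table, make_negative_cohort

from conftest import (
    CNA_LADDER,
    CNA_PRINTED,
    FUSION_LADDER,
    FUSION_PRINTED,
    ladder_to_series,
)


def brute_mean_sd_cv(values):
    """Independent pure-Python mean / sample-SD / CV oracle."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    sd = math.sqrt(var)
    return mean, sd, 100.0 * sd / mean


class TestReplicateSummary:
    @pytest.mark.parametrize("dilution", sorted(FUSION_LADDER))
    def test_fusion_ladder_cells_reproduce(self, dilution):
        """Every printed average and CV of the fusion dilution series."""
        summ = replicate_summary(FUSION_LADDER[dilution], mean_decimals=0)
        avg, cv = FUSION_PRINTED[dilution]
        assert summ.display_mean == avg
        assert summ.display_cv == cv

    @pytest.mark.parametrize("dilution", sorted(CNA_PRINTED))
    def test_cna_ladder_cells_reproduce(self, dilution):
        summ = replicate_summary(CNA_LADDER[dilution], mean_decimals=2)
        avg, cv = CNA_PRINTED[dilution]
        assert summ.display_mean == avg
        assert summ.display_cv == cv

    def test_sample_sd_convention_is_decisive(self):
        """(66, 98, 81): population SD would print 16.0% CV; n-1 gives 19.6%."""
        summ = replicate_summary([66, 98, 81])
        assert summ.sd == pytest.approx(16.0104, abs=1e-3)
        pop_sd = float(np.std([66, 98, 81]))
        assert round_half_away(100 * pop_sd / summ.mean, 1) == 16.0
        assert summ.display_cv == "19.6%"

    def test_constant_replicates_have_zero_cv(self):
        assert replicate_summary([7, 7, 7]).cv_percent == 0.0

    def test_zero_mean_with_spread_is_undefined(self):
        with pytest.raises(ValueError, match="CV undefined"):
            replicate_summary([-1.0, 1.0])

    def test_half_away_rounding(self):
        """600.5 prints as 601 (half away from zero), not banker's 600."""
        assert round_half_away(600.5) == 601
        assert round_half_away(0.25, 1) == 0.3
        assert replicate_summary([549, 652]).display_mean == "601"


@settings(max_examples=300, derandomize=True, deadline=None)
@given(
    values=st.lists(
        st.floats(min_value=0.1, max_value=1e4, allow_nan=False), min_size=2, max_size=10
    )
)
def test_summary_matches_brute_force_oracle(values):
    """Mean/SD/CV agree with an independent recomputation to 1e-9 relative."""
    summ = replicate_summary(values)
    mean, sd, cv = brute_mean_sd_cv(values)
    assert summ.mean == pytest.approx(mean, rel=1e-9)
    assert summ.sd == pytest.approx(sd, rel=1e-9, abs=1e-12)
    assert summ.cv_percent == pytest.approx(cv, rel=1e-9, abs=1e-12)


class TestDetectionAndLOD:
    def test_fusion_ladder_fully_detected(self, fusion_series):
        rates = detection_rate_by_dilution(fusion_series)
        assert all(r.fraction == 1.0 for r in rates.values())

    def test_cna_ladder_detected_through_d3_only(self, cna_series):
        rates = detection_rate_by_dilution(cna_series)
        assert [rates[d].fraction for d in ("D1", "D2", "D3", "D4", "D5")] == [1, 1, 1, 0, 0]

    def test_invalid_calls_leave_the_denominator(self, fusion_series):
        rows = fusion_series.rows.copy()
        rows.loc[rows["dilution"] == "D5", "call"] = ["invalid", "detected", "detected"]
        fusion_series.rows = rows
        rates = detection_rate_by_dilution(fusion_series)
        assert rates["D5"].valid_total == 2 and rates["D5"].fraction == 1.0

    def test_all_invalid_dilution_is_flagged(self, fusion_series):
        rows = fusion_series.rows.copy()
        rows.loc[rows["dilution"] == "D5", "call"] = "invalid"
        fusion_series.rows = rows
        with pytest.warns(UserWarning, match="no QC-valid"):
            rates = detection_rate_by_dilution(fusion_series)
        assert math.isnan(rates["D5"].fraction)

    def test_fusion_lod_is_lowest_dilution(self, fusion_series):
        lod = determine_lod(fusion_series)
        assert lod.lod_dilution == "D5"
        assert lod.lod_value == pytest.approx(42.0)

    def test_cna_lod_stops_at_d3(self, cna_series):
        lod = determine_lod(cna_series)
        assert lod.lod_dilution == "D3"
        assert lod.lod_value == pytest.approx(1.40)

    def test_single_fully_detected_dilution(self):
        series = ladder_to_series({"D1": [10.0, 12.0], "D2": [None, None]}, "fusion", "X")
        assert determine_lod(series).lod_dilution == "D1"

    def test_no_detection_anywhere_is_flagged(self):
        series = ladder_to_series({"D1": [None, None], "D2": [None, None]}, "cna", "X")
        with pytest.warns(UserWarning, match="LOD undefined"):
            lod = determine_lod(series)
        assert lod.lod_dilution is None and math.isnan(lod.lod_value)

    def test_verification_panel_at_lod(self):
        calls = [("EGFR", "detected"), ("ERBB2", "detected"), ("MET", "detected")]
        assert verify_at_lod(calls, ["EGFR", "ERBB2", "MET"]) == (1.0, True)
        calls[1] = ("ERBB2", "not_detected")
        frac, ok = verify_at_lod(calls, ["EGFR", "ERBB2", "MET"])
        assert frac == pytest.approx(2 / 3) and not ok


class TestSpecificity:
    def _cohort(self, n=3, fus=5, cna=2, seed=11):
        profile = AssayProfile(seed=seed)
        return cohort_call_table(make_negative_cohort(n, fus, cna, profile))

    def test_counts_and_conservation(self):
        table = self._cohort()
        res = specificity(table, "fusion")
        assert res.overall_assayed == 15
        assert res.overall_assayed == sum(a for _, a, _, _ in res.per_sample)
        assert res.overall_detected == sum(d for _, _, d, _ in res.per_sample)

    def test_one_detection_among_1140(self):
        """Arithmetic check: one hit gives 99.9% pooled, 98.9% for that donor."""
        records = [
            dict(sample_id=f"NHD{s}", variant_kind="fusion", call="not_detected")
            for s in range(1, 13)
            for _ in range(95)
        ]
        df = pd.DataFrame(records)
        df.loc[0, "call"] = "detected"
        res = specificity(df, "fusion")
        assert res.overall_assayed == 1140 and res.overall_detected == 1
        assert res.overall_specificity_percent == pytest.approx(99.912, abs=1e-3)
        per = dict((s, p) for s, _, _, p in res.per_sample)
        assert per["NHD1"] == pytest.approx(98.947, abs=1e-3)
        assert all(p == 100.0 for s, p in per.items() if s != "NHD1")

    def test_qc_failed_samples_are_excluded_with_warning(self):
        table = self._cohort()
        with pytest.warns(UserWarning, match="excluding"):
            res = specificity(table, "fusion", qc_failed_samples=["NHD1"])
        assert res.overall_assayed == 10


class TestPrecision:
    @pytest.mark.parametrize(
        "detected, expected, pct", [(18, 18, 100.0), (28, 29, 96.6), (0, 7, 0.0)]
    )
    def test_hit_rate_rounding(self, detected, expected, pct):
        assert hit_rate(detected, expected) == pct

    def _study(self, measurements):
        """Tiny 2-run design: run 1 triplicate, run 2 singleton."""
        records = []
        for target, per_run in measurements.items():
            for run, values in enumerate(per_run, start=1):
                for rep, (value, call) in enumerate(values, start=1):
                    records.append(
                        dict(
                            target_id=target,
                            run=run,
                            day=run,
                            operator=f"OP{run % 2 + 1}",
                            instrument="INST1",
                            replicate=rep,
                            measurement=value,
                            call=call,
                        )
                    )
        return pd.DataFrame.from_records(records)

    def test_identical_measurements_give_zero_cv_and_full_hit_rate(self):
        study = self._study({"X": [[(5.0, "detected")] * 3, [(5.0, "detected")]]})
        rep = precision_analysis(study, "repeatability")
        inter = precision_analysis(study, "intermediate")
        assert rep.hit_rate_percent == 100.0
        assert rep.average_cv == 0.0 and inter.average_cv == 0.0

    def test_miss_counts_against_hit_rate_but_not_cv(self):
        study = self._study(
            {"X": [[(10.0, "detected"), (12.0, "detected"), (1.0, "not_detected")], [(11.0, "detected")]]}
        )
        rep = precision_analysis(study, "repeatability")
        assert (rep.hit_rate_detected, rep.hit_rate_expected) == (3, 4)
        # CV uses only the two detected replicates of run 1
        _, _, cv = brute_mean_sd_cv([10.0, 12.0])
        assert rep.cv_by_variant["X"] == pytest.approx(cv)

    def test_censored_rows_leave_the_denominator(self):
        study = self._study({"X": [[(10.0, "detected")] * 3, [(0.0, "invalid")]]})
        rep = precision_analysis(study, "repeatability")
        assert (rep.hit_rate_detected, rep.hit_rate_expected) == (3, 3)

    def test_intermediate_uses_per_run_means(self):
        study = self._study(
            {"X": [[(8.0, "detected"), (12.0, "detected"), (10.0, "detected")], [(20.0, "detected")]]}
        )
        inter = precision_analysis(study, "intermediate")
        _, _, cv = brute_mean_sd_cv([10.0, 20.0])  # run means
        assert inter.cv_by_variant["X"] == pytest.approx(cv)

    def test_single_run_variant_skipped_with_warning(self):
        study = self._study({"X": [[(10.0, "detected")] * 3]})
        with pytest.warns(UserWarning, match="fewer than 2 run"):
            inter = precision_analysis(study, "intermediate")
        assert "X" not in inter.cv_by_variant

    def test_factor_groupings_use_level_means(self):
        study = self._study(
            {"X": [[(8.0, "detected"), (12.0, "detected")], [(20.0, "detected")]]}
        )
        by_op = precision_analysis(study, "by_operator")
        _, _, cv = brute_mean_sd_cv([10.0, 20.0])  # OP2 mean 10, OP1 mean 20
        assert by_op.cv_by_variant["X"] == pytest.approx(cv)

    def test_unknown_grouping_rejected(self):
        study = self._study({"X": [[(1.0, "detected")] * 2]})
        with pytest.raises(ValueError, match="grouping"):
            precision_analysis(study, "bogus")
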