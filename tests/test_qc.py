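"""Control-based QC: formulas, threshold monotonicity, variability, pass/fail."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from platescreen import (
    AnalysisConfig,
    ScreenDataset,
    SimulationConfig,
    WellAddress,
    WellRecord,
    WellRole,
    WellStatus,
    control_variability,
    plate_pass_fail,
    plate_sensitivity_specificity,
    score_screen,
    screen_qc_summary,
    sensitivity_from_counts,
    simulate_screen,
    specificity_from_counts,
    ssmd_star,
)
from tests.conftest import make_plate


@given(tp=st.integers(0, 50), fn=st.integers(0, 50))
def test_sensitivity_is_the_quoted_formula(tp, fn):
    got = sensitivity_from_counts(tp, fn)
    if tp + fn == 0:
        assert got is None
    else:
        assert got == pytest.approx(100.0 * tp / (tp + fn))
        assert 0.0 <= got <= 100.0


@given(tn=st.integers(0, 50), fp=st.integers(0, 50))
def test_specificity_is_the_quoted_formula(tn, fp):
    got = specificity_from_counts(tn, fp)
    if tn + fp == 0:
        assert got is None
    else:
        assert got == pytest.approx(100.0 * tn / (tn + fp))


def test_worked_count_examples():
    assert sensitivity_from_counts(11, 1) == pytest.approx(100 * 11 / 12)
    assert specificity_from_counts(10, 2) == pytest.approx(100 * 10 / 12)
    assert sensitivity_from_counts(12, 0) == 100.0


class TestPlateQC:
    def _scored_plate(self, small_config, pos, neg):
        plate = make_plate(
            [10, 12, 14, 16, 18], positive_readings=pos, negative_readings=neg
        )
        return ssmd_star(plate, small_config)

    def test_counts_partition_controls(self, small_config):
        scores = self._scored_plate(small_config, [6, 7, 20], [13, 14, 15])
        qc = plate_sensitivity_specificity(scores, -0.5)
        assert qc.tp + qc.fn == 3
        assert qc.tn + qc.fp == 3
        assert qc.tp == 2  # wells at 6 and 7 fall below -0.5; 20 does not
        assert qc.fp == 0

    def test_control_exactly_at_threshold_is_not_a_hit(self, small_config):
        # use a control's own realised score as the cutoff: strict < means
        # a control sitting exactly at the threshold is a true negative
        scores = self._scored_plate(small_config, [6], [12])
        at_threshold = scores.scores_for_role(WellRole.NEGATIVE_CONTROL)[0]
        qc = plate_sensitivity_specificity(scores, at_threshold)
        assert qc.tn == 1 and qc.fp == 0

    def test_missing_control_type_flags_metric(self, small_config):
        scores = self._scored_plate(small_config, [], [13, 15])
        qc = plate_sensitivity_specificity(scores, -0.5)
        assert qc.sensitivity is None
        assert any("positive" in f for f in qc.flags)


@pytest.fixture(scope="module")
def screen_scores():
    config = AnalysisConfig()
    dataset, _ = simulate_screen(
        SimulationConfig(plates=6, seed=21, baseline_cv=0.10,
                         inert_effect_log_sd=0.10)
    )
    return score_screen(dataset, config)


class TestScreenQC:
    def test_threshold_monotonicity(self, screen_scores):
        qc = screen_qc_summary(screen_scores, thresholds=[-0.5, -1.0])
        for plate in screen_scores.plates:
            loose = plate_sensitivity_specificity(plate, -0.5)
            tight = plate_sensitivity_specificity(plate, -1.0)
            assert tight.sensitivity <= loose.sensitivity
            assert tight.specificity >= loose.specificity
        summary = qc.summary.set_index("threshold")
        assert (
            summary.loc[-1.0, "sensitivity_mean"].mean()
            <= summary.loc[-0.5, "sensitivity_mean"].mean()
        )

    def test_summary_shape_mirrors_replicate_by_threshold(self, screen_scores):
        qc = screen_qc_summary(screen_scores, thresholds=[-0.5, -1.0])
        assert len(qc.summary) == 4  # 2 replicates x 2 thresholds
        assert set(qc.summary.columns) >= {
            "sensitivity_mean", "sensitivity_sd", "specificity_mean", "specificity_sd"
        }

    def test_single_plate_sd_is_zero(self, small_config):
        plate = make_plate([10, 12, 14, 16, 18], positive_readings=[6, 7],
                           negative_readings=[13, 15])
        scores = ssmd_star(plate, small_config)
        from platescreen.scoring import ScreenScores

        qc = screen_qc_summary(ScreenScores([scores], []), thresholds=[-0.5])
        assert (qc.summary["sensitivity_sd"] == 0.0).all()

    def test_null_effect_sensitivity_matches_negative_fp_rate(self):
        """With inert positive controls, 'sensitivity' is just the FP rate."""
        config = AnalysisConfig()
        dataset, _ = simulate_screen(
            SimulationConfig(plates=20, replicates=1, seed=5,
                             positive_control_effect=1.0,
                             background_exclusion_rate=0.0)
        )
        qc = screen_qc_summary(score_screen(dataset, config), thresholds=[-0.5])
        row = qc.summary.iloc[0]
        fp_rate = 100.0 - row["specificity_mean"]
        assert row["sensitivity_mean"] == pytest.approx(fp_rate, abs=10.0)


class TestControlVariability:
    def _dataset(self, plate_readings):
        wells = []
        for p, readings in enumerate(plate_readings):
            for i, value in enumerate(readings):
                wells.append(
                    WellRecord(
                        f"P{p}", WellAddress("A", i + 1), WellRole.NEGATIVE_CONTROL,
                        "DMSO", 0.0, status=WellStatus.OK, fluorescence=value,
                        replicate=1,
                    )
                )
        return ScreenDataset(wells)

    def test_identical_readings_give_zero_cv(self):
        report = control_variability(self._dataset([[100, 100], [100, 100]]))
        row = report[report.role == "negative_control"].iloc[0]
        assert row.within_plate_cv_mean == 0.0
        assert row.between_plate_cv == 0.0

    def test_between_plate_cv_arithmetic(self):
        # plate means 100 and 110: sample SD 7.071, mean 105 -> CV 6.734 %
        report = control_variability(self._dataset([[100, 100], [110, 110]]))
        row = report[report.role == "negative_control"].iloc[0]
        assert row.between_plate_cv == pytest.approx(6.7344, abs=1e-3)

    def test_day_effect_inflates_between_plate_cv(self):
        def between_cv(day_sd):
            dataset, _ = simulate_screen(
                SimulationConfig(plates=8, replicates=1, seed=9,
                                 plates_per_day=2, day_effect_log_sd=day_sd,
                                 plate_effect_log_sd=0.0)
            )
            report = control_variability(dataset)
            return report[(report.role == "negative_control")
                          & (report.day == "all")].iloc[0].between_plate_cv

        assert between_cv(0.3) > between_cv(0.0)

    def test_per_day_breakdown_present(self):
        dataset, _ = simulate_screen(
            SimulationConfig(plates=4, replicates=1, seed=2, plates_per_day=2)
        )
        report = control_variability(dataset)
        assert set(report.day) == {"all", "D1", "D2"}


class TestPassFail:
    def test_inactive_positive_controls_fail(self, small_config):
        plate = make_plate([10, 12, 14, 16, 18], positive_readings=[14, 15],
                           negative_readings=[13, 15])
        qc = plate_sensitivity_specificity(ssmd_star(plate, small_config), -0.5)
        ok, reasons = plate_pass_fail(qc, small_config)
        assert not ok
        assert any("no activity" in r for r in reasons)

    def test_healthy_plate_passes(self, small_config):
        plate = make_plate([10, 12, 14, 16, 18], positive_readings=[5, 6],
                           negative_readings=[13, 15])
        qc = plate_sensitivity_specificity(ssmd_star(plate, small_config), -0.5)
        ok, reasons = plate_pass_fail(qc, small_config)
        assert ok and reasons == []

    def test_degenerate_reference_fails(self, small_config):
        plate = make_plate([10, 12, 14, 16, 18], positive_readings=[5, 6],
                           negative_readings=[13, 15])
        qc = plate_sensitivity_specificity(ssmd_star(plate, small_config), -0.5)
        ok, reasons = plate_pass_fail(qc, small_config, degenerate_reference=True)
        assert not ok
        assert any("degenerate" in r for r in reasons)
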