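"""SSMD*/SSMD scoring against brute-force oracles and invariance properties."""

import math

import numpy as np
import pytest

from platescreen import (
    AnalysisConfig,
    ScoringError,
    WellRole,
    comparison_metrics,
    percent_reduction,
    simulate_control_groups,
    ssmd_controls,
    ssmd_star,
)
from tests.conftest import make_plate

SQRT2 = math.sqrt(2.0)


def brute_force_scores(test_readings, query, factor=SQRT2):
    """Independent sort-based median/MAD recomputation of the per-well score."""
    values = sorted(test_readings)
    n = len(values)

    def median(vs):
        vs = sorted(vs)
        m = len(vs)
        mid = m // 2
        return vs[mid] if m % 2 else 0.5 * (vs[mid - 1] + vs[mid])

    med = median(values)
    mad = median([abs(v - med) for v in values])
    scale = 1.4826 * mad
    return (query - med) / (factor * scale)


class TestSSMDStar:
    def test_median_well_scores_zero(self, small_config):
        plate = make_plate([10, 12, 14, 16, 18])
        scores = ssmd_star(plate, small_config)
        frame = scores.frame
        assert frame.loc[frame.fluorescence == 14, "ssmd_star"].iloc[0] == 0.0

    def test_worked_example_against_hand_arithmetic(self, small_config):
        # reference {10,12,14,16,18}: median 14, MAD 2, scale 2.9652
        # a control well at 8 scores (8-14)/(sqrt2*2.9652) = -1.4308
        plate = make_plate([10, 12, 14, 16, 18], positive_readings=[8])
        scores = ssmd_star(plate, small_config)
        assert scores.reference.location == 14
        assert scores.reference.scale == pytest.approx(2.9652)
        pos = scores.scores_for_role(WellRole.POSITIVE_CONTROL)
        assert pos[0] == pytest.approx(-6 / (SQRT2 * 2.9652), rel=1e-9)
        assert pos[0] == pytest.approx(-1.4308, abs=1e-4)

    def test_affine_invariance(self, small_config):
        rng = np.random.default_rng(0)
        readings = rng.lognormal(7, 0.2, 12).tolist()
        base = ssmd_star(make_plate(readings), small_config).frame["ssmd_star"]
        for a, b in [(3.0, 0.0), (2.0, 0.0), (0.5, 100.0), (7.3, 11.1)]:
            scaled = [a * x + b for x in readings]
            got = ssmd_star(make_plate(scaled), small_config).frame["ssmd_star"]
            np.testing.assert_allclose(got, base, rtol=1e-12)

    def test_monotone_in_reading(self, small_config):
        rng = np.random.default_rng(1)
        readings = sorted(rng.lognormal(7, 0.3, 15))
        frame = ssmd_star(make_plate(readings), small_config).frame
        ordered = frame.sort_values("fluorescence")["ssmd_star"].to_numpy()
        assert (np.diff(ordered) >= 0).all()
        below = frame.fluorescence < frame.fluorescence.median()
        assert (frame.loc[below, "ssmd_star"] < 0).all()

    def test_matches_brute_force_on_small_plates(self, small_config):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(5, 11))
            readings = rng.lognormal(7, 0.3, n).tolist()
            frame = ssmd_star(make_plate(readings), small_config).frame
            for row in frame.itertuples(index=False):
                expect = brute_force_scores(readings, row.fluorescence)
                assert row.ssmd_star == pytest.approx(expect, rel=1e-12)

    def test_degenerate_reference_raises(self, small_config):
        with pytest.raises(ScoringError, match="degenerate"):
            ssmd_star(make_plate([5, 5, 5, 5, 5]), small_config)

    def test_too_few_reference_wells_raises(self, config):
        with pytest.raises(ScoringError, match="minimum reference"):
            ssmd_star(make_plate([1, 2, 3]), config)

    def test_dead_wells_are_not_scored_and_not_reference(self, small_config):
        plate = make_plate([10, 12, 14, 16, 18, None])
        scores = ssmd_star(plate, small_config)
        assert scores.reference.n_reference == 5
        dead = scores.frame[scores.frame.status == "dead"]
        assert dead["ssmd_star"].isna().all()

    def test_leave_one_out_policy_excludes_self(self):
        cfg = AnalysisConfig(min_reference_size=4, reference_policy="test_loo")
        readings = [10.0, 12.0, 14.0, 16.0, 180.0]
        frame = ssmd_star(make_plate(readings), cfg).frame
        outlier = frame.loc[frame.fluorescence == 180.0, "ssmd_star"].iloc[0]
        # reference for the outlier is {10,12,14,16}: median 13, scale 2.9652
        assert outlier == pytest.approx((180 - 13) / (SQRT2 * 1.4826 * 2), rel=1e-12)

    def test_negative_controls_join_reference_only_on_request(self, small_config):
        cfg_neg = AnalysisConfig(min_reference_size=4,
                                 reference_policy="test_and_negative")
        plate = make_plate([10, 12, 14, 16, 18], negative_readings=[100, 110])
        default = ssmd_star(plate, small_config)
        widened = ssmd_star(plate, cfg_neg)
        assert default.reference.n_reference == 5
        assert widened.reference.n_reference == 7
        assert widened.reference.location != default.reference.location


class TestSSMDControls:
    def test_pairwise_difference_oracle(self):
        # positives {4,6}, negatives {10,12}: diffs {-6,-8,-4,-6},
        # median -6, sample SD sqrt(8/3)
        got = ssmd_controls([4, 6], [10, 12])
        diffs = [p - n for p in (4, 6) for n in (10, 12)]
        mean = sum(diffs) / 4
        sd = math.sqrt(sum((d - mean) ** 2 for d in diffs) / 3)
        assert got == pytest.approx(-6 / sd, rel=1e-12)
        assert got == pytest.approx(-3.674, abs=1e-3)

    def test_inhibitory_positives_score_negative(self):
        rng = np.random.default_rng(3)
        neg = rng.lognormal(7, 0.15, 12)
        pos = 0.5 * rng.lognormal(7, 0.15, 12)
        assert ssmd_controls(pos, neg) < 0

    def test_identical_groups_give_zero(self):
        vals = [3.0, 5.0, 9.0]
        assert ssmd_controls(vals, vals) == 0.0

    def test_constant_groups_raise(self):
        with pytest.raises(ScoringError, match="zero SD"):
            ssmd_controls([7, 7], [7, 7])


class TestPercentReduction:
    def test_forced_arithmetic(self):
        assert percent_reduction([50, 50], [100, 100]) == pytest.approx(50.0)
        assert percent_reduction([10.0], [10.0]) == 0.0
        assert percent_reduction([200.0], [100.0]) == -100.0  # activation

    def test_nonpositive_control_raises(self):
        with pytest.raises(ScoringError):
            percent_reduction([1.0], [0.0])

    def test_recovers_planted_halving(self):
        values = [
            percent_reduction(*simulate_control_groups(n=19, effect=0.5, cv=0.15,
                                                       seed=s))
            for s in range(20)
        ]
        assert np.mean(values) == pytest.approx(50.0, abs=5.0)


class TestComparisonMetrics:
    def test_degenerate_groups_flag_undefined(self):
        m = comparison_metrics([10, 10], [10, 10])
        assert m.signal_to_background == pytest.approx(1.0)
        assert m.signal_to_noise is None
        assert m.z_prime is None

    def test_z_prime_formula(self):
        # mean_pos 40 sd 2, neg mean 100 sd 3 -> Z' = 1 - 3*5/60 = 0.75
        pos = [38.0, 42.0]  # mean 40, sd(ddof=1) = 2.828 -> craft exact groups
        pos = [40 - 2 / math.sqrt(2), 40 + 2 / math.sqrt(2)]
        neg = [100 - 3 / math.sqrt(2), 100 + 3 / math.sqrt(2)]
        m = comparison_metrics(pos, neg)
        assert m.z_prime == pytest.approx(0.75, rel=1e-12)
        assert m.signal_to_background == pytest.approx(0.4, rel=1e-12)
        assert m.signal_to_noise == pytest.approx(-60 / 3, rel=1e-12)

    def test_z_prime_scale_invariant(self):
        rng = np.random.default_rng(5)
        pos, neg = rng.normal(40, 2, 10), rng.normal(100, 3, 10)
        z1 = comparison_metrics(pos, neg).z_prime
        z2 = comparison_metrics(5 * pos, 5 * neg).z_prime
        assert z2 == pytest.approx(z1, rel=1e-12)
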