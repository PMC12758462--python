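"""Classifier core: weights, REL, band scores, selection, severity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atlas_cpet import (
    INTERCENTILE_RANGES,
    CentileLabel,
    ClassifierConfig,
    IntercentileRange,
    RangeProbabilities,
    SeverityCategory,
    SymptomTrajectory,
    SyntheticSpec,
    classify,
    classify_peak,
    compute_weights,
    evaluate_centile,
    generate_trajectory,
    normalize,
    range_scores,
    rel,
    select_range,
    severity_from_range,
)

CFG = ClassifierConfig()


def _traj(work_rates, scores, symptom="dyspnea", sex="M", age=60.0):
    return SymptomTrajectory(symptom, sex, age, np.asarray(work_rates, float),
                             np.asarray(scores, float))


def _on_centile(cset, label, work_rates):
    scores = [evaluate_centile(cset, label, w) for w in work_rates]
    return _traj(work_rates, scores)


class TestWeights:
    def test_all_ones_when_no_inertial_points(self, hand_grid_set):
        traj = _traj([50, 100, 150], [2, 3, 4])
        assert np.allclose(compute_weights(traj, hand_grid_set, CFG), 1.0)

    def test_inertial_points_downweighted_then_rescaled(self, synthetic_set):
        # first two stages sit where P5 and P95 coincide at 0
        traj = _traj([5, 10, 150, 180], [0, 0, 4, 5])
        w = compute_weights(traj, synthetic_set, CFG)
        expected = np.array([0.25, 0.25, 1.0, 1.0]) * (4 / 2.5)
        assert np.allclose(w, expected)
        assert w.sum() == pytest.approx(4.0)

    def test_all_inertial_rescales_to_uniform(self, synthetic_set):
        traj = _traj([2, 5, 10], [0, 0, 0])
        assert np.allclose(compute_weights(traj, synthetic_set, CFG), 1.0)

    def test_symptom_mismatch_rejected(self, hand_grid_set):
        traj = _traj([50], [2], symptom="leg_effort")
        with pytest.raises(ValueError, match="symptom"):
            compute_weights(traj, hand_grid_set, CFG)


class TestRel:
    def test_exact_fit_scores_one(self, hand_grid_set):
        traj = _on_centile(hand_grid_set, CentileLabel.P50, [0, 50, 100, 150, 200])
        assert rel(traj, hand_grid_set, CentileLabel.P50, CFG) == 1.0

    def test_single_point_unit_deviation(self, hand_grid_set):
        # P50 at 100 W is 4.0; a score of 5.0 deviates by exactly 1
        traj = _traj([100], [5.0])
        assert rel(traj, hand_grid_set, CentileLabel.P50, CFG) == pytest.approx(
            math.exp(-1.0)
        )

    def test_two_point_mean_of_losses(self, hand_grid_set):
        # deviations 0 and ln 2 -> (1 + 1/2) / 2 = 0.75
        base = evaluate_centile(hand_grid_set, CentileLabel.P50, 150.0)
        traj = _traj([100, 150], [4.0, base + math.log(2.0)])
        assert rel(traj, hand_grid_set, CentileLabel.P50, CFG) == pytest.approx(0.75)

    def test_clamp_caps_outlier_influence(self, hand_grid_set):
        # MIN at 100 W is 1.0; a score of 10 deviates by 9, clamped to 5
        traj = _traj([100], [10.0])
        assert rel(traj, hand_grid_set, CentileLabel.MIN, CFG) == pytest.approx(
            math.exp(-CFG.clamp_dev)
        )

    def test_floor_applies_for_distant_trajectories(self, hand_grid_set):
        cfg = ClassifierConfig(alpha=5.0)
        traj = _traj([100], [10.0])
        assert rel(traj, hand_grid_set, CentileLabel.MIN, cfg) == cfg.min_loss

    def test_strictly_decreasing_in_deviation(self, hand_grid_set):
        rels = [
            rel(_traj([100], [4.0 + d]), hand_grid_set, CentileLabel.P50, CFG)
            for d in (0.0, 0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a > b for a, b in zip(rels, rels[1:]))
        assert rels[0] == 1.0

    @given(st.floats(0.1, 4.9), st.floats(0.25, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_calibration(self, dev, alpha):
        """REL is in [min_loss, 1], is 1 iff deviation is 0, and shrinks
        when every deviation grows by a constant below the clamp."""
        work_rates = np.array([0.0, 100.0, 200.0])
        values = np.tile(np.linspace(1, 7, 7), (3, 1)) + np.arange(3)[:, None]
        from atlas_cpet import CentileGrid, CentileSet

        cset = CentileSet("dyspnea", "M", (40, 80), CentileGrid(work_rates, values))
        cfg = ClassifierConfig(alpha=alpha)
        base = np.array(
            [evaluate_centile(cset, CentileLabel.P50, w) for w in work_rates]
        )
        r0 = rel(_traj(work_rates, base), cset, CentileLabel.P50, cfg)
        r1 = rel(
            _traj(work_rates, np.clip(base + dev, 0, 10)), cset, CentileLabel.P50, cfg
        )
        assert r0 == 1.0
        assert cfg.min_loss <= r1 < r0 <= 1.0


class TestRangeScores:
    def test_products_of_bordering_rels(self, hand_grid_set):
        traj = _traj([50, 100, 150], [2.5, 4.2, 4.4])
        scores, rels = range_scores(traj, hand_grid_set, CFG)
        for r in INTERCENTILE_RANGES:
            assert scores[r] == pytest.approx(rels[r.lower] * rels[r.upper])
            assert CFG.min_loss**2 <= scores[r] <= 1.0

    def test_on_p50_trajectory_adjacent_scores_dominate(self, hand_grid_set):
        traj = _on_centile(hand_grid_set, CentileLabel.P50, [0, 50, 100, 150, 200])
        scores, rels = range_scores(traj, hand_grid_set, CFG)
        assert rels[CentileLabel.P50] == 1.0
        ranked = sorted(scores, key=scores.get, reverse=True)
        assert {str(r) for r in ranked[:2]} == {"P25-P50", "P50-P75"}


class TestNormalize:
    def test_uniform_scores_give_uniform_probabilities(self):
        probs = normalize({r: 2.0 for r in INTERCENTILE_RANGES})
        assert np.allclose(probs.probabilities, 1 / 6)

    def test_proportionality(self):
        scores = {r: float(i + 1) for i, r in enumerate(INTERCENTILE_RANGES)}
        probs = normalize(scores)
        assert probs.probabilities[5] / probs.probabilities[0] == pytest.approx(6.0)

    @given(st.lists(st.floats(1e-8, 1.0), min_size=6, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_always_sums_to_one(self, raw):
        probs = normalize(dict(zip(INTERCENTILE_RANGES, raw)))
        assert abs(probs.probabilities.sum() - 1.0) < 1e-9


def _oracle_select(p, thresholds=(3, 4, 5), tie="higher"):
    """Independent recursive implementation of the threshold rule,
    working on band indices 0..5 (band i lies between labels i and i+1)."""

    def best_of(bands):
        top = bands[0]
        for b in bands[1:]:
            if p[b] > p[top] or (p[b] == p[top] and tie == "higher"):
                top = b
        return top

    def step(bands, ths):
        if not ths:
            return best_of(bands)
        t, rest = ths[0], ths[1:]
        below = [b for b in bands if b + 1 <= t]
        above = [b for b in bands if b >= t]
        if not below or not above:
            return step(bands, rest)
        mass_below = sum(p[b] for b in below)
        mass_above = sum(p[b] for b in above)
        if mass_above > mass_below or (mass_above == mass_below and tie == "higher"):
            return step(above, rest)
        return step(below, rest)

    return step(list(range(6)), list(thresholds))


class TestSelectRange:
    def test_all_mass_on_one_band(self):
        p = np.zeros(6)
        p[4] = 1.0
        assert str(select_range(RangeProbabilities(p), CFG)) == "P75-P95"

    def test_hand_walk_moderate_wins(self):
        # below P50: 0.30; P50-P75: 0.40; above P75: 0.30
        p = np.array([0.10, 0.10, 0.10, 0.40, 0.15, 0.15])
        assert str(select_range(RangeProbabilities(p), CFG)) == "P50-P75"

    def test_uniform_ties_go_higher(self):
        p = np.full(6, 1 / 6)
        assert str(select_range(RangeProbabilities(p), CFG)) == "P95-MAX"

    def test_uniform_ties_go_lower_with_lower_rule(self):
        cfg = ClassifierConfig(tie_rule="lower")
        p = np.full(6, 1 / 6)
        assert str(select_range(RangeProbabilities(p), cfg)) == "MIN-P5"

    @pytest.mark.parametrize("tie_rule", ["higher", "lower"])
    def test_agrees_with_recursive_oracle(self, tie_rule):
        rng = np.random.default_rng(2024)
        cfg = ClassifierConfig(tie_rule=tie_rule)
        for _ in range(1000):
            p = rng.dirichlet(np.full(6, rng.uniform(0.2, 3.0)))
            got = select_range(RangeProbabilities(p), cfg)
            want = _oracle_select(p, tie=tie_rule)
            assert got == INTERCENTILE_RANGES[want]


class TestSeverityMaps:
    @pytest.mark.parametrize(
        "range_str,expected",
        [
            ("MIN-P5", SeverityCategory.MILD),
            ("P5-P25", SeverityCategory.MILD),
            ("P25-P50", SeverityCategory.MILD),
            ("P50-P75", SeverityCategory.MODERATE),
            ("P75-P95", SeverityCategory.SEVERE),
            ("P95-MAX", SeverityCategory.VERY_SEVERE),
        ],
    )
    def test_range_to_severity(self, range_str, expected):
        assert severity_from_range(IntercentileRange.from_string(range_str)) == expected

    @pytest.mark.parametrize(
        "score,expected",
        [
            (0, SeverityCategory.MILD),
            (2, SeverityCategory.MILD),
            (2.5, SeverityCategory.MODERATE),
            (3, SeverityCategory.MODERATE),
            (4, SeverityCategory.MODERATE),
            (5, SeverityCategory.SEVERE),
            (6, SeverityCategory.SEVERE),
            (7, SeverityCategory.VERY_SEVERE),
            (10, SeverityCategory.VERY_SEVERE),
        ],
    )
    def test_peak_score_to_severity(self, score, expected):
        assert classify_peak(score) == expected

    def test_peak_score_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_peak(10.5)
        with pytest.raises(ValueError):
            classify_peak(-0.5)


class TestClassify:
    def test_trajectory_between_p50_and_p75_is_moderate(self, hand_grid_set):
        work_rates = [0, 50, 100, 150, 200]
        mid = [
            0.5
            * (
                evaluate_centile(hand_grid_set, CentileLabel.P50, w)
                + evaluate_centile(hand_grid_set, CentileLabel.P75, w)
            )
            for w in work_rates
        ]
        res = classify(_traj(work_rates, mid), hand_grid_set)
        assert res.severity == SeverityCategory.MODERATE
        assert str(res.selected_range) == "P50-P75"

    def test_trajectory_above_p95_is_very_severe(self, hand_grid_set):
        # strictly above P95 at every point, between P95 and MAX
        work_rates = [100, 150, 200]
        scores = [7.0, 8.2, 9.5]
        res = classify(_traj(work_rates, scores), hand_grid_set)
        assert res.severity == SeverityCategory.VERY_SEVERE

    def test_single_point_sets_few_points_flag(self, hand_grid_set):
        res = classify(_traj([100], [4.0]), hand_grid_set)
        assert "few_points" in res.flags
        # on P50 exactly: tie between the two adjacent strata, broken upward
        assert res.severity in (SeverityCategory.MILD, SeverityCategory.MODERATE)

    def test_on_centile_selection_is_adjacent(self, hand_grid_set):
        work_rates = [50, 100, 150]
        for lab in CentileLabel:
            res = classify(_on_centile(hand_grid_set, lab, work_rates), hand_grid_set)
            assert lab in (res.selected_range.lower, res.selected_range.upper)

    def test_metadata_mismatch_rejected(self, hand_grid_set):
        with pytest.raises(ValueError, match="sex"):
            classify(_traj([100], [4.0], sex="F"), hand_grid_set)
        with pytest.raises(ValueError, match="age"):
            classify(_traj([100], [4.0], age=30.0), hand_grid_set)

    def test_determinism(self, synthetic_set, default_spec):
        rng = np.random.default_rng(5)
        traj, _ = generate_trajectory(
            synthetic_set, INTERCENTILE_RANGES[3], default_spec, rng
        )
        res1 = classify(traj, synthetic_set)
        res2 = classify(traj, synthetic_set)
        assert res1 == res2
        assert np.array_equal(
            res1.range_probabilities.probabilities,
            res2.range_probabilities.probabilities,
        )

    def test_upward_shift_never_lowers_severity(self, synthetic_set):
        """Shifting every score upward (no clamping, all below the
        ceiling) can only keep or raise the severity category."""
        spec = SyntheticSpec(noise_sd=0.3)
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(100):
            target = INTERCENTILE_RANGES[int(rng.integers(6))]
            traj, _ = generate_trajectory(synthetic_set, target, spec, rng)
            for delta in (0.5, 1.0, 2.0):
                if traj.scores.max() + delta > 10:
                    continue
                shifted = SymptomTrajectory(
                    traj.symptom,
                    traj.subject_sex,
                    traj.subject_age,
                    traj.work_rates,
                    traj.scores + delta,
                )
                assert classify(shifted, synthetic_set).severity >= classify(
                    traj, synthetic_set
                ).severity
                checked += 1
        assert checked > 100

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            _traj([], [])
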