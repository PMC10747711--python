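import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phonealign.evaluation import (
    harmonic_mean,
    midpoint_evaluate,
    onset_evaluate,
    per_phone_error_rates,
    tolerance_table,
)
from phonealign.types import LabeledSegment

seg = LabeledSegment


def quadratic_oracle(truth, pred):
    """Independent nested-loop midpoint scoring (multi-match counting)."""
    hits = 0
    dt_start, dt_end = [], []
    for t in truth:
        mid = (t.start + t.end) / 2
        for p in pred:
            if p.start <= mid <= p.end and t.label == p.label:
                hits += 1
                dt_start.append(abs(t.start - p.start))
                dt_end.append(abs(t.end - p.end))
    return hits, dt_start, dt_end


def random_alignments(rng, n_labels=3):
    labels = [f"p{i}" for i in range(n_labels)]

    def one():
        cuts = np.sort(rng.uniform(0, 1, size=rng.integers(1, 8)))
        cuts = np.concatenate([[0.0], cuts, [1.0]])
        return [
            seg(labels[rng.integers(n_labels)], float(a), float(b))
            for a, b in zip(cuts, cuts[1:])
            if b - a > 1e-6
        ]

    return one(), one()


class TestHarmonicMean:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (0.7322, 0.6762, 0.7031),
            (0.1654, 0.6808, 0.2661),
            (0.5844, 0.6625, 0.6210),
        ],
    )
    def test_published_style_values(self, a, b, expected):
        assert round(harmonic_mean(a, b), 4) == expected

    def test_equal_arguments_identity(self):
        for x in (0.1, 0.5, 1.0):
            assert harmonic_mean(x, x) == pytest.approx(x)

    def test_zero_argument_gives_zero(self):
        assert harmonic_mean(0.0, 0.7) == 0.0
        assert harmonic_mean(0.7, 0.0) == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0.001, 1.0), st.floats(0.001, 1.0))
    def test_symmetric_and_between_min_and_max(self, a, b):
        hm = harmonic_mean(a, b)
        assert hm == pytest.approx(harmonic_mean(b, a))
        assert min(a, b) - 1e-12 <= hm <= max(a, b) + 1e-12


class TestMidpointEvaluate:
    def test_perfect_alignment(self):
        truth = [seg("aa", 0.0, 0.5), seg("iy", 0.5, 1.0)]
        report = midpoint_evaluate(truth, truth)
        assert report.hits == 2
        assert report.harmonic_mean == 1.0
        assert report.dt_start == (0.0, 0.0) and report.dt_end == (0.0, 0.0)

    def test_midpoint_membership(self):
        truth = [seg("aa", 0.1, 0.3)]  # midpoint 0.2
        assert midpoint_evaluate(truth, [seg("aa", 0.15, 0.35)]).hits == 1
        assert midpoint_evaluate(truth, [seg("aa", 0.25, 0.35)]).hits == 0

    def test_label_mismatch_is_no_hit(self):
        report = midpoint_evaluate([seg("aa", 0.0, 1.0)], [seg("iy", 0.0, 1.0)])
        assert report.hits == 0
        assert report.harmonic_mean == 0.0
        assert report.match_fraction == 1.0  # matched ignoring labels

    def test_multi_match_counted_without_deduplication(self):
        # both predictions contain the truth midpoint with the right label
        truth = [seg("aa", 0.0, 1.0)]
        pred = [seg("aa", 0.0, 0.6), seg("aa", 0.4, 1.0)]
        report = midpoint_evaluate(truth, pred)
        assert report.hits == 2
        assert report.recall_like == 2.0

    def test_unique_matching_variant_caps_hits(self):
        truth = [seg("aa", 0.0, 1.0)]
        pred = [seg("aa", 0.0, 0.6), seg("aa", 0.4, 1.0)]
        report = midpoint_evaluate(truth, pred, unique_matching=True)
        assert report.hits == 1

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            midpoint_evaluate([], [seg("aa", 0.0, 1.0)])
        with pytest.raises(ValueError):
            midpoint_evaluate([seg("aa", 0.0, 1.0)], [])

    def test_matches_quadratic_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            truth, pred = random_alignments(rng)
            report = midpoint_evaluate(truth, pred)
            hits, dt_start, dt_end = quadratic_oracle(truth, pred)
            assert report.hits == hits
            assert list(report.dt_start) == pytest.approx(dt_start)
            assert list(report.dt_end) == pytest.approx(dt_end)
            assert report.recall_like == pytest.approx(hits / len(truth))
            assert report.precision_like == pytest.approx(hits / len(pred))


class TestOnsetEvaluate:
    def test_within_tolerance_and_label_correct(self):
        truth = [seg("t", 0.2, 0.4)]
        p, r, f1 = onset_evaluate(truth, [seg("t", 0.215, 0.4)], 0.02)
        assert (p, r, f1) == (1.0, 1.0, 1.0)

    def test_outside_tolerance_no_match(self):
        truth = [seg("t", 0.2, 0.4)]
        p, r, f1 = onset_evaluate(truth, [seg("t", 0.225, 0.4)], 0.02)
        assert (p, r, f1) == (0.0, 0.0, 0.0)

    def test_match_with_wrong_label_not_correct(self):
        truth = [seg("t", 0.2, 0.4)]
        p, r, _ = onset_evaluate(truth, [seg("d", 0.2, 0.4)], 0.02)
        assert (p, r) == (0.0, 0.0)

    def test_identical_alignments_perfect(self):
        truth = [seg("t", 0.0, 0.2), seg("aa", 0.2, 0.5), seg("n", 0.5, 1.0)]
        assert onset_evaluate(truth, truth) == (1.0, 1.0, 1.0)

    def test_greedy_matching_is_one_to_one(self):
        # one truth onset, two predictions within tolerance: only one match
        truth = [seg("t", 0.2, 0.4), seg("t", 0.4, 0.6)]
        pred = [seg("t", 0.205, 0.4), seg("t", 0.21, 0.6)]
        p, r, _ = onset_evaluate(truth, pred, 0.02)
        assert p == 0.5 and r == 0.5  # 0.205 pairs with 0.2; 0.21 has no partner


class TestToleranceTable:
    def test_counting(self):
        report = midpoint_evaluate(
            [seg("a", 0.0, 1.0)], [seg("a", 0.005, 1.03)]
        )
        table = tolerance_table(report, [0.02, 0.04, 0.06])
        assert table.fractions_start == (1.0, 1.0, 1.0)
        assert table.fractions_end == (0.0, 1.0, 1.0)

    def test_strictly_below_semantics(self):
        report = midpoint_evaluate([seg("a", 0.0, 1.0)], [seg("a", 0.02, 1.0)])
        table = tolerance_table(report, [0.02, 0.04])
        assert table.fractions_start == (0.0, 1.0)  # 0.02 is not < 0.02

    def test_all_zero_deltas(self):
        truth = [seg("a", 0.0, 1.0)]
        table = tolerance_table(midpoint_evaluate(truth, truth))
        assert table.fractions_start == (1.0, 1.0, 1.0)

    def test_no_hits_rejected(self):
        report = midpoint_evaluate([seg("a", 0.0, 1.0)], [seg("b", 0.0, 1.0)])
        with pytest.raises(ValueError):
            tolerance_table(report)

    def test_fractions_monotone_for_random_deltas(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            truth, pred = random_alignments(rng)
            try:
                report = midpoint_evaluate(truth, pred)
                table = tolerance_table(report, [0.01, 0.02, 0.05, 0.1, 0.5])
            except ValueError:
                continue
            assert all(
                a <= b for a, b in zip(table.fractions_start, table.fractions_start[1:])
            )
            assert all(
                a <= b for a, b in zip(table.fractions_end, table.fractions_end[1:])
            )
            # cross-check one threshold against a sorting oracle
            sorted_d = sorted(report.dt_start)
            k = sum(1 for d in sorted_d if d < 0.05)
            assert table.fractions_start[2] == k / len(sorted_d)


class TestPerPhoneErrorRates:
    def test_perfect_alignment_zero_errors(self):
        truth = [seg("aa", 0.0, 0.5), seg("t", 0.5, 1.0)]
        assert per_phone_error_rates(truth, truth) == {"aa": 0.0, "t": 0.0}

    def test_never_matched_phone_rate_one(self):
        truth = [seg("zh", 0.0, 1.0)]
        assert per_phone_error_rates(truth, [seg("s", 0.0, 1.0)]) == {"zh": 1.0}

    def test_partial_counting(self):
        truth = [seg("t", 0.0, 0.2), seg("t", 0.2, 0.4), seg("t", 0.4, 0.6), seg("t", 0.6, 0.8)]
        pred = [seg("t", 0.0, 0.2), seg("t", 0.2, 0.4), seg("x", 0.4, 0.8)]
        assert per_phone_error_rates(truth, pred) == {"t": 0.5}
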