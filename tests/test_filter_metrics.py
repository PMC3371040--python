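"""Truth-set metrics, the QUAL x DP grid search, and call-set concordance.

Expected metric values for the printed confusion rows were verified by
hand arithmetic (e.g. 50/65 = 0.7692, 2*50/(2*50+9+15) = 0.8065) and the
grid search is checked against independently coded brute-force loops.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from postvar.filter_metrics import (
    ConfusionCounts,
    CutoffCombo,
    DegenerateGridError,
    apply_filter,
    compute_metrics,
    confusion_counts,
    format_pct,
    grid_search,
    qual_concordance,
    validation_rate,
)
from postvar.variant_io import TruthEntry, VariantRecord


def _rec(pos, qual, dp, sample="S1", dp4=None):
    return VariantRecord(
        chrom="chr1", pos=pos, ref="A", alt="G", qual=qual, dp=dp, dp4=dp4, sample_id=sample
    )


def _truth(pos, status, sample="S1"):
    return TruthEntry(chrom="chr1", pos=pos, ref="A", alt="G", sample_id=sample, status=status)


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "counts,recall,accuracy,f",
        [
            ((50, 9, 85, 15), 0.7692, 0.8475, 0.8065),  # tier-one SNVs at QUAL>=28, DP>=5
            ((65, 80, 14, 0), 1.0, 0.4483, None),       # tier-two SNVs unfiltered
            ((59, 10, 70, 6), 0.9077, 0.8551, None),    # tier-two SNVs at best cutoffs
            ((12, 1, 9, 0), 1.0, 0.9231, None),         # tier-one indels at QUAL>=17, DP>=3
            ((9, 10, 0, 3), 0.75, 0.4737, None),        # tier-two indels unfiltered
            ((9, 0, 10, 3), 0.75, 1.0, None),           # tier-two indels at QUAL>=21, DP>=3
        ],
    )
    def test_validated_callset_rows(self, counts, recall, accuracy, f):
        m = compute_metrics(ConfusionCounts(*counts))
        assert m.recall == pytest.approx(recall, abs=5e-5)
        assert m.accuracy == pytest.approx(accuracy, abs=5e-5)
        if f is not None:
            assert m.f_score == pytest.approx(f, abs=5e-5)

    def test_zero_denominators_are_undefined_not_zero(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert m.recall is None and m.accuracy is None and m.f_score is None
        assert m.validate_rate == 0.0

    @given(
        tp=st.integers(0, 200), fp=st.integers(0, 200),
        tn=st.integers(0, 200), fn=st.integers(0, 200),
    )
    @settings(max_examples=200, derandomize=True)
    def test_f_is_harmonic_mean_identity(self, tp, fp, tn, fn):
        m = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
        if m.recall is not None and m.accuracy is not None and (m.recall + m.accuracy) > 0:
            harmonic = 2 * m.accuracy * m.recall / (m.accuracy + m.recall)
            assert m.f_score == pytest.approx(harmonic, abs=1e-12)
            assert min(m.recall, m.accuracy) - 1e-12 <= m.f_score <= max(m.recall, m.accuracy) + 1e-12

    def test_percent_rendering_is_half_up_two_decimals(self):
        assert format_pct(50 / 65) == "76.92%"
        assert format_pct(50 / 59) == "84.75%"
        assert format_pct(65 / 159) == "40.88%"
        assert format_pct(None) == "NA"


class TestValidationRate:
    @pytest.mark.parametrize(
        "v,n,expected", [(65, 159, 0.4088), (12, 22, 0.5455), (0, 10, 0.0)]
    )
    def test_rates(self, v, n, expected):
        assert validation_rate(v, n) == pytest.approx(expected, abs=5e-5)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            validation_rate(0, 0)


class TestConfusionCounts:
    def test_hand_enumeration(self):
        calls = [_rec(1, 30, 6), _rec(2, 10, 6), _rec(3, 30, 6), _rec(4, 10, 2)]
        truth = [_truth(1, "validated"), _truth(2, "validated"),
                 _truth(3, "failed"), _truth(4, "failed")]
        c = confusion_counts(calls, truth, CutoffCombo(28, 5))
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 1)

    def test_loosest_cutoff_predicts_everything(self):
        calls = [_rec(i, 5, 3) for i in range(1, 7)]
        truth = [_truth(i, "validated" if i <= 2 else "failed") for i in range(1, 7)]
        c = confusion_counts(calls, truth, CutoffCombo(0, 0))
        assert c.fn == 0 and c.fp == 4 and c.tp == 2

    def test_absent_calls_are_fn_or_tn(self):
        truth = [_truth(1, "validated"), _truth(2, "failed")]
        c = confusion_counts([], truth, CutoffCombo(0, 0))
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 0, 1, 1)

    def test_matches_brute_force_reclassification(self, tier1_like_set):
        calls, truth = tier1_like_set
        cutoff = CutoffCombo(28, 5)
        c = confusion_counts(calls, truth, cutoff)
        # independent per-variant loop
        by_key = {r.key: r for r in calls}
        tp = fp = tn = fn = 0
        for t in truth:
            r = by_key.get(t.key)
            pred = r is not None and r.qual >= 28 and r.dp is not None and r.dp >= 5
            if t.status == "validated":
                tp, fn = tp + pred, fn + (not pred)
            else:
                fp, tn = fp + pred, tn + (not pred)
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)

    def test_conservation_and_monotonicity(self, tier1_like_set):
        calls, truth = tier1_like_set
        prev_by_dp = {}
        for q in range(15, 36, 4):
            prev = None
            for d in range(3, 16, 3):
                c = confusion_counts(calls, truth, CutoffCombo(q, d))
                assert c.total == len(truth)
                if prev is not None:  # raising dp_min shrinks the predicted set
                    assert c.tp <= prev.tp and c.fp <= prev.fp
                if d in prev_by_dp:  # raising qual_min shrinks it too
                    assert c.tp <= prev_by_dp[d].tp and c.fp <= prev_by_dp[d].fp
                prev = c
                prev_by_dp[d] = c

    def test_validate_rate_invariant_to_cutoff(self, tier1_like_set):
        calls, truth = tier1_like_set
        rates = {
            compute_metrics(confusion_counts(calls, truth, CutoffCombo(q, d))).validate_rate
            for q, d in [(15, 3), (28, 5), (35, 15)]
        }
        assert rates == {65 / 159}


class TestGridSearch:
    def test_perfect_separation_limit(self):
        calls = [_rec(i, 50, 20) for i in range(1, 6)]
        truth = [_truth(i, "validated") for i in range(1, 6)]
        result = grid_search(calls, truth)
        assert result.best_f_score == 1.0
        assert CutoffCombo(15, 3) in result.best_combos  # loosest combo keeps all

    def test_planted_separation_recovery(self, planted_set):
        calls, truth = planted_set
        result = grid_search(calls, truth)
        assert result.best_f_score == 1.0
        window = {
            c for c in result.best_combos if 25 < c.qual_min <= 30 and 4 < c.dp_min <= 6
        }
        assert window, "no perfect combo inside the planted cutoff window"

    def test_matches_independent_double_loop(self, tier1_like_set):
        calls, truth = tier1_like_set
        result = grid_search(calls, truth)
        # brute-force re-evaluation with separately written code
        by_key = {r.key: r for r in calls}
        best = -1.0
        for q in range(15, 36):
            for d in range(3, 16):
                tp = fp = fn = 0
                for t in truth:
                    r = by_key.get(t.key)
                    pred = r is not None and r.qual >= q and r.dp is not None and r.dp >= d
                    if t.status == "validated" and pred:
                        tp += 1
                    elif t.status == "validated":
                        fn += 1
                    elif pred:
                        fp += 1
                if 2 * tp + fp + fn > 0:
                    best = max(best, 2 * tp / (2 * tp + fp + fn))
        assert result.best_f_score == pytest.approx(best, abs=1e-12)
        assert len(result.rows) == 21 * 13

    def test_degenerate_grid_errors(self):
        truth = [_truth(i, "failed") for i in range(1, 4)]
        with pytest.raises(DegenerateGridError):
            grid_search([], truth)


class TestApplyFilter:
    def test_depth_bounds(self):
        calls = [_rec(1, 50, 2), _rec(2, 50, 3), _rec(3, 50, 10_000), _rec(4, 50, 10_001)]
        kept = apply_filter(calls, qual_min=0, dp_min=3, dp_max=10_000)
        assert [r.pos for r in kept] == [2, 3]

    def test_identity_filter(self, tier1_like_set):
        calls, _ = tier1_like_set
        assert apply_filter(calls, qual_min=0, dp_min=0, dp_max=float("inf")) == list(calls)

    def test_matches_per_record_predicate(self, tier1_like_set):
        calls, _ = tier1_like_set
        kept = apply_filter(calls, qual_min=28, dp_min=5, dp_max=10_000)
        expected = [r for r in calls if r.qual >= 28 and r.dp is not None and 5 <= r.dp <= 10_000]
        assert kept == expected

    def test_missing_dp_removed_when_bounds_active(self):
        rec = _rec(1, 50, None)
        assert apply_filter([rec], dp_min=3, dp_max=100) == []

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            apply_filter([], dp_min=10, dp_max=5)


class TestQualConcordance:
    def test_identical_sets(self, tier1_like_set):
        calls, _ = tier1_like_set
        r, frac, n = qual_concordance(calls, calls)
        assert r == pytest.approx(1.0)
        assert frac == 0.0
        assert n == len(calls)

    def test_affine_shift(self, tier1_like_set):
        calls, _ = tier1_like_set
        shifted = [
            VariantRecord(
                chrom=c.chrom, pos=c.pos, ref=c.ref, alt=c.alt,
                qual=c.qual + 1, dp=c.dp, dp4=c.dp4, sample_id=c.sample_id,
            )
            for c in calls
        ]
        r, frac, _ = qual_concordance(calls, shifted)
        assert r == pytest.approx(1.0)
        assert frac == 0.0  # set_a is uniformly lower
        r2, frac2, _ = qual_concordance(shifted, calls)
        assert frac2 == 1.0 and r2 == pytest.approx(1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(1)
        qa = rng.uniform(10, 60, size=100)
        qb = qa + rng.normal(0, 3, size=100)
        set_a = [_rec(i + 1, round(q, 2), 10) for i, q in enumerate(qa)]
        set_b = [_rec(i + 1, round(max(q, 0), 2), 10) for i, q in enumerate(qb)]
        r, frac, n = qual_concordance(set_a, set_b)
        xa = np.array([x.qual for x in set_a])
        xb = np.array([x.qual for x in set_b])
        expected = np.mean((xa - xa.mean()) * (xb - xb.mean())) / (xa.std() * xb.std())
        assert r == pytest.approx(expected, abs=1e-12)
        assert frac == np.mean(xa > xb)
        assert n == 100

    def test_too_few_pairs_or_zero_variance(self):
        with pytest.raises(ValueError):
            qual_concordance([_rec(1, 10, 5)], [_rec(1, 10, 5)])
        flat = [_rec(i, 10, 5) for i in range(1, 5)]
        with pytest.raises(ValueError):
            qual_concordance(flat, flat)
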