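import numpy as np
import pytest

from camtriage import (
    ClassificationMatrix,
    auc,
    classify,
    confusion,
    rates,
    roc_curve,
    threshold_for_fp,
    time_savings,
)
from camtriage.synthetic import (
    DRY_POPULATION,
    WET_POPULATION,
    PopulationConfig,
    generate_population,
)

from conftest import make_recordings
from oracles import naive_rates_at_threshold


class TestClassify:
    def test_below_threshold_is_discarded(self):
        assert classify(0.5, 1.0) == "discard"

    def test_tie_is_kept_for_inspection(self):
        assert classify(1.0, 1.0) == "keep"
        assert classify(0.0, 0.0) == "keep"


class TestConfusion:
    def test_enumerated_example(self):
        recs = make_recordings(target_d=[0.8, 2.0], nontarget_d=[0.1, 0.9])
        m = confusion(recs, 0.85, "filter1")
        assert (m.tp, m.fn, m.fp, m.tn) == (1, 1, 1, 1)

    def test_zero_threshold_discards_nothing(self):
        recs = make_recordings(target_d=[0.0, 1.0], nontarget_d=[0.0, 2.0])
        m = confusion(recs, 0.0, "filter1")
        assert m.tp == 0 and m.fp == 0
        assert m.fn == 2 and m.tn == 2

    def test_infinite_threshold_discards_everything(self):
        recs = make_recordings(target_d=[1.0], nontarget_d=[2.0, 3.0])
        m = confusion(recs, np.inf, "filter1")
        assert m.fn == 0 and m.tn == 0
        assert m.tp == 2 and m.fp == 1

    def test_missing_method_names_recording(self):
        recs = make_recordings(target_d=[1.0], nontarget_d=[2.0])
        with pytest.raises(KeyError, match="t0"):
            confusion(recs, 1.0, "filter2")

    def test_marginals_invariant_over_thresholds(self, rng):
        recs = make_recordings(target_d=rng.random(30), nontarget_d=rng.random(20))
        for thr in [0.0, 0.3, 0.7, 2.0]:
            m = confusion(recs, thr, "filter1")
            assert m.n_nontarget == 20 and m.n_target == 30


class TestRates:
    def test_arithmetic(self):
        tp_rate, fp_rate = rates(ClassificationMatrix(tp=1, fn=1, fp=1, tn=2))
        assert tp_rate == pytest.approx(0.5)
        assert fp_rate == pytest.approx(1 / 3)

    def test_perfect_classifier(self):
        assert rates(ClassificationMatrix(tp=5, fn=0, fp=0, tn=7)) == (1.0, 0.0)

    def test_empty_class_is_an_error(self):
        with pytest.raises(ValueError):
            rates(ClassificationMatrix(tp=0, fn=0, fp=1, tn=1))


class TestRocCurve:
    def test_enumerated_example(self):
        recs = make_recordings(target_d=[1.0, 2.0, 3.0], nontarget_d=[0.5, 1.5])
        curve = roc_curve(recs, "filter1")
        # the candidate threshold in the interval containing 1.2 is 1.25
        i = int(np.searchsorted(curve.thresholds, 1.2))
        assert curve.tp_rates[i] == pytest.approx(0.5)
        assert curve.fp_rates[i] == pytest.approx(1 / 3)

    def test_monotone_with_sentinel_endpoints(self, rng):
        recs = make_recordings(
            target_d=rng.lognormal(1, 0.5, 40), nontarget_d=rng.lognormal(0, 0.5, 30)
        )
        curve = roc_curve(recs, "filter1")
        assert np.all(np.diff(curve.tp_rates) >= 0)
        assert np.all(np.diff(curve.fp_rates) >= 0)
        assert (curve.fp_rates[0], curve.tp_rates[0]) == (0.0, 0.0)
        assert (curve.fp_rates[-1], curve.tp_rates[-1]) == (1.0, 1.0)

    def test_agrees_with_exhaustive_sweep(self, rng):
        d_t = rng.lognormal(1, 0.6, 120)
        d_n = rng.lognormal(0, 0.6, 80)
        recs = make_recordings(target_d=d_t, nontarget_d=d_n)
        curve = roc_curve(recs, "filter1")
        d_all = [r.d("filter1") for r in recs]
        labels = [r.label for r in recs]
        for thr, fp_r, tp_r in curve.points:
            want_tp, want_fp = naive_rates_at_threshold(d_all, labels, thr)
            assert tp_r == pytest.approx(want_tp)
            assert fp_r == pytest.approx(want_fp)

    def test_separable_data_passes_through_perfect_corner(self):
        recs = make_recordings(target_d=[5.0, 6.0], nontarget_d=[1.0, 2.0])
        curve = roc_curve(recs, "filter1")
        perfect = (np.isclose(curve.fp_rates, 0) & np.isclose(curve.tp_rates, 1))
        assert perfect.any()

    def test_single_class_rejected(self):
        recs = make_recordings(target_d=[1.0, 2.0], nontarget_d=[])
        with pytest.raises(ValueError):
            roc_curve(recs, "filter1")

    def test_null_labels_give_half_auc(self):
        cfg = PopulationConfig(
            n_target=500, n_nontarget=500,
            target_log_mean=0.0, target_log_sd=0.6,
            nontarget_log_mean=0.0, nontarget_log_sd=0.6, seed=99,
        )
        curve = roc_curve(generate_population(cfg), "filter1")
        assert auc(curve) == pytest.approx(0.5, abs=0.05)

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        d_t = rng.lognormal(1, 0.6, 100)
        d_n = rng.lognormal(0, 0.6, 90)
        recs = make_recordings(target_d=d_t, nontarget_d=d_n)
        ours = auc(roc_curve(recs, "filter1"))
        # positive class = non-target, discarded when D is LOW -> score is -D
        y = [0] * len(d_t) + [1] * len(d_n)
        ref = roc_auc_score(y, np.concatenate([-d_t, -d_n]))
        assert ours == pytest.approx(ref, abs=1e-12)


class TestThresholdForFP:
    def test_order_statistic_bound(self, rng):
        recs = make_recordings(
            target_d=np.arange(1.0, 101.0), nontarget_d=rng.uniform(0, 100, 50)
        )
        op = threshold_for_fp(recs, "filter1", 0.05)
        n_targets_below = int(np.sum(np.arange(1.0, 101.0) < op.threshold))
        assert n_targets_below <= 5
        assert op.achieved_fp_rate <= 0.05

    def test_maximality_no_larger_candidate_fits(self, rng):
        recs = make_recordings(
            target_d=rng.lognormal(1, 0.6, 60), nontarget_d=rng.lognormal(0, 0.6, 40)
        )
        tol = 0.10
        op = threshold_for_fp(recs, "filter1", tol)
        curve = roc_curve(recs, "filter1")
        larger = curve.thresholds > op.threshold
        assert np.all(curve.fp_rates[larger] > tol)
        assert op.achieved_fp_rate <= tol

    def test_high_tolerance_sits_above_nearly_all(self):
        recs = make_recordings(
            target_d=np.arange(1.0, 11.0), nontarget_d=[0.5, 5.5]
        )
        op = threshold_for_fp(recs, "filter1", 0.95)
        assert op.achieved_fp_rate == pytest.approx(0.9)
        assert op.threshold > 9.0

    def test_separable_data_reaches_perfect_point(self):
        recs = make_recordings(target_d=[5.0, 6.0, 7.0], nontarget_d=[1.0, 2.0])
        op = threshold_for_fp(recs, "filter1", 0.01)
        assert op.achieved_fp_rate == 0.0
        assert op.achieved_tp_rate == 1.0
        assert op.discarded_count == 2

    def test_impossible_tolerance_returns_trivial_point(self):
        # the smallest D belongs to a target, so any discarding loses footage
        recs = make_recordings(target_d=[0.1, 0.2, 0.3], nontarget_d=[1.0, 2.0])
        op = threshold_for_fp(recs, "filter1", 0.0)
        assert (op.achieved_fp_rate, op.achieved_tp_rate) == (0.0, 0.0)
        assert op.discarded_count == 0
        assert op.time_savings_min == 0.0

    def test_time_savings_counts_all_discards(self):
        recs = make_recordings(target_d=[0.5, 9.5], nontarget_d=[0.1, 0.2, 9.0])
        op = threshold_for_fp(recs, "filter1", 0.6)
        # 4 of 5 recordings fall below the chosen threshold (one of them a
        # wrongly discarded target), 15 s each — all of them skip inspection
        assert op.discarded_count == 4
        assert op.achieved_fp_rate == pytest.approx(0.5)
        assert op.time_savings_min == pytest.approx(4 * 15 / 60)


class TestTimeSavings:
    def test_every_discard_skips_inspection(self):
        m = ClassificationMatrix(tp=398, fp=52, fn=550, tn=991)
        assert time_savings(m, 15.0) == pytest.approx(450 * 15 / 60)

    def test_no_discards_no_savings(self):
        assert time_savings(ClassificationMatrix(tp=0, fp=0, fn=3, tn=4)) == 0.0


def test_dry_condition_separates_better_than_wet():
    """At any fixed FP tolerance the dry preset discards more non-target
    footage than the wet preset: dynamic water raises the empty-scene D."""
    dry = generate_population(PopulationConfig(
        n_target=DRY_POPULATION.n_target, n_nontarget=DRY_POPULATION.n_nontarget,
        nontarget_log_mean=DRY_POPULATION.nontarget_log_mean,
        nontarget_log_sd=DRY_POPULATION.nontarget_log_sd, condition="dry", seed=5,
    ))
    wet = generate_population(PopulationConfig(
        n_target=WET_POPULATION.n_target, n_nontarget=WET_POPULATION.n_nontarget,
        nontarget_log_mean=WET_POPULATION.nontarget_log_mean,
        nontarget_log_sd=WET_POPULATION.nontarget_log_sd, condition="wet", seed=5,
    ))
    for tol in (0.05, 0.20):
        tp_dry = threshold_for_fp(dry, "filter1", tol).achieved_tp_rate
        tp_wet = threshold_for_fp(wet, "filter1", tol).achieved_tp_rate
        assert tp_dry > tp_wet
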