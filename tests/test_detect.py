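"""Detection statistics: ROI series, permutation tests, peaks, effect sizes,
Bayes factors, presence decisions."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mmntrack import (
    ComponentWindow,
    DecisionRules,
    EpochsSet,
    NoiseModel,
    average_by_condition,
    bayes_series,
    bf10_from_t,
    build_templates,
    classify_evidence,
    cohens_d_window,
    decide_presence,
    difference_series,
    effect_size,
    find_peak,
    log_bf10_from_t,
    mmn_window,
    p3a_window,
    perm_ttest_serial,
    roi_mean,
)
from mmntrack.containers import RoiSeries
from mmntrack.errors import ConfigurationError, MissingChannelError


def _series(values, t0=-100.0, sfreq=512.0):
    values = np.asarray(values, dtype=float)
    t = t0 + np.arange(values.shape[-1]) * 1000.0 / sfreq
    return RoiSeries(values=values, time_ms=t, source="evoked-difference")


class TestRoiMean:
    def test_identical_channels_pass_through(self):
        t = np.linspace(-100, 599, 359)
        wave = np.sin(t / 50.0)
        data = np.broadcast_to(wave, (6, 359))
        ep = EpochsSet(
            data=data[None],
            channel_names=["F3", "Fz", "F4", "C3", "Cz", "C4"],
            sampling_rate_hz=512.0,
            time_ms=-100.0 + np.arange(359) * 1000.0 / 512.0,
            condition=np.array(["standard"]),
            block_id=np.array([1], dtype=object),
        )
        out = roi_mean(ep)
        assert np.allclose(out.values[0], wave)

    def test_mean_cancels_opposite_channels(self):
        data = np.zeros((1, 6, 10))
        data[0, 0] = 3.0
        data[0, 1] = -3.0
        ep = EpochsSet(
            data=data,
            channel_names=["F3", "Fz", "F4", "C3", "Cz", "C4"],
            sampling_rate_hz=512.0,
            time_ms=-100.0 + np.arange(10) * 1000.0 / 512.0,
            condition=np.array(["standard"]),
            block_id=np.array([1], dtype=object),
        )
        assert np.allclose(roi_mean(ep).values, 0.0)

    def test_montage_invariance(self, rng):
        """An 11-electrode patient montage gives the same ROI series as a
        larger montage restricted to the same six channels."""
        roi = ["F3", "Fz", "F4", "C3", "Cz", "C4"]
        full_names = roi + ["P3", "Pz", "P4", "T7", "T8"]
        data11 = rng.normal(size=(4, 11, 50))
        t = -100.0 + np.arange(50) * 1000.0 / 512.0
        ep11 = EpochsSet(
            data=data11, channel_names=full_names, sampling_rate_hz=512.0,
            time_ms=t, condition=np.array(["standard"] * 4),
            block_id=np.ones(4, dtype=object),
        )
        ep6 = EpochsSet(
            data=data11[:, :6], channel_names=roi, sampling_rate_hz=512.0,
            time_ms=t, condition=np.array(["standard"] * 4),
            block_id=np.ones(4, dtype=object),
        )
        assert np.allclose(roi_mean(ep11, roi).values, roi_mean(ep6, roi).values)

    def test_missing_channel_error_lists_available(self):
        ep = EpochsSet(
            data=np.zeros((1, 2, 5)), channel_names=["Cz", "Fz"],
            sampling_rate_hz=512.0,
            time_ms=-100.0 + np.arange(5) * 1000.0 / 512.0,
            condition=np.array(["standard"]),
            block_id=np.array([1], dtype=object),
        )
        with pytest.raises(MissingChannelError, match="Cz"):
            roi_mean(ep, ["F3"])


class TestPermutation:
    def test_identical_sets_not_significant(self, rng):
        a = rng.normal(size=(8, 60))
        res = perm_ttest_serial(a, a.copy(), "paired", seed=0)
        assert not res.significant.any()
        assert res.significant_intervals == []

    def test_pvalue_floor_and_dominance(self, rng):
        a = rng.normal(-1.0, 1.0, size=(10, 80))
        b = rng.normal(0.0, 1.0, size=(10, 80))
        res = perm_ttest_serial(a, b, "paired", tail="negative", seed=1)
        assert (res.p_corr >= 1.0 / (res.n_permutations + 1) - 1e-12).all()
        assert (res.p_corr >= res.p_uncorr - 1e-12).all()
        assert ((res.p_corr >= 0) & (res.p_corr <= 1)).all()

    def test_seed_reproducibility(self, rng):
        a = rng.normal(size=(6, 40))
        b = rng.normal(size=(6, 40))
        r1 = perm_ttest_serial(a, b, "paired", seed=42)
        r2 = perm_ttest_serial(a, b, "paired", seed=42)
        assert np.array_equal(r1.p_corr, r2.p_corr)

    def test_exhaustive_equivalence_paired(self, rng):
        """Random sign-flip p-values converge to the 2^n enumeration."""
        diffs = rng.normal(-0.7, 1.0, size=(7, 50))
        zeros = np.zeros_like(diffs)
        ex = perm_ttest_serial(diffs, zeros, "paired", exhaustive=True)
        rd = perm_ttest_serial(
            diffs, zeros, "paired", n_permutations=4000, seed=5
        )
        p = ex.p_corr
        err = np.maximum(np.abs(rd.p_corr - p) - 1.0 / 4001, 0.0)
        se = np.sqrt(np.maximum(p * (1 - p), 1e-12) / 4000)
        assert err.mean() <= 2 * se.mean()
        assert (err <= 3.9 * np.maximum(se, 1e-9)).all()

    def test_exhaustive_equivalence_independent(self, rng):
        """Random relabelling converges to full C(n, n_a) enumeration on a
        tiny two-group design (<= 10 trials)."""
        a = rng.normal(1.0, 1.0, size=(4, 30))
        b = rng.normal(0.0, 1.0, size=(6, 30))
        ex = perm_ttest_serial(a, b, "independent", tail="positive",
                               exhaustive=True)
        rd = perm_ttest_serial(a, b, "independent", tail="positive",
                               n_permutations=4000, seed=9)
        p = ex.p_corr
        err = np.maximum(np.abs(rd.p_corr - p) - 1.0 / 4001, 0.0)
        se = np.sqrt(np.maximum(p * (1 - p), 1e-12) / 4000)
        assert err.mean() <= 2 * se.mean()
        assert (err <= 3.9 * np.maximum(se, 1e-9)).all()

    def test_too_few_items_rejected(self):
        with pytest.raises(ConfigurationError):
            perm_ttest_serial(np.zeros((1, 5)), np.zeros((1, 5)), "paired")

    def test_unequal_paired_sets_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            perm_ttest_serial(
                rng.normal(size=(4, 5)), rng.normal(size=(5, 5)), "paired"
            )

    def test_welch_vs_pooled_switch(self, rng):
        a = rng.normal(0.5, 2.0, size=(20, 30))
        b = rng.normal(0.0, 1.0, size=(100, 30))
        rw = perm_ttest_serial(a, b, "independent", tail="positive", seed=0)
        rp = perm_ttest_serial(a, b, "independent", tail="positive", seed=0,
                               equal_var=True)
        assert not np.allclose(rw.t_obs, rp.t_obs)


class TestPeaks:
    def test_noiseless_duration_mmn_peak(self, default_config):
        tpl = build_templates(default_config)
        diff = _series(
            (tpl["duration"].total - tpl["standard"].total).mean(axis=0)
        )
        lat, amp = find_peak(diff, mmn_window())
        assert abs(lat - 205.0) <= 1000.0 / 512.0
        assert amp < 0

    def test_monotone_ramp_peaks_at_edge(self):
        vals = np.linspace(0.0, -5.0, 359)
        lat, amp = find_peak(_series(vals), mmn_window())
        t = _series(vals).time_ms
        in_win = (t >= 80) & (t <= 230)
        assert lat == t[in_win][-1]  # most negative end of a falling ramp
        assert amp == vals[in_win][-1]

    def test_flat_series_ties_to_earliest(self):
        vals = np.zeros(359)
        lat, _ = find_peak(_series(vals), mmn_window())
        t = _series(vals).time_ms
        assert lat == t[(t >= 80)][0]


class TestEffectSizes:
    def test_hand_computed_paired_d(self):
        """Paired diffs {-3, -1, -2, -2}: d = -2 / 0.8165 = -2.449."""
        a = np.array([[-3.0], [-1.0], [-2.0], [-2.0]])
        b = np.zeros_like(a)
        d, _, flag = cohens_d_window(a, b, "paired", (0.0, 0.0), np.array([0.0]))
        assert d == pytest.approx(-2.449, abs=1e-3)
        assert not flag

    def test_zero_variance_flagged_inf(self):
        a = np.full((4, 1), -2.0)
        b = np.zeros_like(a)
        d, _, flag = cohens_d_window(a, b, "paired", (0.0, 0.0), np.array([0.0]))
        assert d == -math.inf
        assert flag

    def test_equal_sets_give_zero(self, rng):
        a = rng.normal(size=(6, 10))
        t = np.arange(10, dtype=float)
        d, g, _ = cohens_d_window(a, a.copy(), "paired", (0.0, 9.0), t)
        assert d == 0.0

    def test_window_clipping_flag(self, rng):
        # rising ramp peaks at the epoch's last sample: the 100 ms
        # peak-centred effect window must clip and be flagged
        diff = _series(np.linspace(0.0, 5.0, 359))
        window = ComponentWindow("late", (540.0, 599.0), "positive")
        a = np.tile(diff.values, (5, 1)) + rng.normal(0, 0.1, size=(5, 359))
        eff = effect_size(a, np.zeros_like(a), "paired", diff, window)
        assert eff.window_clipped

    def test_hedges_correction_shrinks(self, rng):
        a = rng.normal(-1.0, 1.0, size=(8, 20))
        b = np.zeros_like(a)
        t = np.arange(20, dtype=float)
        d, g, _ = cohens_d_window(a, b, "paired", (0.0, 19.0), t)
        assert abs(g) < abs(d)


class TestBayes:
    def test_t_zero_favors_null(self):
        assert bf10_from_t(0.0, 20) < 1.0

    def test_monotone_in_t(self):
        assert bf10_from_t(4.0, 30) > bf10_from_t(2.0, 30)

    @given(st.floats(0.0, 8.0), st.integers(3, 500))
    def test_paired_formula_closed_form(self, t, n):
        expected = (1 + t**2 / (n - 1)) ** (n / 2.0) / math.sqrt(n)
        assert math.exp(log_bf10_from_t(t, n)) == pytest.approx(expected, rel=1e-9)

    def test_series_max_and_category(self, rng):
        a = rng.normal(-1.5, 1.0, size=(12, 100))
        b = rng.normal(0.0, 1.0, size=(12, 100))
        bs = bayes_series(a, b, "paired")
        assert (bs.bf10 > 0).all()
        assert bs.max_bf10 >= bs.bf10.min()
        assert bs.category == classify_evidence(bs.max_bf10)

    def test_jzs_alternative_runs(self, rng):
        a = rng.normal(-1.0, 1.0, size=(8, 20))
        b = rng.normal(0.0, 1.0, size=(8, 20))
        bs = bayes_series(a, b, "paired", method="jzs")
        assert np.isfinite(bs.log10_bf10).all()

    @pytest.mark.parametrize(
        "bf,category",
        [
            (0.5, "favors-null"),
            (1.0, "anecdotal"),
            (2.9, "anecdotal"),
            (3.0, "moderate"),
            (15.0, "strong"),
            (30.0, "very strong"),
            (99.9, "very strong"),
            (100.0, "extreme"),
            (1e9, "extreme"),
        ],
    )
    def test_evidence_bins(self, bf, category):
        assert classify_evidence(bf) == category

    def test_nonpositive_bf_rejected(self):
        with pytest.raises(ConfigurationError):
            classify_evidence(0.0)

    @given(st.floats(0.01, 1e6))
    def test_bins_partition_positive_axis(self, bf):
        assert classify_evidence(bf) in {
            "favors-null", "anecdotal", "moderate", "strong", "very strong",
            "extreme",
        }


class TestDecisions:
    def _perm_and_bayes(self, a, b, window, seed=0):
        perm = perm_ttest_serial(
            a, b, "paired", tail=window.polarity, seed=seed,
            time_ms=_series(a[0]).time_ms,
        )
        bs = bayes_series(a, b, "paired", window, _series(a[0]).time_ms)
        return perm, bs

    def test_strong_effect_present_both_methods(self, rng):
        t = _series(np.zeros(359)).time_ms
        effect = -2.0 * np.exp(-0.5 * ((t - 200.0) / 20.0) ** 2)
        a = effect + rng.normal(0, 0.4, size=(14, 359))
        b = rng.normal(0, 0.4, size=(14, 359))
        perm, bs = self._perm_and_bayes(a, b, mmn_window())
        decisions = decide_presence(perm, bs, mmn_window())
        assert all(d.present for d in decisions)

    def test_bf_just_below_threshold_absent(self, rng):
        perm = perm_ttest_serial(
            rng.normal(size=(6, 50)), rng.normal(size=(6, 50)), "paired",
            tail="negative", seed=0,
        )
        bs = bayes_series(
            rng.normal(size=(6, 50)), rng.normal(size=(6, 50)), "paired"
        )
        bs.max_bf10 = 2.9
        decisions = decide_presence(perm, bs, mmn_window(),
                                    DecisionRules(bf_threshold=3.0))
        bayes_call = [d for d in decisions if d.method == "bayes"][0]
        assert not bayes_call.present

    def test_min_duration_suppresses_single_sample(self):
        t = _series(np.zeros(359)).time_ms
        perm = perm_ttest_serial(
            np.random.default_rng(0).normal(size=(6, 359)),
            np.random.default_rng(1).normal(size=(6, 359)),
            "paired", tail="negative", seed=0, time_ms=t,
        )
        # forge a single significant sample inside the window
        perm.significant_intervals = [(150.0, 150.0)]
        from mmntrack.detect import _perm_present

        assert not _perm_present(perm, mmn_window(), DecisionRules())
        assert _perm_present(perm, mmn_window(), DecisionRules(min_duration_ms=0.0))

    def test_tail_polarity_mismatch_rejected(self, rng):
        a, b = rng.normal(size=(6, 50)), rng.normal(size=(6, 50))
        perm = perm_ttest_serial(a, b, "paired", tail="positive", seed=0)
        bs = bayes_series(a, b, "paired")
        with pytest.raises(ConfigurationError):
            decide_presence(perm, bs, mmn_window())


def test_end_to_end_single_subject_noiseless(small_config):
    """Noiseless fixture: duration MMN/P3a peaks recovered at template
    latencies from the averaged difference wave."""
    from mmntrack import NoiseModel, generate_sequence, synthesize_epochs

    tpl = build_templates(small_config)
    noise = NoiseModel(0.0, 0.0, 0.0, seed=0)
    ep = synthesize_epochs(generate_sequence(small_config), tpl, noise,
                           small_config)
    ev = average_by_condition(ep)
    diff = difference_series(ev["duration"], ev["standard"])
    lat_mmn, amp_mmn = find_peak(diff, mmn_window())
    lat_p3a, amp_p3a = find_peak(diff, p3a_window())
    assert abs(lat_mmn - 205.0) <= 1000.0 / 512.0
    assert abs(lat_p3a - 300.0) <= 1000.0 / 512.0
    assert amp_mmn < 0 < amp_p3a
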