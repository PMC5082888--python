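"""Epoching, averaging, CNR, HR summaries and condition comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsbundle import (
    CNRConfig,
    aggregate_conditions,
    aggregate_pair,
    average_epochs,
    cnr,
    compare_conditions,
    epoch_trials,
    generate_paradigm,
    hr_summary,
)
from nirsbundle.activation import trial_regressor
from nirsbundle.errors import ConfigError, DataError
from nirsbundle.metrics import HRSummary

FS = 1.81


class TestEpoching:
    def test_five_epochs_per_condition(self, paradigm):
        n = int(round(paradigm.total_duration_s * FS))
        y = np.zeros(n)
        for cond in ("little", "thumb"):
            assert len(epoch_trials(y, FS, paradigm, condition=cond)) == 5
        assert len(epoch_trials(y, FS, paradigm)) == 10

    def test_forty_eight_channels_ten_trials_480_epochs(self, paradigm):
        n = int(round(paradigm.total_duration_s * FS))
        total = sum(
            len(epoch_trials(np.zeros(n), FS, paradigm)) for _ in range(48)
        )
        assert total == 480

    def test_unknown_condition_no_epochs(self, paradigm):
        n = int(round(paradigm.total_duration_s * FS))
        assert epoch_trials(np.zeros(n), FS, paradigm, condition="ring") == []

    def test_out_of_bounds_epochs_dropped(self, paradigm):
        short = np.zeros(int(round(100 * FS)))  # recording ends at 100 s
        epochs = epoch_trials(short, FS, paradigm)
        onsets_fitting = [o for o in paradigm.onsets() if (o + 24) <= 100]
        assert len(epochs) == len(onsets_fitting)

    def test_epoch_length_is_54_samples(self, paradigm):
        n = int(round(paradigm.total_duration_s * FS))
        epochs = epoch_trials(np.arange(n, dtype=float), FS, paradigm)
        assert {len(e) for e in epochs} == {54}


class TestAveraging:
    def test_identical_epochs_zero_sd(self):
        e = np.sin(np.arange(54) / 5)
        mean, sd = average_epochs([e, e, e])
        assert np.allclose(mean, e)
        assert np.allclose(sd, 0)

    def test_opposite_epochs_zero_mean(self):
        e = np.sin(np.arange(54) / 5)
        mean, _ = average_epochs([e, -e])
        assert np.allclose(mean, 0)

    def test_noisy_copies_converge_to_truth(self):
        truth = trial_regressor(FS)
        rng = np.random.default_rng(0)
        epochs = [truth + rng.normal(0, 0.2, truth.size) for _ in range(5)]
        mean, sd = average_epochs(epochs)
        # CLT bound: pointwise |mean - truth| within 3*sd/sqrt(5)
        bound = 3 * sd / math.sqrt(5)
        assert np.mean(np.abs(mean - truth) <= bound + 1e-12) > 0.95

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(DataError):
            average_epochs([np.zeros(10), np.zeros(11)])

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            average_epochs([])


class TestCNR:
    def test_task_equals_rest_zero_cnr(self, rng):
        # identical sample content in the task and rest windows -> CNR = 0
        fs = 1.0
        pattern = rng.normal(size=6)
        series = np.zeros(30)
        series[0:6] = pattern  # rest window [-6, 0) relative to onset at 6 s
        series[12:18] = pattern  # task window [6, 12) post-onset
        c = cnr(series, fs, onset_s=6.0, config=CNRConfig(task_window_s=(6.0, 12.0)))
        assert c == pytest.approx(0.0, abs=1e-12)

    def test_unit_contrast_arithmetic(self):
        """mean_task=1, mean_rest=0, var_task=var_rest=0.5 -> CNR=1."""
        fs = 1.0
        rest = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0]) * math.sqrt(5.0 / 12.0)
        task_dev = np.array([1.0, -1.0] * 5) * math.sqrt(0.45)
        series = np.zeros(30)
        series[0:6] = rest
        series[12:22] = 1.0 + task_dev
        assert np.var(series[0:6], ddof=1) == pytest.approx(0.5)
        assert np.var(series[12:22], ddof=1) == pytest.approx(0.5)
        c = cnr(series, fs, onset_s=6.0)
        assert c == pytest.approx(1.0)

    def test_negation_antisymmetry(self, rng):
        series = rng.normal(size=54)
        c_pos = cnr(series, FS, onset_s=0.0, t0_series_s=-6.0)
        c_neg = cnr(-series, FS, onset_s=0.0, t0_series_s=-6.0)
        assert c_neg == pytest.approx(-c_pos)

    @settings(max_examples=30, deadline=None)
    @given(scale=st.floats(min_value=0.01, max_value=100, allow_nan=False))
    def test_positive_scaling_invariance(self, scale):
        rng = np.random.default_rng(5)
        series = rng.normal(size=54) + trial_regressor(FS)
        base = cnr(series, FS, onset_s=0.0, t0_series_s=-6.0)
        scaled = cnr(scale * series, FS, onset_s=0.0, t0_series_s=-6.0)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            cnr(np.ones(54), FS, onset_s=0.0, t0_series_s=-6.0)


class TestHRSummary:
    def test_scaled_hrf_peak_and_time(self):
        reg = trial_regressor(FS)
        reg = reg / reg.max()
        s = hr_summary(reg, FS)
        assert s.peak == pytest.approx(1.0)
        t_grid = -6.0 + np.arange(reg.size) / FS
        assert s.time_to_peak_s == pytest.approx(t_grid[np.argmax(reg)])
        assert 0 < s.time_to_peak_s < 20

    def test_constant_series_degenerate_skew(self):
        s = hr_summary(np.full(54, 2.5), FS)
        assert s.mean == s.peak == 2.5
        assert s.skewness == 0.0
        assert not s.skew_defined

    def test_symmetric_triangle_zero_skew(self):
        # brute-force check on the sampled window: symmetric -> skew ~ 0
        n = 54
        fs = FS
        y = np.zeros(n)
        i0 = int(round(6 * fs))
        i1 = int(round(26 * fs))
        m = i1 - i0
        half = m // 2
        tri = np.concatenate([np.linspace(0, 1, half), np.linspace(1, 0, m - half)])
        y[i0:i1] = tri
        s = hr_summary(y, fs)
        assert abs(s.skewness) < 0.15

    def test_empty_window_rejected(self):
        with pytest.raises(DataError):
            hr_summary(np.zeros(54), FS, response_window_s=(0.0, 50.0))


class TestAggregate:
    @pytest.mark.parametrize(
        "a,b,mean,sd",
        [
            (5.04, 5.34, 5.19, 0.21),
            (5.06, 5.35, 5.21, 0.21),
            (9.39, 9.94, 9.67, 0.39),
            (0.57, 0.48, 0.53, 0.06),
        ],
    )
    def test_condition_pair_cells(self, a, b, mean, sd):
        assert aggregate_pair(a, b) == (mean, sd)

    def test_equal_inputs_zero_sd(self):
        assert aggregate_pair(4.2, 4.2) == (4.2, 0.0)

    def test_aggregate_conditions_fields(self):
        s1 = HRSummary(mean=5.04, peak=5.06, time_to_peak_s=9.39, skewness=0.57)
        s2 = HRSummary(mean=5.34, peak=5.35, time_to_peak_s=9.94, skewness=0.48)
        agg = aggregate_conditions([s1, s2])
        assert agg["mean"] == (5.19, 0.21)
        assert agg["peak"] == (5.21, 0.21)
        assert agg["time_to_peak_s"] == (9.67, 0.39)
        assert agg["skewness"] == (0.53, 0.06)

    def test_single_summary_rejected(self):
        with pytest.raises(DataError):
            aggregate_conditions([HRSummary(1, 1, 1, 0)])


class TestCompareConditions:
    def _epochs(self, rng, shift, n=20):
        reg = trial_regressor(FS)
        return [shift * reg + rng.normal(0, 1.0, reg.size) for _ in range(n)]

    def test_identical_groups_p_near_one(self, rng):
        a = self._epochs(rng, 1.0)
        t, p = compare_conditions(a, list(a), FS)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(1)
        reg = trial_regressor(FS)
        a = [0.0 * reg + rng.normal(0, 1, reg.size) for _ in range(20)]
        b = [20.0 * reg.max() + reg * 0 + rng.normal(0, 1, reg.size) for _ in range(20)]
        _, p = compare_conditions(a, b, FS)
        assert p < 1e-3

    def test_group_swap_symmetry(self, rng):
        a = self._epochs(rng, 0.5)
        b = self._epochs(rng, 1.5)
        t_ab, p_ab = compare_conditions(a, b, FS)
        t_ba, p_ba = compare_conditions(b, a, FS)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_degenerate_variance_rejected(self):
        a = [np.zeros(54)] * 3
        with pytest.raises(DataError):
            compare_conditions(a, a, FS)


def test_paradigm_counts_and_duration():
    for seed in (0, 1, 2):
        p = generate_paradigm(seed)
        assert p.total_duration_s == 320.0
        assert len(p.trials) == 10
        assert len(p.onsets("little")) == 5
        assert len(p.onsets("thumb")) == 5
        assert p.onsets() == [20.0 + 30.0 * k for k in range(10)]
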