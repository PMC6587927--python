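import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn

from p3decode import (
    amplitude_contrast,
    decode_contrast,
    downselect_power_curve,
    epoch_events,
    latency_split,
    lognormal_mode,
    roi_average,
    rt_tertiles,
    window_mean,
)
from p3decode.constants import ROI_CHANNELS
from p3decode.preprocess import EpochSet
from p3decode.stats import baselined_values


def _epochs(data, channel_names, window=(0.0, 1.0), labels=None, meta=None):
    n = data.shape[0]
    if labels is None:
        labels = np.zeros(n, dtype=int)
    if meta is None:
        meta = pd.DataFrame({
            "onset_s": np.arange(n, dtype=float), "label": "background",
            "subject": "s1", "experiment": "E", "condition": "c",
        })
    return EpochSet(data=data, window=window, labels=labels, meta=meta,
                    sample_rate_hz=128.0, channel_names=channel_names)


def _roi_channel_names():
    extra = tuple(f"ch{i}" for i in range(64 - len(ROI_CHANNELS)))
    return ROI_CHANNELS + extra


class TestRoiAverage:
    def test_identical_channels(self):
        names = _roi_channel_names()
        data = np.tile(np.arange(128.0), (2, 64, 1))
        traces = roi_average(_epochs(data, names))
        np.testing.assert_allclose(traces.values[0], data[0, 0])

    def test_pz_six_others_zero(self):
        names = _roi_channel_names()
        data = np.zeros((1, 64, 128))
        data[0, names.index("Pz")] = 6.0
        traces = roi_average(_epochs(data, names))
        np.testing.assert_allclose(traces.values[0], 1.0)

    def test_missing_channel_named(self):
        names = tuple(f"ch{i}" for i in range(64))
        with pytest.raises(ValueError, match="Pz"):
            roi_average(_epochs(np.zeros((1, 64, 128)), names))

    def test_noiseless_template_projection(self, clean_db, template, montage):
        """ROI trace of a noiseless trial = template x mean ROI topography gain."""
        (_, rec), = clean_db.recordings.items()
        ep = epoch_events(rec, clean_db.events)
        traces = roi_average(ep)
        tgt = (ep.meta["label"] == "target").to_numpy()
        expected = template.waveform(traces.times_s) * template.topography[montage.roi_indices()].mean()
        np.testing.assert_allclose(traces.values[tgt][0], expected, atol=1e-5)


class TestWindowMean:
    times = np.arange(128) / 128.0

    def test_constant(self):
        assert window_mean(np.full(128, 3.5), self.times) == pytest.approx(3.5)

    def test_ramp_mean_is_midpoint(self):
        # samples 52..108 inclusive on the 128 Hz grid average to 0.625
        assert window_mean(self.times.copy(), self.times) == pytest.approx(0.625)

    def test_zero(self):
        assert window_mean(np.zeros(128), self.times) == 0.0

    def test_window_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            window_mean(np.zeros(64), self.times[:64], window=(0.4, 0.85))

    def test_vectorized_over_trials(self):
        vals = np.stack([np.zeros(128), np.ones(128)])
        out = window_mean(vals, self.times)
        np.testing.assert_allclose(out, [0.0, 1.0])

    @settings(max_examples=20, deadline=None)
    @given(c=stn.floats(min_value=-1e6, max_value=1e6))
    def test_constant_property(self, c):
        assert window_mean(np.full(128, c), self.times) == pytest.approx(c)


def _values_df(cond_values: dict, bg_by_subject: dict, subject="s1"):
    rows = []
    for cond, vals in cond_values.items():
        for v in vals:
            rows.append(dict(subject=subject, condition=cond, label="target", amp=v, prob=v))
    targets = pd.DataFrame(rows)
    bgr = []
    for subj, vals in bg_by_subject.items():
        for v in vals:
            bgr.append(dict(subject=subj, condition="any", label="background", amp=v, prob=v))
    return targets, pd.DataFrame(bgr)


class TestContrasts:
    def test_identical_values_p_half(self):
        vals = np.random.default_rng(0).standard_normal(50)
        targets, bg = _values_df({"a": vals, "b": vals}, {"s1": [0.0]})
        res = amplitude_contrast(targets, bg, "a", "b")
        assert res.p == pytest.approx(0.5)
        assert res.t == pytest.approx(0.0)

    def test_background_only_targets_centered_at_zero(self):
        rng = np.random.default_rng(1)
        bg_vals = rng.standard_normal(500)
        targets, bg = _values_df({"a": bg_vals[:250]}, {"s1": bg_vals})
        out = baselined_values(targets, bg, "amp")
        assert abs(out["amp"].mean()) < 5 * bg_vals.std() / np.sqrt(250)

    def test_missing_background_subject_rejected(self):
        targets, bg = _values_df({"a": [1.0], "b": [0.5]}, {"other": [0.0]})
        with pytest.raises(ValueError, match="s1"):
            amplitude_contrast(targets, bg, "a", "b")

    def test_monte_carlo_power(self):
        """N(1.0, 0.3) vs N(0.7, 0.3), n=200: p < 0.01 in >= 95% of seeded runs."""
        hits = 0
        n_runs = 60
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            targets, bg = _values_df(
                {"a": rng.normal(1.0, 0.3, 200), "b": rng.normal(0.7, 0.3, 200)},
                {"s1": [0.0]},
            )
            if amplitude_contrast(targets, bg, "a", "b").p < 0.01:
                hits += 1
        assert hits / n_runs >= 0.95

    def test_constant_decoder_stub_all_zero_differences(self):
        targets, bg = _values_df({"a": [0.7] * 5, "b": [0.7] * 5}, {"s1": [0.7] * 20})
        out = baselined_values(targets, bg, "prob")
        np.testing.assert_allclose(out["prob"], 0.0, atol=1e-12)

    def test_baselining_invariance(self):
        """Adding a per-subject constant to every trial leaves the contrast unchanged."""
        rng = np.random.default_rng(2)
        t1, b1 = _values_df(
            {"a": rng.normal(1, 0.3, 80), "b": rng.normal(0.8, 0.3, 80)},
            {"s1": rng.normal(0, 0.3, 100)},
        )
        res1 = amplitude_contrast(t1, b1, "a", "b")
        t2, b2 = t1.copy(), b1.copy()
        t2["amp"] += 17.3
        b2["amp"] += 17.3
        res2 = amplitude_contrast(t2, b2, "a", "b")
        assert res1.t == pytest.approx(res2.t, rel=1e-9)
        assert res1.p == pytest.approx(res2.p, rel=1e-9)

    def test_decode_contrast_uses_prob_column(self):
        rng = np.random.default_rng(3)
        targets, bg = _values_df(
            {"a": rng.normal(0.8, 0.1, 100), "b": rng.normal(0.5, 0.1, 100)},
            {"s1": rng.normal(0.2, 0.1, 100)},
        )
        res = decode_contrast(targets, bg, "a", "b")
        assert res.p < 0.01
        assert 0 < res.p <= 1


class TestDownselect:
    def _pool(self, seed=4, n=120, n_subjects=2):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subjects):
            subj = f"s{s}"
            for cond, mu in (("a", 1.0), ("b", 0.8)):
                for v, p in zip(rng.normal(mu, 0.3, n), rng.normal(mu, 0.15, n)):
                    rows.append(dict(subject=subj, condition=cond, label="target", amp=v, prob=p))
        targets = pd.DataFrame(rows)
        bg = pd.DataFrame([
            dict(subject=f"s{s}", condition="any", label="background", amp=v, prob=v)
            for s in range(n_subjects) for v in rng.normal(0, 0.3, 200)
        ])
        return targets, bg

    def test_fraction_one_reproduces_direct_contrast_exactly(self):
        targets, bg = self._pool()
        curve = downselect_power_curve(targets, bg, "a", "b", [1.0], n_reps=3, seed=0)
        direct_amp = amplitude_contrast(targets, bg, "a", "b").p
        direct_dec = decode_contrast(targets, bg, "a", "b").p
        for method, direct in (("amplitude", direct_amp), ("decode", direct_dec)):
            ps = curve.records.loc[curve.records["method"] == method, "p"]
            assert (ps == direct).all()

    def test_determinism(self):
        targets, bg = self._pool()
        a = downselect_power_curve(targets, bg, "a", "b", [0.3, 0.6], n_reps=1, seed=42)
        b = downselect_power_curve(targets, bg, "a", "b", [0.3, 0.6], n_reps=1, seed=42)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_mean_p_nonincreasing_in_fraction(self):
        targets, bg = self._pool(seed=5, n=150)
        curve = downselect_power_curve(
            targets, bg, "a", "b", [0.2, 0.5, 1.0], n_reps=100, seed=1
        )
        for method in ("amplitude", "decode"):
            s = curve.summary[curve.summary["method"] == method].sort_values("fraction")
            mp = s["mean_p"].to_numpy()
            assert mp[0] >= mp[1] >= mp[2]

    def test_tiny_fraction_skipped_with_warning(self):
        targets, bg = self._pool(n=20)
        with pytest.warns(UserWarning, match="skipped"):
            curve = downselect_power_curve(targets, bg, "a", "b", [0.05, 1.0], n_reps=2, seed=0)
        assert curve.skipped_fractions == [0.05]
        assert set(curve.summary["fraction"]) == {1.0}

    def test_invalid_fraction_rejected(self):
        targets, bg = self._pool(n=10)
        with pytest.raises(ValueError, match="fractions"):
            downselect_power_curve(targets, bg, "a", "b", [0.0, 0.5], n_reps=1, seed=0)


class TestRtTertiles:
    def test_one_to_nine(self):
        groups, (q33, q66) = rt_tertiles(np.arange(1.0, 10.0))
        np.testing.assert_array_equal(groups[0], [0, 1, 2])
        np.testing.assert_array_equal(groups[1], [3, 4, 5])
        np.testing.assert_array_equal(groups[2], [6, 7, 8])

    def test_ties_warn(self):
        with pytest.warns(UserWarning, match="degenerate"):
            groups, _ = rt_tertiles(np.full(10, 0.5))
        sizes = sorted(len(g) for g in groups)
        assert sizes == [0, 0, 10]

    def test_lognormal_group_sizes(self):
        rng = np.random.default_rng(6)
        rts = rng.lognormal(-0.5, 0.4, 3000)
        groups, _ = rt_tertiles(rts)
        for g in groups:
            assert abs(len(g) - 1000) <= 20

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            rt_tertiles(np.array([0.3, np.nan, 0.5]))

    def test_too_few_rejected(self):
        with pytest.raises(ValueError, match="3"):
            rt_tertiles(np.array([0.3, 0.4]))


class TestLognormalMode:
    def test_degenerate_all_equal(self):
        assert lognormal_mode(np.full(100, 0.5)) == pytest.approx(0.5)

    def test_parameter_recovery(self):
        mu, sigma = -1.517, 0.4
        rng = np.random.default_rng(7)
        sample = rng.lognormal(mu, sigma, 10_000)
        mode = lognormal_mode(sample)
        expected = np.exp(mu - sigma**2)
        assert abs(mode - expected) / expected < 0.05

    def test_mode_below_median(self):
        rng = np.random.default_rng(8)
        sample = rng.lognormal(-1.0, 0.5, 5000)
        assert lognormal_mode(sample) < np.median(sample)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            lognormal_mode(np.array([0.5, 0.0, 0.2]))


class TestLatencySplit:
    def test_boundary_rule(self):
        split = latency_split(np.array([0.1, 0.2194, 0.3]), threshold_s=0.2194)
        np.testing.assert_array_equal(split["short"], [0])
        np.testing.assert_array_equal(split["long"], [1, 2])

    def test_threshold_below_min_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            split = latency_split(np.array([0.5, 0.6]), threshold_s=0.1)
        assert len(split["short"]) == 0

    def test_missing_latency_rejected(self):
        with pytest.raises(ValueError, match="latencies"):
            latency_split(np.array([0.2, np.nan]))
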