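"""Referencing, segmentation, Welch PSD, baseline normalization, bands."""

import numpy as np
import pytest
from scipy import signal as sps

from ecogest import io, preprocess
from ecogest.preprocess import (
    BandPartition,
    BaselineStats,
    PSDMatrix,
    SegmentPlan,
    WelchConfig,
    band_aggregate,
    baseline_mean,
    normalize_psd,
    rapid_window_plan,
    reference_filter,
    segment_array,
    welch_psd,
)


def recording(signal, fs=1000.0):
    events = io.EventTable.from_rows([(0, "cue_start", 0.01, "rock"), (0, "cue_stop", 0.02, "")])
    return io.Recording(np.asarray(signal, float), fs, [str(i) for i in range(len(signal))], events)


class TestReferenceFilter:
    def test_session_mean_zeroes_constant_channels(self):
        rec = recording(np.full((2, 100), 7.0))
        out = reference_filter(rec, "session_mean")
        assert np.allclose(out.signal, 0.0)

    def test_car_leaves_antisymmetric_pair_unchanged(self):
        x = np.sin(np.linspace(0, 10, 200))[None, :]
        rec = recording(np.vstack([x, -x]))
        out = reference_filter(rec, "car")
        assert np.allclose(out.signal, rec.signal)

    def test_session_mean_gives_zero_mean_channels(self):
        rng = np.random.default_rng(0)
        rec = recording(rng.normal(size=(4, 1000)))
        out = reference_filter(rec, "session_mean")
        assert np.allclose(out.signal.mean(axis=1), 0.0, atol=1e-12)

    def test_car_on_single_channel_is_refused(self):
        rec = recording(np.ones((1, 100)))
        with pytest.raises(ValueError):
            reference_filter(rec, "car")


class TestSegmentation:
    def test_default_plan_cuts_ten_segments_from_1200ms(self):
        segs = segment_array(np.zeros((3, 1200)), 1000.0, SegmentPlan())
        assert len(segs) == 10
        assert all(s.shape == (3, 300) for s in segs)

    def test_single_whole_epoch_window(self):
        plan = SegmentPlan(window_ms=500, stride_ms=0, n_segments=1)
        segs = segment_array(np.zeros((2, 500)), 1000.0, plan)
        assert len(segs) == 1 and segs[0].shape == (2, 500)

    def test_zero_stride_repeats_the_same_window(self):
        plan = SegmentPlan(window_ms=300, stride_ms=0, n_segments=10)
        x = np.random.default_rng(1).normal(size=(1, 400))
        segs = segment_array(x, 1000.0, plan)
        assert len(segs) == 10
        for s in segs[1:]:
            assert np.array_equal(s, segs[0])

    def test_too_short_epoch_reports_required_duration(self):
        with pytest.raises(ValueError, match="needs"):
            segment_array(np.zeros((1, 500)), 1000.0, SegmentPlan())

    def test_window_starts_are_rounded_per_segment(self):
        # non-integer stride: starts follow round(i * stride * fs)
        plan = SegmentPlan(window_ms=100, stride_ms=100 / 9, n_segments=10)
        starts = plan.starts(1000.0)
        assert list(starts) == [round(i * 100 / 9) for i in range(10)]


class TestWelch:
    def test_sinusoid_peak_matches_periodogram_oracle(self):
        fs = 2000.0
        t = np.arange(600) / fs
        x = np.sin(2 * np.pi * 50 * t)[None, :]
        psd = welch_psd(x, fs, WelchConfig())
        f_ref, p_ref = sps.periodogram(x, fs=fs, axis=1)
        assert psd.freqs[np.argmax(psd.values[0])] == pytest.approx(
            f_ref[np.argmax(p_ref[0])], abs=4.0
        )
        assert abs(psd.freqs[np.argmax(psd.values[0])] - 50.0) < 4.0

    def test_zero_signal_gives_zero_psd(self):
        psd = welch_psd(np.zeros((2, 600)), 2000.0)
        assert np.allclose(psd.values, 0.0)

    def test_white_noise_total_power_is_parseval_consistent(self):
        rng = np.random.default_rng(3)
        fs, sigma = 1000.0, 1.5
        totals = []
        for _ in range(50):
            x = rng.normal(scale=sigma, size=(1, 512))
            psd = welch_psd(x, fs, WelchConfig(nperseg=256, nfft=256))
            df = psd.freqs[1] - psd.freqs[0]
            totals.append(psd.values.sum() * df)
        assert np.mean(totals) == pytest.approx(sigma**2, rel=0.2)

    def test_short_segment_is_rejected_until_capped(self):
        cfg = WelchConfig(nperseg=256)
        with pytest.raises(ValueError, match="shorter"):
            welch_psd(np.zeros((1, 100)), 1000.0, cfg)
        psd = welch_psd(np.zeros((1, 100)), 1000.0, cfg.for_length(100))
        assert psd.values.shape[1] == 256 // 2 + 1  # nfft keeps the grid


def psd_matrix(values, fs=1000.0, nfft=256):
    freqs = np.fft.rfftfreq(nfft, 1 / fs)
    return PSDMatrix(values=np.broadcast_to(values, (2, len(freqs))).copy(), freqs=freqs)


class TestBaselineAndNormalization:
    def test_single_matrix_baseline_is_itself(self):
        m = psd_matrix(np.linspace(1, 2, 129))
        base = baseline_mean([m])
        assert np.array_equal(base.mean_psd, m.values)
        assert base.n_relax_segments == 1

    def test_mean_of_a_and_3a_is_2a(self):
        a = psd_matrix(np.linspace(1, 2, 129))
        b = PSDMatrix(values=3 * a.values, freqs=a.freqs)
        base = baseline_mean([a, b])
        assert np.allclose(base.mean_psd, 2 * a.values)

    def test_baseline_variance_shrinks_like_one_over_n(self):
        # each baseline bin is the mean of n iid draws, so across repeated
        # baselines its variance is the element variance / n
        rng = np.random.default_rng(7)
        n = 40
        baselines = [
            baseline_mean([psd_matrix(rng.uniform(1, 2, size=129)) for _ in range(n)])
            for _ in range(300)
        ]
        bin_var = np.var([b.mean_psd[0, 5] for b in baselines])
        assert bin_var == pytest.approx((1 / 12) / n, rel=0.3)

    def test_inconsistent_grids_rejected(self):
        a = psd_matrix(np.ones(129), nfft=256)
        b = psd_matrix(np.ones(65), nfft=128)
        with pytest.raises(ValueError):
            baseline_mean([a, b])
        with pytest.raises(ValueError):
            baseline_mean([])

    def test_normalizing_by_itself_gives_ones(self):
        m = psd_matrix(np.linspace(1, 5, 129))
        base = baseline_mean([m])
        out = normalize_psd(m, base)
        assert np.allclose(out.values, 1.0)

    def test_double_task_psd_gives_twos_and_scale_invariance(self):
        m = psd_matrix(np.linspace(1, 5, 129))
        base = baseline_mean([m])
        doubled = PSDMatrix(values=2 * m.values, freqs=m.freqs)
        assert np.allclose(normalize_psd(doubled, base).values, 2.0)
        scaled_base = BaselineStats(7 * base.mean_psd, base.freqs, 1)
        scaled_task = PSDMatrix(values=7 * doubled.values, freqs=m.freqs)
        assert np.array_equal(
            normalize_psd(scaled_task, scaled_base).values,
            normalize_psd(doubled, base).values,
        )

    def test_zero_baseline_bin_in_analysis_band_is_an_error(self):
        m = psd_matrix(np.ones(129))
        base = baseline_mean([m])
        base.mean_psd[:, 10] = 0.0  # bin 10 is ~39 Hz, inside 12-40
        with pytest.raises(ValueError, match="non-positive"):
            normalize_psd(m, base, BandPartition())


class TestBandAggregation:
    def grid(self, fs=2000.0, nfft=256):
        return np.fft.rfftfreq(nfft, 1 / fs)

    def test_constant_psd_aggregates_to_the_constant(self):
        freqs = self.grid()
        norm = PSDMatrix(values=np.full((3, len(freqs)), 4.2), freqs=freqs)
        out = band_aggregate(norm, BandPartition())
        assert out.shape == (3, 5)
        assert np.allclose(out, 4.2)

    def test_default_partition_gives_five_features_per_channel(self):
        freqs = self.grid()
        norm = PSDMatrix(values=np.ones((8, len(freqs))), freqs=freqs)
        assert band_aggregate(norm, BandPartition()).shape == (8, 5)

    def test_indicator_psd_isolates_its_band(self):
        freqs = self.grid()
        part = BandPartition()
        mask = (freqs >= 70) & (freqs < 135)
        values = np.where(mask, 1.0, 0.0)[None, :]
        out = band_aggregate(PSDMatrix(values=values, freqs=freqs), part)
        expected = np.zeros(5)
        expected[part.labels.index("70-135")] = 1.0
        assert np.allclose(out[0], expected)

    def test_band_with_no_bins_reports_resolution(self):
        freqs = np.array([0.0, 50.0, 100.0])
        norm = PSDMatrix(values=np.ones((1, 3)), freqs=freqs)
        part = BandPartition((("4-12", 4.0, 12.0),))
        with pytest.raises(ValueError, match="4-12"):
            band_aggregate(norm, part)

    def test_aggregation_commutes_with_channel_permutation(self):
        rng = np.random.default_rng(2)
        freqs = self.grid()
        values = rng.uniform(0, 2, size=(6, len(freqs)))
        perm = rng.permutation(6)
        a = band_aggregate(PSDMatrix(values=values[perm], freqs=freqs), BandPartition())
        b = band_aggregate(PSDMatrix(values=values, freqs=freqs), BandPartition())[perm]
        assert np.array_equal(a, b)


class TestRapidWindowPlan:
    def test_longest_interval_recovers_the_default_plan(self):
        plan = rapid_window_plan(1200.0)
        assert (plan.window_ms, plan.stride_ms, plan.n_segments) == (300.0, 100.0, 10)

    def test_300ms_interval_degenerates_to_zero_stride(self):
        plan = rapid_window_plan(300.0)
        assert plan.stride_ms == 0.0 and plan.window_ms == 300.0

    def test_short_interval_halves_the_window(self):
        plan = rapid_window_plan(200.0)
        assert plan.window_ms == pytest.approx(100.0)
        assert plan.stride_ms == pytest.approx(100.0 / 9.0)

    @pytest.mark.parametrize("t_ms", range(100, 1300, 100))
    def test_ten_windows_tile_the_interval_exactly(self, t_ms):
        plan = rapid_window_plan(float(t_ms))
        assert plan.n_segments == 10
        assert plan.coverage_ms == pytest.approx(float(t_ms))

    def test_out_of_range_interval_rejected(self):
        for t in (50.0, 1300.0):
            with pytest.raises(ValueError):
                rapid_window_plan(t)


class TestFullPipeline:
    def test_null_session_features_are_near_one(self, null_features):
        ds, _ = null_features
        assert ds.X.mean() == pytest.approx(1.0, abs=0.05)

    def test_feature_matrix_shape_is_segments_by_channels_times_bands(self, small_features):
        ds, _ = small_features
        assert ds.X.shape == (30, 10, 8 * 5)
        assert len(ds.feature_names) == 40

    def test_planted_features_are_elevated(self, small_features):
        from conftest import planted_columns

        ds, truth = small_features
        cols = planted_columns(ds, truth)
        others = [j for j in range(ds.n_features) if j not in cols]
        assert ds.X[:, :, cols].mean() > 1.3
        assert ds.X[:, :, others].mean() == pytest.approx(1.0, abs=0.05)
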