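"""Calcium pipeline: ROI extraction, ratio formula, photobleach fit and
correction, binning, signed area, and end-to-end recovery against the
generator's ground truth."""

import numpy as np
import pytest

from famfeed.imaging import (
    CalciumResponseModel,
    PipelineError,
    RatioTrace,
    TwoChannelRecording,
    average_binned,
    bin_timecourse,
    compare_response_groups,
    compute_raw_ratio,
    correct_photobleach,
    extract_roi_trace,
    fit_photobleach,
    signed_area,
)
from famfeed.simulate import ImagingSimParams, gen_imaging_recording, render_tiff_stack


def make_recording(cyan, yellow, bg_c=0.0, bg_y=0.0, onset=0.0, dt=1.0):
    cyan = np.asarray(cyan, dtype=float)
    n = len(cyan)
    return TwoChannelRecording(
        time_s=np.arange(n) * dt,
        i_480=cyan,
        i_535=np.asarray(yellow, dtype=float),
        bg_480=np.full(n, bg_c),
        bg_535=np.full(n, bg_y),
        stimulus_onset_s=onset,
    )


class TestRoiExtraction:
    def _stack(self, frames):
        return np.stack([np.stack([f, f]) for f in frames])  # same both channels

    def test_uniform_frames(self):
        stack = self._stack([np.full((21, 21), 7.0)] * 4)
        rec = extract_roi_trace(stack, (10, 10), 3.0, 8.0, np.arange(4.0), 0.0)
        np.testing.assert_allclose(rec.i_480, 7.0)
        np.testing.assert_allclose(rec.bg_480, 7.0)

    def test_single_bright_pixel(self):
        # radius-1 disc about an integer centre holds 5 pixels (centre + 4)
        frame = np.zeros((15, 15))
        frame[7, 7] = 10.0
        rec = extract_roi_trace(self._stack([frame, frame]), (7, 7), 1.0, 4.0,
                                np.array([0.0, 1.0]), 0.0)
        assert rec.i_480[0] == pytest.approx(10.0 / 5)
        assert rec.bg_480[0] == 0.0

    def test_roi_out_of_bounds_rejected(self):
        stack = self._stack([np.zeros((10, 10))])
        with pytest.raises(PipelineError, match="bounds"):
            extract_roi_trace(stack, (1, 1), 2.0, 6.0, np.array([0.0]), 0.0)

    def test_empty_annulus_rejected(self):
        stack = self._stack([np.zeros((21, 21))])
        with pytest.raises(PipelineError, match="annulus"):
            extract_roi_trace(stack, (10, 10), 1.0, 1.05, np.array([0.0]), 0.0)

    def test_renderer_round_trip(self, tmp_path):
        import tifffile

        p = ImagingSimParams(duration_s=10.0, transient_amplitude=0.1,
                             stimulus_onset_s=5.0, noise_sd=0.0)
        rec, _ = gen_imaging_recording(p)
        path = tmp_path / "stack.tif"
        render_tiff_stack(rec, path, shape=(64, 64), center=(32, 32),
                          spot_sigma=3.0, roi_radius=10.0)
        stack = tifffile.imread(str(path))
        got = extract_roi_trace(stack, (32, 32), 10.0, 20.0,
                                rec.time_s, rec.stimulus_onset_s)
        np.testing.assert_allclose(got.i_480, rec.i_480, rtol=0.01)
        np.testing.assert_allclose(got.i_535, rec.i_535, rtol=0.01)


class TestRawRatio:
    def test_pure_bleed_through_cancels(self):
        cyan = np.array([100.0, 90.0, 80.0]) + 5.0
        rec = make_recording(cyan, 0.65 * (cyan - 5.0) + 3.0, bg_c=5.0, bg_y=3.0)
        raw = compute_raw_ratio(rec)
        np.testing.assert_allclose(raw.values, 0.0, atol=1e-12)

    def test_direct_arithmetic(self):
        rec = make_recording([100.0, 100.0], [165.0, 165.0])
        raw = compute_raw_ratio(rec)
        np.testing.assert_allclose(raw.values, 1.00)

    def test_time_realigned_to_stimulus(self):
        rec = make_recording(np.ones(5) * 10, np.ones(5) * 10, onset=2.0)
        raw = compute_raw_ratio(rec)
        np.testing.assert_allclose(raw.time_s, [-2, -1, 0, 1, 2])

    def test_zero_denominator_names_frame(self):
        rec = make_recording([100.0, 5.0, 100.0], [165.0] * 3, bg_c=5.0)
        with pytest.raises(PipelineError, match="frame 1"):
            compute_raw_ratio(rec)


class TestPhotobleachFit:
    def test_exact_exponential_recovered(self):
        t = np.arange(0.0, 300.0, 0.5)
        tr = RatioTrace(t, 2.0 * np.exp(-t / 300.0), "raw")
        fit = fit_photobleach(tr)
        assert fit.amplitude == pytest.approx(2.0, rel=1e-6)
        assert fit.decay_rate == pytest.approx(1 / 300.0, rel=1e-6)

    def test_constant_trace_boundary(self):
        t = np.arange(0.0, 100.0)
        fit = fit_photobleach(RatioTrace(t, np.full(100, 1.7), "raw"))
        assert fit.decay_rate == pytest.approx(0.0, abs=1e-8)
        assert fit.amplitude == pytest.approx(1.7, rel=1e-6)
        assert fit.residual_rms == pytest.approx(0.0, abs=1e-6)

    def test_monte_carlo_rate_recovery(self):
        # 900 frames, noise 1% of amplitude: lambda back within 10%
        t = np.arange(900.0)
        true_lam = 1 / 300.0
        worst = 0.0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = 2.0 * np.exp(-true_lam * t) + rng.normal(0, 0.02, t.size)
            fit = fit_photobleach(RatioTrace(t, y, "raw"))
            worst = max(worst, abs(fit.decay_rate - true_lam) / true_lam)
        assert worst < 0.10

    def test_nonpositive_values_rejected(self):
        t = np.arange(10.0)
        with pytest.raises(PipelineError, match="positive"):
            fit_photobleach(RatioTrace(t, np.linspace(1, -0.1, 10), "raw"))

    def test_too_few_frames_rejected(self):
        with pytest.raises(PipelineError, match="5 frames"):
            fit_photobleach(RatioTrace(np.arange(4.0), np.ones(4), "raw"))


class TestBleachCorrection:
    def test_raw_equals_fit_gives_zero(self):
        t = np.arange(0.0, 200.0)
        raw = RatioTrace(t, 1.5 * np.exp(-t / 400), "raw")
        fit = fit_photobleach(raw)
        cor = correct_photobleach(raw, fit)
        np.testing.assert_allclose(cor.values, 0.0, atol=1e-9)
        assert cor.stage == "corrected"

    def test_scalar_scaling(self):
        t = np.arange(0.0, 200.0)
        base = 1.5 * np.exp(-t / 400)
        fit = fit_photobleach(RatioTrace(t, base, "raw"))
        cor = correct_photobleach(RatioTrace(t, 1.1 * base, "raw"), fit)
        np.testing.assert_allclose(cor.values, 0.1, atol=1e-8)

    def test_full_trace_fit_attenuates_boxcar_modestly_when_long(self):
        # 120 s boxcar of amplitude 0.10 centred in a 1500 s recording:
        # fitting straight through the response costs part of the
        # plateau, but the recovered level stays within 0.10 +/- 0.02
        t = np.arange(-750.0, 750.0, 0.5)
        box = ((t >= 0) & (t < 120)).astype(float)
        raw = RatioTrace(t, 2.0 * np.exp(-(t + 750) / 1200) * (1 + 0.10 * box), "raw")
        cor = correct_photobleach(raw, fit_photobleach(raw))
        plateau = cor.values[(t >= 10) & (t <= 110)].mean()
        assert plateau == pytest.approx(0.10, abs=0.02)


class TestBinning:
    def test_constant_trace(self):
        t = np.arange(-20.0, 40.0)
        b = bin_timecourse(RatioTrace(t, np.full(t.size, 0.3), "corrected"))
        np.testing.assert_allclose(b.means, 0.3)

    def test_linear_ramp_first_bin(self):
        t = np.arange(0.0, 30.0)  # 1 Hz
        b = bin_timecourse(RatioTrace(t, t.copy(), "corrected"))
        assert b.bin_edges[0] == 0.0
        assert b.means[0] == pytest.approx(4.5)  # mean of samples 0..9

    @pytest.mark.parametrize("rate", [2.0, 5.0, 10.0])
    def test_twelve_poststimulus_bins(self, rate):
        p = ImagingSimParams(duration_s=170.0, frame_rate_hz=rate,
                             stimulus_onset_s=40.0)
        rec, _ = gen_imaging_recording(p)
        res = CalciumResponseModel(rec).fit()
        post = res.binned.bin_edges[:-1][
            (res.binned.bin_edges[:-1] >= 0) & (res.binned.bin_edges[:-1] < 120)
        ]
        assert len(post) == 12

    def test_empty_trace_rejected(self):
        tr = RatioTrace(np.array([]), np.array([]), "corrected")
        with pytest.raises(PipelineError, match="empty"):
            bin_timecourse(tr)

    def test_cross_animal_average_weights_animals_equally(self):
        t_fast = np.arange(0.0, 20.0, 0.1)   # 200 frames
        t_slow = np.arange(0.0, 20.0, 1.0)   # 20 frames
        b1 = bin_timecourse(RatioTrace(t_fast, np.full(t_fast.size, 1.0), "corrected"))
        b2 = bin_timecourse(RatioTrace(t_slow, np.full(t_slow.size, 3.0), "corrected"))
        avg = average_binned([b1, b2])
        np.testing.assert_allclose(avg.means, 2.0)  # not frame-weighted
        np.testing.assert_array_equal(avg.counts, 2)


class TestSignedArea:
    def test_zero_trace(self):
        t = np.arange(0.0, 130.0)
        s = signed_area(RatioTrace(t, np.zeros(t.size), "corrected"))
        assert s.signed_area == 0.0

    def test_constant_rectangle(self):
        t = np.arange(0.0, 121.0)
        s = signed_area(RatioTrace(t, np.full(t.size, 0.05), "corrected"))
        assert s.signed_area == pytest.approx(6.0)

    def test_matches_oversampled_riemann_oracle(self):
        rng = np.random.default_rng(0)
        t = np.arange(-10.0, 130.0, 0.2)
        # random smooth trace: sum of a few sinusoids
        v = sum(
            a * np.sin(2 * np.pi * f * t + ph)
            for a, f, ph in zip(rng.uniform(0.01, 0.05, 4),
                                rng.uniform(0.002, 0.02, 4),
                                rng.uniform(0, 2 * np.pi, 4))
        )
        s = signed_area(RatioTrace(t, v, "corrected"))
        fine = np.linspace(0.0, 120.0, t.size * 100)
        riemann = np.sum(np.interp(fine, t, v)) * (fine[1] - fine[0])
        assert s.signed_area == pytest.approx(riemann, abs=1e-3)

    def test_negative_excursions_subtract(self):
        t = np.arange(0.0, 121.0)
        v = np.where(t < 60, 0.1, -0.1)
        s = signed_area(RatioTrace(t, v, "corrected"))
        assert abs(s.signed_area) < 0.11  # near-cancellation, not |area|

    def test_window_outside_span_rejected(self):
        t = np.arange(0.0, 50.0)
        with pytest.raises(PipelineError, match="span"):
            signed_area(RatioTrace(t, np.zeros(50), "corrected"), (0.0, 120.0))


class TestEndToEndRecovery:
    def test_noiseless_null_recovery_exact(self):
        p = ImagingSimParams(transient_amplitude=0.0, noise_sd=0.0)
        rec, _ = gen_imaging_recording(p)
        res = CalciumResponseModel(rec).fit()
        assert np.max(np.abs(res.delta_r.values)) < 1e-9
        assert abs(res.signed_area) < 1e-9

    @pytest.mark.parametrize("a", [0.05, 0.10, 0.15])
    def test_noiseless_transient_area_within_2pct(self, a):
        p = ImagingSimParams(transient_amplitude=a, noise_sd=0.0)
        rec, truth = gen_imaging_recording(p)
        res = CalciumResponseModel(rec).fit()
        assert res.signed_area == pytest.approx(truth.true_signed_area, rel=0.02)

    def test_area_strictly_increasing_in_amplitude(self):
        areas = []
        for a in np.linspace(0.02, 0.30, 8):
            rec, _ = gen_imaging_recording(
                ImagingSimParams(transient_amplitude=float(a), noise_sd=0.0)
            )
            areas.append(CalciumResponseModel(rec).fit().signed_area)
        assert np.all(np.diff(areas) > 0)

    def test_null_noisy_recordings_calibrated(self):
        # 100 transient-free noisy recordings: per-bin means and signed
        # areas centred on zero within 3 standard errors
        bins, areas = [], []
        for seed in range(100):
            p = ImagingSimParams(transient_amplitude=0.0, noise_sd=10.0, seed=seed)
            rec, _ = gen_imaging_recording(p)
            res = CalciumResponseModel(rec).fit()
            bins.append(res.binned.means)
            areas.append(res.signed_area)
        bins = np.array(bins)
        mean = bins.mean(axis=0)
        se = bins.std(axis=0, ddof=1) / np.sqrt(bins.shape[0])
        assert np.all(np.abs(mean) <= 3 * se)
        areas = np.array(areas)
        assert abs(areas.mean()) <= 3 * areas.std(ddof=1) / np.sqrt(areas.size)


class TestGroupComparison:
    def test_identical_groups_not_significant(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = compare_response_groups({"a": g, "b": [x + 1e-9 for x in g]})
        assert res.pairwise_p("a", "b") == pytest.approx(1.0, abs=1e-6)

    def test_power_familiar_vs_novel_separation(self):
        # familiar group mean 5 standard errors (of the group difference)
        # above novel groups: Tukey flags both familiar-vs-novel
        # contrasts in >= 95% of 200 draws
        rng = np.random.default_rng(2024)
        n, sd = 10, 1.0
        shift = 5 * sd * np.sqrt(2.0 / n)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            groups = {
                "HH": rng.normal(shift, sd, n),
                "DH": rng.normal(0.0, sd, n),
                "DD": rng.normal(shift, sd, n),
                "HD": rng.normal(0.0, sd, n),
            }
            res = compare_response_groups(groups)
            if (res.pairwise_p("HH", "DH") < 0.05
                    and res.pairwise_p("DD", "HD") < 0.05):
                hits += 1
        assert hits / n_rep >= 0.95

    def test_type_I_error_calibrated(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            groups = {k: rng.normal(0, 1, 10) for k in "abc"}
            if compare_response_groups(groups).p_overall < 0.05:
                rejections += 1
        assert abs(rejections / n_rep - 0.05) <= 0.02
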