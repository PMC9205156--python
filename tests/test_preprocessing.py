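"""Filtering, impact detection, and window arithmetic."""

import numpy as np
import pytest
from scipy import stats as sps

from strokefall.preprocessing import (
    WINDOW_FRAMES,
    DefectiveDataError,
    PreprocessingError,
    WindowInfeasibleError,
    bandpass_filter,
    bandpass_gain,
    detect_impact,
    exclude_defective,
    extract_fall_window,
    extract_nonfall_window,
    filter_recording,
    lead_frames,
    preprocess_dataset,
)
from strokefall.synthetic_data import (
    CHANNELS,
    EventAnnotation,
    IMURecording,
    generate_subject,
)

FS = 500


def _sine(freq, n=5000, fs=FS):
    return np.sin(2 * np.pi * freq * np.arange(n) / fs)


def _central(x, frac=0.8):
    n = len(x)
    k = int(n * (1 - frac) / 2)
    return x[k : n - k]


def _lockin_amplitude(x, freq, fs=FS, frac=0.8):
    """Amplitude of the ``freq`` component via quadrature projection over
    the central region; immune to the filter's slow edge transient."""
    c = _central(np.asarray(x, float), frac)
    t = np.arange(len(c)) / fs
    z = c * np.exp(-2j * np.pi * freq * t)
    return 2.0 * abs(z.mean())


class TestBandpassFilter:
    def test_dc_rejection(self):
        out = bandpass_filter(np.ones(5000))
        assert abs(_central(out).mean()) < 1e-3

    def test_passband_gain_at_10hz(self):
        out = bandpass_filter(_sine(10.0))
        amp = _lockin_amplitude(out, 10.0)
        expected = bandpass_gain(10.0)
        assert amp == pytest.approx(expected, rel=1e-2)
        assert expected == pytest.approx(1.0, abs=1e-3)

    def test_stopband_gain_at_120hz(self):
        # longer signal: the stopband residual is ~2e-4, so the edge
        # transient must decay well below that before the measured region
        out = bandpass_filter(_sine(120.0, n=30000))
        amp = _lockin_amplitude(out, 120.0, frac=0.4)
        assert amp <= bandpass_gain(120.0) * 1.05
        assert bandpass_gain(120.0) < 1e-3

    def test_length_preserved_and_idempotent_on_band_limited(self):
        x = _sine(5.0)
        once = bandpass_filter(x)
        twice = bandpass_filter(once)
        assert len(once) == len(x)
        assert _lockin_amplitude(twice, 5.0) == pytest.approx(
            _lockin_amplitude(once, 5.0), rel=1e-2
        )

    def test_short_series_rejected(self):
        with pytest.raises(PreprocessingError, match="warm-up"):
            bandpass_filter(np.ones(10))

    def test_nonfinite_rejected(self):
        x = np.ones(1000)
        x[3] = np.nan
        with pytest.raises(PreprocessingError, match="non-finite"):
            bandpass_filter(x)


def _recording_with_spikes(spikes, n=6000):
    """Quiet 1 g recording with one-frame accel spikes at given (frame, g)."""
    data = np.zeros((n, len(CHANNELS)))
    zcols = [CHANNELS.index(f"{loc}_acc_z") for loc in ("lhip", "rhip", "back")]
    data[:, zcols] = 1.0
    for frame, peak in spikes:
        data[frame, CHANNELS.index("back_acc_x")] = peak
    return IMURecording("t1", data)


def _fall_ann(start, end, impact):
    return EventAnnotation(
        "t1_e000", "t1", "fall", "lateral_fall",
        region_start_frame=start, region_end_frame=end, true_impact_frame=impact,
    )


class TestDetectImpact:
    def test_single_spike_found(self):
        rec = _recording_with_spikes([(3000, 8.0)])
        assert detect_impact(rec, _fall_ann(2000, 4000, 3000)) == 3000

    def test_tie_breaks_to_earliest(self):
        rec = _recording_with_spikes([(2100, 8.0), (3200, 8.0)])
        assert detect_impact(rec, _fall_ann(2000, 4000, 2100)) == 2100

    def test_nonfall_rejected(self):
        rec = _recording_with_spikes([(3000, 8.0)])
        ann = EventAnnotation("e", "t1", "non_fall", "adl", adl_kind="walk",
                              region_start_frame=0, region_end_frame=100)
        with pytest.raises(PreprocessingError):
            detect_impact(rec, ann)

    def test_all_missing_region_is_defect(self):
        rec = _recording_with_spikes([(3000, 8.0)])
        rec.data[2000:4000, :] = np.nan
        with pytest.raises(DefectiveDataError):
            detect_impact(rec, _fall_ann(2000, 4000, 3000))

    def test_recovers_generator_ground_truth(self, stroke_profile):
        """Detected impact within 50 ms of truth for >= 95% of 100 falls."""
        hits = 0
        for seed in range(50):
            rec, anns = generate_subject(stroke_profile, ["lateral_fall", "ap_fall"], seed=seed)
            filtered = filter_recording(rec)
            for ann in anns:
                t_p = detect_impact(filtered, ann)
                hits += abs(t_p - ann.true_impact_frame) <= 25
        assert hits >= 95


class TestWindowArithmetic:
    def test_window_is_500ms(self):
        assert WINDOW_FRAMES == 250
        assert WINDOW_FRAMES / FS == 0.5

    def test_75ms_lead_rounds_up_to_38_frames(self):
        assert lead_frames(75.0) == 38

    @pytest.mark.parametrize(
        "t_p,lead,expected",
        [(5000, 100.0, (4700, 4950)), (5000, 0.0, (4750, 5000))],
    )
    def test_fall_window_equations(self, t_p, lead, expected):
        rec = _recording_with_spikes([(t_p, 8.0)], n=5500)
        w = extract_fall_window(rec, _fall_ann(4000, 5400, t_p), t_p, lead)
        assert (w.start_frame, w.end_frame) == expected
        assert w.data.shape == (250, 18)

    def test_infeasible_window_excluded(self):
        rec = _recording_with_spikes([(200, 8.0)], n=1000)
        with pytest.raises(WindowInfeasibleError):
            extract_fall_window(rec, _fall_ann(0, 900, 200), 200, 75.0)

    def test_longer_lead_shifts_window_strictly_earlier(self):
        rec = _recording_with_spikes([(5000, 8.0)], n=5500)
        ann = _fall_ann(4000, 5400, 5000)
        ends = [extract_fall_window(rec, ann, 5000, t_l).end_frame
                for t_l in (50, 100, 150, 300)]
        assert all(a > b for a, b in zip(ends, ends[1:]))


def _nonfall_ann(start, end):
    return EventAnnotation(
        "t1_e001", "t1", "non_fall", "adl", adl_kind="walk",
        region_start_frame=start, region_end_frame=end,
    )


class TestNonfallWindow:
    def test_latter_half_placement(self):
        rec = _recording_with_spikes([], n=1200)
        for seed in range(20):
            w = extract_nonfall_window(rec, _nonfall_ann(0, 1000), seed)
            assert 500 <= w.end_frame <= 1000
            assert w.end_frame - w.start_frame == 250

    def test_degenerate_region_clips_to_start(self):
        rec = _recording_with_spikes([], n=1200)
        w = extract_nonfall_window(rec, _nonfall_ann(0, 250), seed=0)
        assert (w.start_frame, w.end_frame) == (0, 250)

    def test_too_short_region_rejected(self):
        rec = _recording_with_spikes([], n=1200)
        with pytest.raises(WindowInfeasibleError):
            extract_nonfall_window(rec, _nonfall_ann(0, 200), seed=0)

    def test_end_frame_uniform_over_latter_half(self):
        rec = _recording_with_spikes([], n=1200)
        rng = np.random.default_rng(123)
        ends = np.array(
            [extract_nonfall_window(rec, _nonfall_ann(0, 1000), rng).end_frame
             for _ in range(10_000)]
        )
        assert ends.min() >= 500 and ends.max() <= 1000
        # chi-square goodness of fit against the uniform sampler, 10 bins
        observed, _ = np.histogram(ends, bins=10, range=(500, 1001))
        p = sps.chisquare(observed).pvalue
        assert p > 1e-3


class TestExcludeDefective:
    def test_no_defects_identity(self):
        anns = [_nonfall_ann(0, 300), _nonfall_ann(400, 700)]
        kept, n = exclude_defective(anns)
        assert kept == anns and n == 0

    def test_flagged_removed(self):
        anns = [_nonfall_ann(0, 300) for _ in range(10)]
        for a in anns[:3]:
            a.defective = True
        kept, n = exclude_defective(anns)
        assert len(kept) == 7 and n == 3

    def test_missingness_outside_window_retained(self):
        """NaN in the region but outside the selected window keeps the event."""
        from strokefall.feature_extraction import build_feature_matrix
        from strokefall.synthetic_data import Dataset, SubjectProfile

        rec = _recording_with_spikes([], n=1200)
        rec.data[0:100, 0] = np.nan  # first half of region; windows draw from latter half
        ds = Dataset(
            [SubjectProfile("t1", "control", "stable", 1.0)],
            {"t1": rec},
            [_nonfall_ann(0, 1000)],
        )
        df = build_feature_matrix(ds, 75.0, "both", seed=0)
        assert len(df) == 1


class TestPreprocessDataset:
    def test_defective_events_never_reach_features(self, small_dataset):
        from strokefall.feature_extraction import build_feature_matrix
        from strokefall.synthetic_data import inject_defects

        damaged = inject_defects(small_dataset, 0.15, seed=5)
        flagged = {a.event_id for a in damaged.annotations if a.defective}
        df = build_feature_matrix(damaged, 75.0, "both", seed=5)
        assert flagged and not (set(df["event_id"]) & flagged)

    def test_row_count_conserved_against_exclusion_log(self, small_dataset):
        from strokefall.feature_extraction import build_feature_matrix

        df = build_feature_matrix(small_dataset, 75.0, "both", seed=11)
        n_excluded = len(df.attrs["exclusions"])
        assert len(df) + n_excluded == len(small_dataset.annotations)
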