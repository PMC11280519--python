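import numpy as np
import pytest

from lorenzaf.detector import detect_series
from lorenzaf.rr import segment_windows
from lorenzaf.synthetic import (
    RR_CLIP_MS,
    RhythmSpec,
    gen_af_rr,
    gen_ecg,
    gen_nsr_rr,
    gen_record,
    insert_pac,
)


class TestNSRGenerator:
    def test_zero_sdnn_is_constant(self):
        s = gen_nsr_rr(800, 0.0, 0.9, 60, seed=1)
        assert np.all(s.intervals == 800.0)

    def test_same_seed_same_series(self):
        a = gen_nsr_rr(800, 30, 0.9, 120, seed=42)
        b = gen_nsr_rr(800, 30, 0.9, 120, seed=42)
        assert np.array_equal(a.intervals, b.intervals)
        assert np.array_equal(a.beat_times, b.beat_times)

    def test_low_dispersion_stays_in_origin_region(self):
        s = gen_nsr_rr(800, 25, 0.9, 300, seed=7)
        d = np.diff(s.intervals)
        assert np.mean(np.abs(d) <= 80) > 0.99

    def test_classified_nsr(self, builtin_mask):
        s = gen_nsr_rr(800, 30, 0.9, 120, seed=1)
        assert detect_series(s, builtin_mask)[0].verdict == "NSR"

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            gen_nsr_rr(-5, 30, 0.9, 60, seed=0)
        with pytest.raises(ValueError):
            gen_nsr_rr(800, 30, 1.0, 60, seed=0)


class TestAFGenerator:
    def test_classified_af(self, builtin_mask):
        s = gen_af_rr(800, 400, 120, seed=1)
        assert detect_series(s, builtin_mask)[0].verdict == "AF"

    def test_tiny_spread_classified_nsr(self, builtin_mask):
        s = gen_af_rr(800, 1.0, 120, seed=1)
        assert detect_series(s, builtin_mask)[0].verdict == "NSR"

    def test_same_seed_same_series(self):
        a = gen_af_rr(800, 400, 120, seed=9)
        b = gen_af_rr(800, 400, 120, seed=9)
        assert np.array_equal(a.intervals, b.intervals)

    def test_clipping_and_support(self):
        s = gen_af_rr(800, 700, 300, seed=2)
        assert s.intervals.min() >= RR_CLIP_MS[0]
        assert s.intervals.max() <= RR_CLIP_MS[1]
        with pytest.raises(ValueError):
            gen_af_rr(800, 0.0, 60, seed=0)


class TestPAC:
    def test_compensatory_pause_arithmetic(self):
        s = gen_nsr_rr(800, 0.0, 0.0, 20, seed=0)
        out = insert_pac(s, 5, prematurity_c=0.7)
        assert out.intervals[5] == pytest.approx(560.0)
        assert out.intervals[6] == pytest.approx(1040.0)
        # local two-beat sum and all later beat times preserved
        assert out.intervals[5] + out.intervals[6] == pytest.approx(1600.0)
        assert np.allclose(out.beat_times[6:], s.beat_times[6:])

    def test_prematurity_near_one_is_identity_limit(self):
        s = gen_nsr_rr(800, 0.0, 0.0, 20, seed=0)
        out = insert_pac(s, 5, prematurity_c=0.999)
        assert np.allclose(out.intervals, s.intervals, atol=1.0)

    def test_boundary_index_rejected(self):
        s = gen_nsr_rr(800, 0.0, 0.0, 20, seed=0)
        with pytest.raises(IndexError):
            insert_pac(s, len(s) - 1, 0.7)
        with pytest.raises(ValueError):
            insert_pac(s, 5, 1.5)

    def test_pacs_raise_pac_evidence_but_not_verdict(self, builtin_mask):
        base = gen_nsr_rr(800, 20, 0.9, 120, seed=2)
        s = base
        for k in range(10, len(base) - 2, 14):  # ~10 PACs in 2 min
            s = insert_pac(s, k, 0.7)
        wc = detect_series(s, builtin_mask)[0]
        assert wc.indices.pac_evidence > 0
        assert wc.verdict == "NSR"


class TestECG:
    def test_three_beats_three_r_peaks(self):
        s = gen_nsr_rr(800, 0.0, 0.0, 2.4, seed=0)
        assert len(s) == 3
        ecg = gen_ecg(s, fs=250, noise_sd=0.0)
        x = ecg.samples
        peaks = [i for i in range(1, len(x) - 1)
                 if x[i] > x[i - 1] and x[i] >= x[i + 1] and x[i] > 0.5]
        assert len(peaks) == 3

    def test_same_seed_same_samples(self):
        s = gen_nsr_rr(800, 30, 0.9, 10, seed=3)
        a = gen_ecg(s, fs=250, noise_sd=0.05, seed=11)
        b = gen_ecg(s, fs=250, noise_sd=0.05, seed=11)
        assert np.array_equal(a.samples, b.samples)

    def test_round_trip_through_beat_detector(self):
        from lorenzaf.beats import detect_rpeaks

        s = gen_nsr_rr(850, 20, 0.8, 60, seed=4)
        det = detect_rpeaks(gen_ecg(s, fs=250))
        for t in det.beat_times:
            assert np.min(np.abs(s.beat_times - t)) <= 0.008


class TestRecordGenerator:
    def test_annotation_matches_segment_boundaries(self):
        spec = RhythmSpec(segments=(("NSR", 600.0, {}), ("AF", 600.0, {})), seed=5)
        series, ann, ecg = gen_record(spec)
        assert ecg is None
        assert ann.intervals == ((0.0, 600.0, "N"), (600.0, 1200.0, "AFIB"))

    def test_total_duration_within_one_mean_rr(self):
        spec = RhythmSpec(segments=(("NSR", 300.0, {}), ("AF", 300.0, {})), seed=6)
        series, ann, _ = gen_record(spec)
        assert abs(series.duration_s - 600.0) <= 2.0  # one (clipped) RR

    def test_every_beat_inside_exactly_one_annotated_interval(self):
        spec = RhythmSpec(
            segments=(("NSR", 240.0, {}), ("AF", 240.0, {}), ("PAC", 240.0, {})),
            seed=7,
        )
        series, ann, _ = gen_record(spec)
        for t in series.beat_times:
            hits = [lab for a, b, lab in ann.intervals if a <= t < b]
            if t < ann.end_s:
                assert len(hits) == 1

    def test_mixed_record_confusion_diagonal_dominates(self, builtin_mask):
        from lorenzaf.evaluation import confusion, label_windows

        spec = RhythmSpec(
            segments=(("NSR", 1200.0, {}), ("AF", 1200.0, {})), seed=8,
            record_id="mix",
        )
        series, ann, _ = gen_record(spec)
        results = detect_series(series, builtin_mask)
        determined = [wc for wc in results if wc.verdict != "undetermined"]
        truths = label_windows([wc.window for wc in determined], ann)
        c = confusion([wc.verdict for wc in determined], truths)
        assert c.tp + c.tn > 4 * (c.fp + c.fn)

    def test_determinism_and_validation(self):
        spec = RhythmSpec(segments=(("AF", 120.0, {}),), seed=9)
        a, _, _ = gen_record(spec)
        b, _, _ = gen_record(spec)
        assert np.array_equal(a.intervals, b.intervals)
        with pytest.raises(ValueError):
            RhythmSpec(segments=(("VF", 120.0, {}),), seed=0)
        with pytest.raises(ValueError):
            RhythmSpec(segments=(("AF", -5.0, {}),), seed=0)
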