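import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lorenzaf.detector import (
    GRID_BINS,
    DetectorConfig,
    InsufficientDataError,
    LorenzGrid,
    MaskError,
    SegmentMask,
    af_evidence,
    af_indices,
    build_default_mask,
    build_histogram,
    classify_window,
    detect_series,
    irregularity_evidence,
    load_segment_mask,
    pac_evidence,
    region_counts,
    write_mask,
)
from lorenzaf.rr import RRSeries, compute_delta_rr, segment_windows
from lorenzaf.synthetic import gen_af_rr, gen_nsr_rr

from conftest import naive_af_indices


def grid_with(points, bin_width=40.0):
    counts = np.zeros((GRID_BINS, GRID_BINS), dtype=np.int64)
    for iy, ix, c in points:
        counts[iy, ix] = c
    return LorenzGrid(counts=counts, bin_width_ms=bin_width)


class TestHistogram:
    def test_origin_pair(self):
        g = build_histogram(np.array([0.0, 0.0]))
        assert g.counts[15, 15] == 1 and g.total == 1

    def test_two_point_binning(self):
        # pairs: (x=400, y=-200) and (x=-200, y=400)
        g = build_histogram(np.array([-200.0, 400.0, -200.0]), bin_width_ms=40)
        assert g.counts[10, 25] == 1  # y bin 10, x bin 25
        assert g.counts[25, 10] == 1
        assert g.total == 2

    def test_saturation_into_corner(self):
        g = build_histogram(np.array([10000.0, 10000.0]))
        assert g.counts[30, 30] == 1

    def test_dropping_when_not_saturating(self):
        g = build_histogram(np.array([10000.0, 10000.0, 0.0]), saturate=False)
        assert g.total == 0  # both pairs have an out-of-range coordinate

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            build_histogram(np.array([5.0]))

    @given(st.lists(st.floats(min_value=-700, max_value=700), min_size=2, max_size=200))
    @settings(deadline=None, max_examples=50)
    def test_point_conservation(self, deltas):
        g = build_histogram(np.array(deltas))
        assert g.total == len(deltas) - 1


class TestRegionCounts:
    def test_empty_grid(self, builtin_mask):
        bc, pc = region_counts(grid_with([]), builtin_mask)
        assert bc.sum() == 0 and pc.sum() == 0

    def test_repeat_visits_to_one_bin(self, builtin_mask):
        # (iy=15, ix=10) has center x=-200, y=0 -> region 6 (near-west)
        assert builtin_mask.labels[15, 10] == 6
        bc, pc = region_counts(grid_with([(15, 10, 2)]), builtin_mask)
        assert pc[6] == 2 and bc[6] == 1

    def test_distinct_bins_in_one_region(self, builtin_mask):
        pts = [(20, 20, 1), (21, 25, 1), (25, 21, 1)]  # three quadrant-1 bins
        assert all(builtin_mask.labels[iy, ix] == 1 for iy, ix, _ in pts)
        bc, pc = region_counts(grid_with(pts), builtin_mask)
        assert pc[1] == 3 and bc[1] == 3

    def test_shape_mismatch(self, builtin_mask):
        bad = LorenzGrid(np.zeros((31, 31), dtype=int))
        object.__setattr__(bad, "counts", np.zeros((30, 31), dtype=np.int64))
        with pytest.raises(MaskError):
            region_counts(bad, builtin_mask)


class TestEvidenceIndices:
    def test_all_points_at_origin_no_irregularity(self, builtin_mask):
        bc, pc = region_counts(grid_with([(15, 15, 7)]), builtin_mask)
        assert irregularity_evidence(bc) == 0

    def test_irregularity_counts_distinct_nonorigin_bins(self, builtin_mask):
        pts = [(0, 0, 5), (30, 30, 2), (15, 25, 1)]
        bc, _ = region_counts(grid_with(pts), builtin_mask)
        assert irregularity_evidence(bc) == 3

    def test_pac_sign_conventions(self, builtin_mask):
        # 2 points in one near-west (region 6) bin -> +1
        bc, pc = region_counts(grid_with([(15, 10, 2)]), builtin_mask)
        assert pac_evidence(bc, pc) == 1
        # 2 points in one near-east (region 8) bin -> -1
        assert builtin_mask.labels[15, 20] == 8
        bc, pc = region_counts(grid_with([(15, 20, 2)]), builtin_mask)
        assert pac_evidence(bc, pc) == -1
        # empty grid -> 0
        bc, pc = region_counts(grid_with([]), builtin_mask)
        assert pac_evidence(bc, pc) == 0

    def test_af_evidence_arithmetic(self):
        assert af_evidence(60, 5, 2) == 51
        assert af_evidence(0, 148, 0) == -148

    def test_adding_an_origin_point_lowers_af_evidence_by_one(self, builtin_mask):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 3, size=(31, 31))
        g1 = LorenzGrid(counts)
        counts2 = counts.copy()
        counts2[15, 15] += 1
        g2 = LorenzGrid(counts2)
        i1, i2 = af_indices(g1, builtin_mask), af_indices(g2, builtin_mask)
        assert i2.af_evidence == i1.af_evidence - 1
        assert i2.irregularity_evidence == i1.irregularity_evidence
        assert i2.pac_evidence == i1.pac_evidence

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=30)
    def test_matches_naive_two_loop_reference(self, seed, builtin_mask):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 200))
        deltas = rng.uniform(-800, 800, size=n)
        g = build_histogram(deltas)
        idx = af_indices(g, builtin_mask)
        irr, pac, origin, afe, bc, pc = naive_af_indices(
            deltas.tolist(), builtin_mask.labels.tolist()
        )
        assert (idx.irregularity_evidence, idx.pac_evidence,
                idx.origin_count, idx.af_evidence) == (irr, pac, origin, afe)
        assert idx.bin_count.tolist() == bc
        assert idx.point_count.tolist() == pc


class TestClassification:
    def test_constant_rr_window_is_nsr(self, constant_rr_window, builtin_mask):
        ws = segment_windows(constant_rr_window, 120.0)
        wc = classify_window(constant_rr_window, ws[0], builtin_mask)
        assert wc.verdict == "NSR"
        assert wc.indices.af_evidence == -148

    def test_tie_at_threshold_is_af(self, builtin_mask):
        # seed frozen by prior search: this window scores AFEvidence == 50
        s = gen_af_rr(800, 180, 120, seed=82)
        wc = classify_window(s, segment_windows(s, 120.0)[0], builtin_mask)
        assert wc.indices.af_evidence == 50
        assert wc.verdict == "AF"
        # one unit below the threshold flips the verdict
        cfg = DetectorConfig(af_threshold=51)
        wc2 = classify_window(s, segment_windows(s, 120.0)[0], builtin_mask, cfg)
        assert wc2.verdict == "NSR"

    def test_sparse_window_undetermined(self, builtin_mask):
        s = RRSeries.from_intervals(np.array([800.0, 810.0, 790.0]))
        wc = classify_window(s, segment_windows(s, 120.0)[0], builtin_mask)
        assert wc.verdict == "undetermined" and wc.indices is None

    def test_detection_stateless_across_windows(self, builtin_mask):
        nsr = gen_nsr_rr(800, 30, 0.9, 360, seed=3)
        full = detect_series(nsr, builtin_mask)
        # classifying any window in isolation matches the batch result
        ws = segment_windows(nsr, 120.0)
        for k in (2, 0, 1):
            wc = classify_window(nsr, ws[k], builtin_mask)
            assert wc.verdict == full[k].verdict

    def test_af_and_nsr_generators_separate(self, builtin_mask):
        af = gen_af_rr(800, 400, 120, seed=1)
        nsr = gen_nsr_rr(800, 30, 0.9, 120, seed=1)
        assert detect_series(af, builtin_mask)[0].verdict == "AF"
        assert detect_series(nsr, builtin_mask)[0].verdict == "NSR"


class TestSegmentMask:
    def test_builtin_origin_region_is_5x5_block(self, builtin_mask):
        assert int((builtin_mask.labels == 0).sum()) == 25
        block = builtin_mask.labels[13:18, 13:18]
        assert (block == 0).all()
        assert int(builtin_mask.labels.size) == 961

    def test_builtin_matches_programmatic_geometry(self, builtin_mask):
        assert np.array_equal(builtin_mask.labels, build_default_mask().labels)

    def test_wrong_shape_rejected(self, tmp_path):
        p = tmp_path / "mask.txt"
        p.write_text("\n".join(" ".join("0" for _ in range(31)) for _ in range(32)))
        with pytest.raises(MaskError, match="31x31"):
            load_segment_mask(p)

    def test_label_out_of_range_rejected(self, tmp_path, builtin_mask):
        labels = builtin_mask.labels.copy()
        labels[0, 0] = 13
        p = tmp_path / "mask.txt"
        p.write_text("\n".join(" ".join(str(v) for v in row) for row in labels))
        with pytest.raises(MaskError, match="0..12"):
            load_segment_mask(p)

    def test_bad_origin_geometry_rejected(self, tmp_path, builtin_mask):
        labels = builtin_mask.labels.copy()
        labels[15, 15] = 5  # carve a hole in region 0
        p = tmp_path / "mask.txt"
        p.write_text("\n".join(" ".join(str(v) for v in row) for row in labels))
        with pytest.raises(MaskError, match="region-0"):
            load_segment_mask(p)

    def test_mask_file_round_trip(self, tmp_path, builtin_mask):
        p = tmp_path / "mask.txt"
        write_mask(builtin_mask, p)
        back = load_segment_mask(p)
        assert np.array_equal(back.labels, builtin_mask.labels)

    def test_irregularity_bounded_by_nonorigin_bins(self, builtin_mask):
        rng = np.random.default_rng(0)
        g = LorenzGrid(rng.integers(0, 5, size=(31, 31)))
        idx = af_indices(g, builtin_mask)
        assert idx.irregularity_evidence <= 961 - 25
        assert int(idx.point_count.sum()) == g.total
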