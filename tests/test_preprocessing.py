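"""Segmentation, the artifact/purity filters, and the text adapters."""
import numpy as np
import pandas as pd
import pytest

from hrvaf import preprocessing as pre
from hrvaf import synthetic as syn
from hrvaf.types import RRRecording


def make_rec(rr, rhythm="SR", beats=None):
    rr = np.asarray(rr, dtype=float)
    n = len(rr)
    rhythm = np.full(n, rhythm, dtype=object) if isinstance(rhythm, str) \
        else np.asarray(rhythm, dtype=object)
    beats = np.full(n, "sinus", dtype=object) if beats is None \
        else np.asarray(beats, dtype=object)
    return RRRecording("P1", "db", rr, beats, rhythm)


class TestSegmentation:
    def test_constant_sr_recording_tiles_into_75_beat_windows(self):
        rec = make_rec([800.0] * 750)  # 10 minutes
        segs, qc = pre.segment_recording(rec)
        assert len(segs) == 10
        assert all(len(s) == 75 for s in segs)
        assert all(s.removed_ms_total == 0 for s in segs)
        assert all(s.rhythm_class == "SR" for s in segs)

    def test_single_long_interval_removed_but_window_kept(self):
        rr = [800.0] * 35 + [3500.0] + [800.0] * 35 + [900.0] * 4 + [800.0] * 75
        rec = make_rec(rr)
        segs, qc = pre.segment_recording(rec)
        first = segs[0]
        assert first.n_removed == 1
        assert first.removed_ms_total == 3500.0
        assert np.all(first.rr_ms <= 3000.0)

    def test_removed_six_seconds_discards_window_inclusively(self):
        # removed durations sum to exactly 6000 ms -> "at least 10%" -> drop
        rr = [200.0] * 30 + [800.0] * 30 + [3000.0] * 10
        assert sum(rr) == 60000.0
        segs, qc = pre.segment_recording(make_rec(rr))
        assert len(segs) == 0
        assert qc.discarded["artifact_excess"] == 1

    def test_mixed_rhythm_window_excluded(self):
        rhythm = ["SR"] * 40 + ["AF"] * 35
        segs, qc = pre.segment_recording(make_rec([800.0] * 75, rhythm))
        assert segs == [] and qc.discarded["mixed_rhythm"] == 1

    def test_empty_recording_gives_empty_output(self):
        segs, qc = pre.segment_recording(None)
        assert segs == [] and qc.n_windows == 0

    def test_adjacency_marks_removal_gaps(self):
        rr = [800.0] * 30 + [100.0] + [800.0] * 45
        segs, _ = pre.segment_recording(make_rec(rr))
        s = segs[0]
        assert len(s.adjacency) == len(s) - 1
        assert int((~s.adjacency).sum()) == 1  # one gap where the artifact sat

    def test_window_tiling_is_a_partition(self, small_cohort):
        """Every interval lands in exactly one window (counted via QC)."""
        cfg = pre.SegmentationConfig()
        for rec in small_cohort["recordings"][:6]:
            ends = np.cumsum(rec.rr_ms)
            starts = ends - rec.rr_ms
            widx = np.floor(starts / (cfg.window_s * 1000)).astype(int)
            # by construction each start maps to exactly one window index
            assert len(widx) == len(rec)
            assert np.all(np.diff(widx) >= 0)

    def test_loosening_bounds_never_loses_segments(self, small_cohort):
        strict = pre.SegmentationConfig()
        loose = pre.SegmentationConfig(rr_min_ms=1.0, rr_max_ms=1e9,
                                       max_removed_fraction=0.999)
        for rec in small_cohort["recordings"]:
            n_strict = len(pre.segment_recording(rec, strict)[0])
            n_loose = len(pre.segment_recording(rec, loose)[0])
            assert n_loose >= n_strict

    def test_no_emitted_segment_mixes_rhythms_or_keeps_outliers(self, small_cohort):
        for s in small_cohort["segments"]:
            assert np.all((s.rr_ms >= 240.0) & (s.rr_ms <= 3000.0))


class TestSummarizeFiltering:
    def test_fixture_counts(self):
        fixtures = syn.make_filter_fixtures()
        qcs = [pre.segment_recording(fx.recording)[1] for fx in fixtures]
        table = pre.summarize_filtering(qcs)
        # totals: pure windows regardless of artifact outcome
        assert table.loc["all", "SR_total"] == 4   # pure_sr(2) + light + heavy
        assert table.loc["all", "SR_filtered"] == 3  # heavy one dropped
        assert table.loc["all", "AF_total"] == 1
        assert table.loc["all", "AF_filtered"] == 1

    def test_empty_input_gives_zero_table(self):
        table = pre.summarize_filtering([])
        assert (table.to_numpy() == 0).all()

    def test_disabled_filters_make_total_equal_filtered(self, small_cohort):
        cfg = pre.SegmentationConfig(rr_min_ms=1.0, rr_max_ms=1e9,
                                     max_removed_fraction=0.999,
                                     min_retained_intervals=2)
        qcs = [pre.segment_recording(r, cfg)[1] for r in small_cohort["recordings"]]
        t = pre.summarize_filtering(qcs)
        assert (t["AF_total"] == t["AF_filtered"]).all()
        assert (t["SR_total"] == t["SR_filtered"]).all()

    def test_split_mapping_buckets_rows(self, small_cohort):
        qcs = small_cohort["qcs"]
        ids = [qc.patient_id for qc in qcs]
        mapping = {pid: ("Training" if i % 2 else "Test") for i, pid in enumerate(ids)}
        t = pre.summarize_filtering(qcs, mapping)
        assert set(t.index) <= {"Training", "Test"}
        total_all = pre.summarize_filtering(qcs).loc["all"].sum()
        assert t.to_numpy().sum() == total_all


class TestAnnotationAdapter:
    def test_two_beats_make_one_interval(self, tmp_path):
        p = tmp_path / "rec.ann"
        p.write_text("0.0\t+\t(N\n0.0\tN\n0.800\tN\n")
        rec = pre.read_rr_annotation_text(p)
        assert len(rec) == 1
        assert rec.rr_ms[0] == pytest.approx(800.0)
        assert rec.rhythm_label[0] == "SR"

    def test_rhythm_change_forwards_labels(self, tmp_path):
        p = tmp_path / "rec.ann"
        lines = ["0.0\t+\t(N"] + [f"{0.8 * i}\tN" for i in range(5)] \
            + ["3.2\t+\t(AFIB"] + [f"{3.2 + 0.6 * i}\tN" for i in range(1, 4)]
        p.write_text("\n".join(lines) + "\n")
        rec = pre.read_rr_annotation_text(p)
        assert list(rec.rhythm_label) == ["SR"] * 4 + ["AF"] * 3

    def test_unknown_rhythm_maps_to_other(self, tmp_path, caplog):
        p = tmp_path / "rec.ann"
        p.write_text("0.0\t+\t(WEIRD\n0.0\tN\n0.8\tN\n")
        rec = pre.read_rr_annotation_text(p)
        assert rec.rhythm_label[0] == "other"

    def test_missing_file_raises_named_error(self, tmp_path):
        with pytest.raises(IOError, match="nope.ann"):
            pre.read_rr_annotation_text(tmp_path / "nope.ann")

    def test_write_read_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        rr = rng.integers(500, 1200, 50).astype(float)  # integer ms: exact sums
        rhythm = np.array(["SR"] * 25 + ["AF"] * 25, dtype=object)
        beats = np.array(["sinus"] * 48 + ["ventricular", "artifact"], dtype=object)
        rec = RRRecording("rt", "db", rr, beats, rhythm)
        path = pre.write_rr_annotation_text(rec, tmp_path / "rt.ann")
        back = pre.read_rr_annotation_text(path)
        np.testing.assert_allclose(back.rr_ms, rec.rr_ms, rtol=0, atol=1e-9)
        np.testing.assert_array_equal(back.rhythm_label, rec.rhythm_label)
        np.testing.assert_array_equal(back.beat_label, rec.beat_label)


class TestSegmentIO:
    def test_segments_roundtrip(self, small_cohort, tmp_path):
        segs = small_cohort["segments"][:10]
        path = pre.write_segments(segs, tmp_path / "segs.csv")
        back = pre.read_segments(path)
        assert len(back) == len(segs)
        for a, b in zip(segs, back):
            np.testing.assert_array_equal(a.rr_ms, b.rr_ms)
            np.testing.assert_array_equal(a.adjacency, b.adjacency)
            assert a.rhythm_class == b.rhythm_class
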