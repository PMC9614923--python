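"""The headless marking workflow: clicks, navigation, resume, merge."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antmark import mot_io, session, synthetic
from antmark.errors import FormatError, IntegrityError, RangeError
from antmark.mot_io import GROUND_TRUTH
from antmark.session import ClickEvent


def _session(image_set_dir, tmp_path, object_id=1, start_frame=0, **kw):
    d = image_set_dir(**kw)
    return session.start_session(d, tmp_path / "out", object_id, start_frame), d


class TestStartSession:
    def test_start_frame_zero_means_first_frame(self, image_set_dir, tmp_path):
        s, _ = _session(image_set_dir, tmp_path)
        assert s.current_frame == 1
        assert s.reference_point is None
        assert s.box_size == 16

    def test_resume_loads_saved_marks(self, image_set_dir, tmp_path):
        d = image_set_dir(n_frames=12)
        s = session.start_session(d, tmp_path / "out", 1)
        for f in range(1, 6):
            s.mark_center(ClickEvent(f, 10.0 + f, 20.0))
            s.advance()
        resumed = session.start_session(d, tmp_path / "out", 1, start_frame=6)
        assert len(resumed.marks) == 5
        assert resumed.current_frame == 6
        assert resumed.reference_point == pytest.approx((15.0, 20.0))

    def test_start_frame_beyond_sequence_is_range_error(self, image_set_dir, tmp_path):
        d = image_set_dir(n_frames=12)
        with pytest.raises(RangeError):
            session.start_session(d, tmp_path / "out", 1, start_frame=400)

    def test_unparsable_image_set_name_is_format_error(self, tmp_path):
        d = tmp_path / "NotAnImageSet"
        (d / "img").mkdir(parents=True)
        with pytest.raises(FormatError):
            session.start_session(d, tmp_path / "out", 1)


class TestMarkCenter:
    def test_click_centres_box(self, image_set_dir, tmp_path):
        d = image_set_dir(box_size=94, size=(256, 256))
        s = session.start_session(d, tmp_path / "out", 1)
        rec = s.mark_center(ClickEvent(1, 100.0, 100.0))
        assert (rec.left, rec.top, rec.width, rec.height) == (53, 53, 94, 94)

    def test_odd_box_size_rounds_half_away(self, image_set_dir, tmp_path):
        d = image_set_dir(box_size=95, size=(256, 256))
        s = session.start_session(d, tmp_path / "out", 1)
        rec = s.mark_center(ClickEvent(1, 100.0, 100.0))
        assert (rec.left, rec.top) == (53, 53)

    def test_edge_click_yields_negative_corner(self, image_set_dir, tmp_path):
        d = image_set_dir(box_size=94, size=(256, 256))
        s = session.start_session(d, tmp_path / "out", 1)
        rec = s.mark_center(ClickEvent(1, 40.0, 40.0))
        assert (rec.left, rec.top) == (-7, -7)

    def test_second_click_replaces_first(self, image_set_dir, tmp_path):
        s, _ = _session(image_set_dir, tmp_path)
        for _ in range(6):
            s.advance()
        s.mark_center(ClickEvent(7, 10.0, 10.0))
        s.mark_center(ClickEvent(7, 30.0, 40.0))
        recs = s.annotations().by_frame(7)
        assert len(recs) == 1
        assert recs[0].center == pytest.approx((30.0, 40.0))


class TestNavigation:
    def test_advance_exposes_previous_mark_as_reference(self, image_set_dir, tmp_path):
        s, _ = _session(image_set_dir, tmp_path)
        s.mark_center(ClickEvent(1, 12.0, 34.0))
        assert s.advance()
        assert s.reference_point == pytest.approx((12.0, 34.0))

    def test_advance_from_unmarked_frame_keeps_reference(self, image_set_dir, tmp_path):
        s, _ = _session(image_set_dir, tmp_path)
        s.mark_center(ClickEvent(1, 12.0, 34.0))
        s.advance()
        s.advance()  # frame 2 unmarked
        assert s.reference_point == pytest.approx((12.0, 34.0))

    def test_rollback_then_advance_is_identity(self, image_set_dir, tmp_path):
        s, _ = _session(image_set_dir, tmp_path)
        s.mark_center(ClickEvent(1, 5.0, 5.0))
        s.advance()
        before = (s.current_frame, s.reference_point, dict(s.marks))
        s.advance()
        s.rollback()
        assert (s.current_frame, s.reference_point, dict(s.marks)) == before

    def test_boundary_moves_are_noops_with_notice(self, image_set_dir, tmp_path):
        s, _ = _session(image_set_dir, tmp_path, n_frames=2)
        assert not s.rollback()
        assert s.last_notice is not None
        s.advance()
        assert not s.advance()
        assert s.last_notice is not None
        assert s.current_frame == 2


class TestAbsentAndModify:
    def test_absent_removes_one_frame(self, image_set_dir, tmp_path):
        s, _ = _session(image_set_dir, tmp_path, n_frames=10)
        for f in range(1, 11):
            s.mark_center(ClickEvent(f, 10.0, 10.0))
            s.advance()
        s.modify(5, 10.0, 10.0)  # ensure marked
        s.current_frame = 5
        s.mark_absent()
        assert len(s.annotations()) == 9
        s.mark_absent()  # absent on an unmarked frame is a no-op
        assert len(s.annotations()) == 9

    def test_modify_touches_only_target_frame(self, image_set_dir, tmp_path):
        s, _ = _session(image_set_dir, tmp_path, n_frames=12)
        for f in range(1, 13):
            s.mark_center(ClickEvent(f, 100.0, 100.0))
            s.advance()
        s.modify(10, 105.0, 100.0)
        for rec in s.annotations():
            expected = (105.0, 100.0) if rec.frame == 10 else (100.0, 100.0)
            assert rec.center == pytest.approx(expected)

    def test_modify_unmarked_frame_creates_mark(self, image_set_dir, tmp_path):
        s, _ = _session(image_set_dir, tmp_path)
        s.modify(3, 50.0, 50.0)
        assert 3 in s.marks

    def test_modify_out_of_range_rejected(self, image_set_dir, tmp_path):
        s, _ = _session(image_set_dir, tmp_path, n_frames=5)
        with pytest.raises(RangeError):
            s.modify(6, 1.0, 1.0)


_event = st.one_of(
    st.tuples(st.just("mark"), st.floats(0, 64, allow_nan=False),
              st.floats(0, 48, allow_nan=False)),
    st.tuples(st.just("advance")),
    st.tuples(st.just("rollback")),
    st.tuples(st.just("absent")),
    st.tuples(st.just("modify"), st.integers(1, 8),
              st.floats(0, 64, allow_nan=False), st.floats(0, 48, allow_nan=False)),
)


@settings(max_examples=25, deadline=None)
@given(st.lists(_event, max_size=40))
def test_event_log_replay_is_deterministic(tmp_path_factory, events):
    """The same event log produces byte-identical output files."""
    outputs = []
    for run in range(2):
        tmp = tmp_path_factory.mktemp(f"replay{run}")
        name = str(mot_io.ImageSetName("0001", 1, 16))
        d = tmp / name
        (d / "img").mkdir(parents=True)
        from PIL import Image

        for i in range(1, 9):
            Image.new("RGB", (64, 48)).save(d / "img" / mot_io.frame_filename(i))
        s = session.start_session(d, tmp / "out", 1)
        session.replay(s, events)
        outputs.append(s.output_path.read_bytes() if s.output_path.exists() else b"")
    assert outputs[0] == outputs[1]


@settings(max_examples=20, deadline=None)
@given(st.data())
def test_alternating_mark_absent_final_state_wins(tmp_path_factory, data):
    """A mark/absent toggle sequence on one frame matches a naive replay."""
    toggles = data.draw(st.lists(st.sampled_from(["mark", "absent"]), min_size=1, max_size=8))
    tmp = tmp_path_factory.mktemp("toggle")
    from PIL import Image

    d = tmp / str(mot_io.ImageSetName("0001", 1, 16))
    (d / "img").mkdir(parents=True)
    Image.new("RGB", (64, 48)).save(d / "img" / mot_io.frame_filename(1))
    s = session.start_session(d, tmp / "out", 1)
    present = False  # independent state-machine oracle
    for t in toggles:
        if t == "mark":
            s.mark_center(ClickEvent(1, 10.0, 10.0))
            present = True
        else:
            s.mark_absent()
            present = False
    assert (1 in s.marks) == present


class TestMerge:
    def _mark_full_pass(self, image_set_dir, tmp_path, object_id, n_frames, x):
        d = image_set_dir(seq_label="0001", n_objects=3, n_frames=n_frames)
        s = session.start_session(d, tmp_path / "out", object_id)
        for f in range(1, n_frames + 1):
            s.mark_center(ClickEvent(f, x, 10.0))
            s.advance()
        return s.output_dir

    def test_full_pass_gives_one_record_per_frame(self, image_set_dir, tmp_path):
        out = self._mark_full_pass(image_set_dir, tmp_path, 1, 12, 5.0)
        merged = session.merge([out])
        assert len(merged) == 12

    def test_merge_is_sorted_and_permutation_invariant(self, image_set_dir, tmp_path):
        dirs = [
            self._mark_full_pass(image_set_dir, tmp_path, oid, 12, float(oid))
            for oid in (3, 1, 2)
        ]
        merged = session.merge(dirs)
        keys = [(r.frame, r.track_id) for r in merged.records]
        assert keys == sorted(keys)
        assert all(a < b for a, b in zip(keys, keys[1:]))
        again = session.merge(list(reversed(dirs)))
        assert again.records == merged.records

    def test_merge_matches_brute_force_sort_oracle(self, tmp_path):
        # three objects with interleaved frame ranges, written by hand
        all_recs = []
        dirs = []
        for oid, frames in [(1, [1, 2, 3]), (2, [2, 3, 4]), (3, [1, 4])]:
            d = tmp_path / f"{oid:04d}"
            d.mkdir()
            recs = [mot_io.BoxRecord(f, oid, f, f, 5, 5, 1) for f in frames]
            mot_io.write_annotations(
                mot_io.SequenceAnnotations("s", GROUND_TRUTH, recs), d / "gt.txt"
            )
            all_recs.extend(recs)
            dirs.append(d)
        merged = session.merge(dirs)
        assert merged.records == sorted(all_recs, key=lambda r: (r.frame, r.track_id))

    def test_duplicate_object_id_across_dirs_rejected(self, tmp_path):
        for sub in ("a", "b"):
            d = tmp_path / sub
            d.mkdir()
            mot_io.write_annotations(
                mot_io.SequenceAnnotations(
                    "s", GROUND_TRUTH, [mot_io.BoxRecord(1, 7, 0, 0, 5, 5, 1)]
                ),
                d / "gt.txt",
            )
        with pytest.raises(IntegrityError):
            session.merge([tmp_path / "a", tmp_path / "b"])

    def test_zero_directories_give_empty_annotations(self):
        assert len(session.merge([])) == 0

    def test_ten_objects_over_351_frames_merge_to_3510_records(self, tmp_path):
        """A fully marked 10-ant, 351-frame indoor sequence merges to 3,510 records."""
        out = synthetic.simulate_colony(
            synthetic.SimConfig(n_ants=10, n_frames=351, seed=5)
        )
        dirs = []
        for tid in out.gt.track_ids:
            d = tmp_path / f"{tid:04d}"
            d.mkdir()
            mot_io.write_annotations(
                mot_io.SequenceAnnotations("0001", GROUND_TRUTH, out.gt.by_track(tid)),
                d / "gt.txt",
            )
            dirs.append(d)
        merged = session.merge(dirs)
        assert len(merged) == 3510
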