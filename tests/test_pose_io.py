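import io

import numpy as np
import pandas as pd
import pytest

from embryokin.errors import DesignError, FormatError, SchemeError, TrackValidationError
from embryokin.pose_io import (
    BodypartScheme,
    StimulusRecord,
    TrialDesign,
    bind_scheme,
    build_track,
    read_designs,
    read_pose_csv,
    write_designs,
    write_pose_csv,
)
from tests.conftest import make_small_track, simple_design


class TestPoseCsv:
    def test_well_formed_round_trip_is_identity(self, rng):
        track = make_small_track(rng, n=30)
        track.mask_frames("UpperBeakTip", [3, 4, 11])
        track.data.loc[3, ("UpperBeakTip", "likelihood")] = 0.0
        track.data.loc[4, ("UpperBeakTip", "likelihood")] = 0.0
        track.data.loc[11, ("UpperBeakTip", "likelihood")] = 0.0
        buf = io.StringIO()
        write_pose_csv(track, buf)
        buf.seek(0)
        back = read_pose_csv(buf, trial_id=track.trial_id)
        assert back.equals(track)

    def test_two_frame_two_label_file(self, rng):
        track = make_small_track(rng, n=2, labels=("A", "B"))
        buf = io.StringIO()
        write_pose_csv(track, buf)
        buf.seek(0)
        back = read_pose_csv(buf, trial_id="t0")
        assert back.n_frames == 2
        assert back.bodyparts == ["A", "B"]
        assert not any(back.missing(lab).any() for lab in back.bodyparts)

    def test_empty_track_writes_header_only_file(self):
        track = build_track("empty", {"A": np.empty((0, 3))})
        buf = io.StringIO()
        write_pose_csv(track, buf)
        lines = buf.getvalue().strip().splitlines()
        assert len(lines) == 3  # scorer, bodyparts, coords; no data rows
        assert lines[0].startswith("scorer")

    def test_likelihood_above_one_names_label_and_frame(self):
        csv = (
            "scorer,s,s,s\n"
            "bodyparts,Beak,Beak,Beak\n"
            "coords,x,y,likelihood\n"
            "0,1.0,2.0,0.9\n"
            "1,1.0,2.0,1.2\n"
        )
        with pytest.raises(TrackValidationError, match=r"Beak.*frame 1.*1\.2"):
            read_pose_csv(io.StringIO(csv))

    def test_missing_header_rows_is_format_error(self):
        with pytest.raises((FormatError, TrackValidationError)):
            read_pose_csv(io.StringIO("x,y\n1,2\n3,4\n"))

    def test_inconsistent_triplet_is_format_error(self):
        csv = (
            "scorer,s,s\n"
            "bodyparts,Beak,Beak\n"
            "coords,x,y\n"
            "0,1.0,2.0\n"
        )
        with pytest.raises(FormatError, match="triplet|likelihood"):
            read_pose_csv(io.StringIO(csv))

    def test_malformed_cells_masked_and_counted_not_dropped(self):
        csv = (
            "scorer,s,s,s\n"
            "bodyparts,Beak,Beak,Beak\n"
            "coords,x,y,likelihood\n"
            "0,1.0,2.0,0.9\n"
            "1,oops,2.0,0.8\n"
            "2,3.0,4.0,0.95\n"
        )
        track = read_pose_csv(io.StringIO(csv))
        assert track.n_frames == 3  # no silent frame drop
        assert track.parse_report == {"Beak": 1}
        assert track.missing("Beak").tolist() == [False, True, False]

    def test_write_then_read_cohort_is_stable(self, rng, tmp_path):
        track = make_small_track(rng, n=10)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_pose_csv(track, p1)
        write_pose_csv(track, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestPoseHdf5:
    def test_hdf5_dialect_matches_csv_reader(self, rng, tmp_path):
        from embryokin.pose_io import read_pose_hdf5

        track = make_small_track(rng, n=12)
        out = track.data.copy()
        out.columns = pd.MultiIndex.from_tuples(
            [(track.scorer, bp, c) for bp, c in out.columns],
            names=("scorer", "bodyparts", "coords"),
        )
        path = tmp_path / "track.h5"
        out.to_hdf(path, key="df_with_missing")
        back = read_pose_hdf5(path, trial_id=track.trial_id)
        assert back.equals(track)


class TestScheme:
    def test_role_resolves_to_underlying_label(self, rng, small_scheme):
        track = make_small_track(
            rng, labels=("UpperBeakTip", "LowerBeakTip", "BeakFulcrum", "EyeCorner", "EggRef")
        )
        view = bind_scheme(track, small_scheme)
        np.testing.assert_array_equal(view.coords("beak_upper"), track.xy("UpperBeakTip"))
        np.testing.assert_array_equal(view.coords("EggRef"), track.xy("EggRef"))

    def test_duplicate_beak_labels_rejected(self):
        with pytest.raises(SchemeError, match="distinct"):
            BodypartScheme(beak_upper="A", beak_lower="A", beak_fulcrum="B")

    def test_absent_label_rejected(self, rng, small_scheme):
        track = make_small_track(rng, labels=("UpperBeakTip", "LowerBeakTip"))
        with pytest.raises(SchemeError, match="lacks labels"):
            bind_scheme(track, small_scheme)

    def test_unbound_role_rejected(self, rng, small_scheme):
        track = make_small_track(
            rng, labels=("UpperBeakTip", "LowerBeakTip", "BeakFulcrum", "EyeCorner", "EggRef")
        )
        view = bind_scheme(track, small_scheme)
        with pytest.raises(SchemeError, match="not bound"):
            view.coords("elbow")

    def test_ed9_requires_tarsus_for_leg(self, rng):
        scheme = BodypartScheme(
            beak_upper="U", beak_lower="L", beak_fulcrum="F",
            leg="Metatarsus", leg_kind="metatarsus",
        )
        track = make_small_track(rng, labels=("U", "L", "F", "Metatarsus"))
        with pytest.raises(SchemeError, match="tarsus"):
            bind_scheme(track, scheme, embryonic_day=9)
        # fine at ED12+
        bind_scheme(track, scheme, embryonic_day=12)


class TestTrialDesign:
    def test_requires_one_pinch_and_one_touch(self):
        with pytest.raises(DesignError, match="one Pinch and one Touch"):
            TrialDesign(
                embryo_id="e",
                embryonic_day=15,
                stimuli=(
                    StimulusRecord("Pinch", 100, 110),
                    StimulusRecord("Pinch", 500, 510),
                ),
            )

    def test_release_before_onset_rejected(self):
        with pytest.raises(DesignError, match="precede"):
            StimulusRecord("Touch", 100, 90)

    def test_overlapping_stimulus_windows_rejected(self):
        with pytest.raises(DesignError, match="overlap"):
            TrialDesign(
                embryo_id="e",
                embryonic_day=15,
                stimuli=(
                    StimulusRecord("Pinch", 100, 600),
                    StimulusRecord("Touch", 500, 510),
                ),
            )

    def test_default_baseline_by_embryonic_day(self):
        assert simple_design(ed=16).baseline_duration_s == 120.0
        assert simple_design(ed=13).baseline_duration_s == 180.0

    def test_yaml_round_trip(self, tmp_path):
        designs = [simple_design("e01"), simple_design("e02", order=("Touch", "Pinch"))]
        path = tmp_path / "designs.yaml"
        write_designs(designs, path)
        back = read_designs(path)
        assert back == designs
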