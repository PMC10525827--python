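import numpy as np
import pytest

from embryokin.errors import DegenerateDesignError
from embryokin.kinematics import beak_distance, movement
from embryokin.pose_io import bind_scheme
from embryokin.qc import preprocess
from embryokin.simulate import (
    SimParams,
    make_design,
    noise_free,
    scheme_for,
    simulate_cohort,
    simulate_trial,
)
from embryokin.stats import fit_repeated_model
from embryokin.windowing import build_interval_table, summarize_cohort, summarize_trial

FAST = dict(frame_rate=5.0)  # 10x fewer frames, same timeline


class TestSingleTrial:
    def test_zero_noise_zero_effect_gives_constant_gap(self):
        params = noise_free(
            SimParams(pinch_events_per_interval=0.0, spont_opening_rate_per_min=0.0, **FAST)
        )
        design = make_design("e01", params)
        track, truth = simulate_trial(params, design, seed=1, embryo_offset_px=0.0)
        view = bind_scheme(track, scheme_for(params), embryonic_day=params.embryonic_day)
        gap = beak_distance(view).values
        np.testing.assert_allclose(gap, params.resting_gap_px, rtol=1e-12)

    def test_same_seed_reproduces_identical_track(self):
        params = SimParams(**FAST)
        design = make_design("e01", params)
        t1, _ = simulate_trial(params, design, seed=42, embryo_offset_px=0.5)
        t2, _ = simulate_trial(params, design, seed=42, embryo_offset_px=0.5)
        assert t1.equals(t2)

    def test_noise_free_pipeline_reproduces_ground_truth_sums(self):
        params = noise_free(SimParams(**FAST))
        design = make_design("e01", params)
        track, truth = simulate_trial(params, design, seed=7, embryo_offset_px=0.0)
        clean, _ = preprocess(track, outlier_k=None)
        view = bind_scheme(clean, scheme_for(params), embryonic_day=params.embryonic_day)
        summary = summarize_trial(beak_distance(view), design)
        merged = summary.merge(
            truth.expected_sums, on=["parameter", "window", "interval"], validate="1:1"
        )
        np.testing.assert_allclose(
            merged["sum"], merged["expected_sum"], rtol=1e-9
        )

    def test_evoked_event_area_matches_closed_form(self):
        """Each trapezoidal opening of amplitude A adds A*(ramp+hold+1)
        pixel-frames to the interval it lies in."""
        params = noise_free(SimParams(spont_opening_rate_per_min=0.0, **FAST))
        design = make_design("e01", params)
        track, truth = simulate_trial(params, design, seed=3, embryo_offset_px=0.0)
        fps = params.frame_rate
        L = int(round(30 * fps))
        ramp = max(int(round(params.event_ramp_s * fps)), 1)
        hold = int(round(params.event_hold_s * fps))
        release = design.stimulus("Pinch").release_frame

        first = truth.expected_sums[
            (truth.expected_sums["window"] == "PostPinch")
            & (truth.expected_sums["interval"] == "0-30")
        ]["expected_sum"].iloc[0]
        events = truth.events[
            (truth.events["stimulus"] == "Pinch")
            & (truth.events["start_frame"] >= release)
            & (truth.events["start_frame"] < release + L)
        ]
        expected_excess = float(
            (events["amplitude_px"] * (ramp + hold + 1)).sum()
        )
        assert first - params.resting_gap_px * L == pytest.approx(expected_excess, rel=1e-9)

    def test_reference_point_is_stationary_without_noise(self):
        params = noise_free(SimParams(**FAST))
        design = make_design("e01", params)
        track, _ = simulate_trial(params, design, seed=5, embryo_offset_px=0.0)
        view = bind_scheme(track, scheme_for(params), embryonic_day=params.embryonic_day)
        np.testing.assert_array_equal(
            movement(view, "egg_reference").values, 0.0
        )

    def test_dropout_fraction_matches_configured_rate(self):
        rate = 0.02
        params = SimParams(
            dropout_rate=rate, burst_rate=0.0, outlier_rate=0.0, **FAST
        )
        design = make_design("e01", params)
        track, truth = simulate_trial(params, design, seed=11)
        n = track.n_frames
        frac = len(truth.dropouts["beak_upper"]) / n
        se = np.sqrt(rate * (1 - rate) / n)
        assert abs(frac - rate) < 3 * se

    def test_ed9_trial_uses_tarsus(self):
        params = SimParams(embryonic_day=9, **FAST)
        design = make_design("e01", params)
        track, _ = simulate_trial(params, design, seed=2)
        assert "tarsus" in track.bodyparts
        assert "metatarsus" not in track.bodyparts
        bind_scheme(track, scheme_for(params), embryonic_day=9)


class TestCohort:
    def test_cohort_files_round_trip(self, tmp_path):
        from embryokin.pose_io import read_designs, read_pose_csv

        params = SimParams(n_embryos=3, **FAST)
        cohort = simulate_cohort(params, seed=4, outdir=tmp_path)
        designs = read_designs(tmp_path / "designs.yaml")
        assert len(designs) == 3
        for track in cohort.tracks:
            back = read_pose_csv(
                tmp_path / f"{track.trial_id}.csv",
                trial_id=track.trial_id,
                frame_rate=params.frame_rate,
            )
            assert back.equals(track)

    def test_same_seed_gives_identical_bytes(self, tmp_path):
        params = SimParams(n_embryos=2, **FAST)
        simulate_cohort(params, seed=9, outdir=tmp_path / "a")
        simulate_cohort(params, seed=9, outdir=tmp_path / "b")
        for name in ("e01.csv", "e02.csv", "designs.yaml", "manifest.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_zero_embryo_offset_yields_negligible_intercept_variance(self, rng):
        params = SimParams(n_embryos=8, embryo_offset_sd_px=0.0, **FAST)
        cohort = simulate_cohort(params, seed=6)
        scheme = scheme_for(params)
        series = {}
        for track in cohort.tracks:
            clean, _ = preprocess(track, outlier_k=None)
            view = bind_scheme(clean, scheme, embryonic_day=params.embryonic_day)
            series[track.trial_id] = [beak_distance(view)]
        table = build_interval_table(summarize_cohort(series, cohort.designs))
        model = fit_repeated_model(table, parameter="beak_distance")
        assert model.embryo_var < 0.1 * model.resid_var

    def test_single_embryo_cohort_degenerates_downstream(self):
        params = SimParams(n_embryos=1, **FAST)
        cohort = simulate_cohort(params, seed=8)
        scheme = scheme_for(params)
        track = cohort.tracks[0]
        clean, _ = preprocess(track, outlier_k=None)
        view = bind_scheme(clean, scheme, embryonic_day=params.embryonic_day)
        table = build_interval_table(
            summarize_cohort({track.trial_id: [beak_distance(view)]}, cohort.designs)
        )
        with pytest.raises(DegenerateDesignError):
            fit_repeated_model(table, parameter="beak_distance")
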