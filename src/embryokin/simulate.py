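"""Synthetic pose-track cohorts with known ground truth.

The generator emulates the structure of the in-ovo recordings the
analysis expects, at 50 frames/s:

* a fixed embryo "skeleton" (beak fulcrum and tips, medial eye corner,
  elbow, metatarsus/tarsus) plus a stationary reference point on the egg,
  each tracked with Gaussian pixel jitter;
* a beak gap that rests at a per-embryo offset around ~20 px and opens in
  trapezoidal pulses: spontaneous small openings throughout the
  recording, plus stimulus-evoked openings after the noxious pinch whose
  rate and amplitude decay over the four post-stimulus intervals (the
  light-touch control evokes none by default);
* spontaneous motility bouts displacing the head and limb landmarks;
* tracking dropouts (isolated frames and bursts) that push the likelihood
  below the analysis cutoff and perturb the reported coordinates;
* rare gross outlier frames with confidently reported but wildly wrong
  coordinates.

Every trial carries a :class:`GroundTruth` with the injected events,
dropout and outlier frames, and the noise-free expected interval sums, so
each pipeline stage can be checked against what was actually put in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from embryokin.errors import DesignError
from embryokin.pose_io import (
    BodypartScheme,
    PoseTrack,
    StimulusRecord,
    TrialDesign,
    build_track,
    default_baseline_duration_s,
    write_designs,
    write_pose_csv,
)

REFERENCE_LABEL = "egg_reference"


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults reflect the experimental protocol the
    analysis targets (50 fps, 16-embryo groups, 120-s baselines)."""

    n_embryos: int = 16
    embryonic_day: int = 16
    group: str = "plain"
    frame_rate: float = 50.0
    stimulus_duration_s: float = 2.0  # clamp contact time
    observation_s: float = 180.0  # recorded post-stimulus observation

    # skeleton (pixels, y-down image frame)
    resting_gap_px: float = 20.0
    fulcrum_tip_offset_px: float = 30.0
    noise_sd_px: float = 0.5
    embryo_offset_sd_px: float = 2.0  # between-embryo resting-gap spread

    # spontaneous motility
    spont_opening_rate_per_min: float = 1.0
    spont_opening_amplitude_px: float = 3.0
    bout_rate_per_min: float = 2.0
    bout_amplitude_px: float = 4.0
    bout_duration_s: float = 1.0

    # stimulus-evoked beak openings (trapezoidal pulses)
    pinch_events_per_interval: float = 5.0  # expected events in the 0-30 s interval
    pinch_amplitude_px: float = 15.0
    touch_events_per_interval: float = 0.0
    touch_amplitude_px: float = 0.0
    decay_per_interval: float = 0.5  # rate and amplitude multiplier per later interval
    event_hold_s: float = 1.5
    event_ramp_s: float = 0.25

    # tracking degradation
    dropout_rate: float = 0.01  # isolated per-frame dropout probability
    burst_rate: float = 0.0002  # per-frame probability a dropout burst starts
    burst_mean_len: float = 15.0
    outlier_rate: float = 0.0005
    outlier_magnitude_px: float = 300.0

    def __post_init__(self):
        if not 0 < self.decay_per_interval <= 1:
            raise ValueError("decay_per_interval must lie in (0, 1]")
        for name in (
            "pinch_events_per_interval", "touch_events_per_interval",
            "dropout_rate", "burst_rate", "outlier_rate",
            "spont_opening_rate_per_min", "bout_rate_per_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def leg_label(self) -> str:
        return "tarsus" if self.embryonic_day == 9 else "metatarsus"


_SKELETON = {
    "beak_fulcrum": (300.0, 200.0),
    "eye_corner": (260.0, 150.0),
    "elbow": (200.0, 260.0),
    "leg": (150.0, 320.0),
    REFERENCE_LABEL: (40.0, 40.0),
}


def scheme_for(params: SimParams) -> BodypartScheme:
    """The body-part scheme matching the simulator's label names."""
    return BodypartScheme(
        beak_upper="beak_upper",
        beak_lower="beak_lower",
        beak_fulcrum="beak_fulcrum",
        eye_corner="eye_corner",
        elbow="elbow",
        leg=params.leg_label,
        leg_kind=params.leg_label,
        reference_points=(REFERENCE_LABEL,),
    )


def make_design(
    embryo_id: str,
    params: SimParams,
    order: Sequence[str] = ("Pinch", "Touch"),
) -> TrialDesign:
    """Standard trial timeline: baseline, stimulus 1, observation, second
    baseline, stimulus 2, observation."""
    fps = params.frame_rate
    baseline_s = default_baseline_duration_s(params.embryonic_day)
    b = int(round(baseline_s * fps))
    stim = int(round(params.stimulus_duration_s * fps))
    obs = int(round(params.observation_s * fps))
    onset1 = b
    release1 = onset1 + stim
    onset2 = release1 + obs + b
    release2 = onset2 + stim
    stimuli = (
        StimulusRecord(order[0], onset1, release1),
        StimulusRecord(order[1], onset2, release2),
    )
    return TrialDesign(
        embryo_id=embryo_id,
        embryonic_day=params.embryonic_day,
        stimuli=stimuli,
        group=params.group,
        baseline_duration_s=baseline_s,
    )


def total_frames(design: TrialDesign, params: SimParams) -> int:
    last = max(s.release_frame for s in design.stimuli)
    # +1 so that movement series (length n-1) still cover the last interval
    return last + int(round(params.observation_s * params.frame_rate)) + 1


@dataclass
class GroundTruth:
    """What was injected into one simulated trial."""

    trial_id: str
    embryo_offset_px: float
    events: pd.DataFrame  # stimulus, start_frame, amplitude_px, width_frames
    dropouts: dict[str, np.ndarray]
    outliers: dict[str, np.ndarray]
    expected_sums: pd.DataFrame  # parameter, window, interval, expected_sum
    gap_series: np.ndarray = field(repr=False, default=None)


def _trapezoid(ramp: int, hold: int, amplitude: float) -> np.ndarray:
    """Rise over ``ramp`` frames, hold, fall; total width 2*ramp + hold."""
    up = amplitude * np.arange(1, ramp + 1) / ramp if ramp else np.empty(0)
    return np.concatenate([up, np.full(hold, amplitude), up[::-1]])


def _place_events(
    rng: np.random.Generator,
    start: int,
    stop: int,
    n_events: int,
    width: int,
) -> list[int]:
    """Non-overlapping pulse start frames fully inside [start, stop)."""
    usable = stop - start - width
    if usable <= 0 or n_events <= 0:
        return []
    starts: list[int] = []
    for _ in range(200):
        if len(starts) == n_events:
            break
        cand = int(rng.integers(start, start + usable))
        if all(abs(cand - s) > width + 2 for s in starts):
            starts.append(cand)
    return sorted(starts)


def _expected_interval_sums(
    gap: np.ndarray, design: TrialDesign, L: int, n_post: int
) -> pd.DataFrame:
    rows = []
    for stim in design.stimuli:
        for i in range(4):
            s = stim.onset_frame - (i + 1) * L
            rows.append(
                {
                    "parameter": "beak_distance",
                    "window": f"Baseline{stim.kind}",
                    "interval": f"{-(i + 1) * 30}-{-i * 30}",
                    "expected_sum": float(gap[s : s + L].sum()),
                }
            )
        for i in range(n_post):
            s = stim.release_frame + i * L
            rows.append(
                {
                    "parameter": "beak_distance",
                    "window": f"Post{stim.kind}",
                    "interval": f"{i * 30}-{(i + 1) * 30}",
                    "expected_sum": float(gap[s : s + L].sum()),
                }
            )
    return pd.DataFrame(rows)


def simulate_trial(
    params: SimParams,
    design: TrialDesign,
    seed: int | np.random.Generator = 0,
    embryo_offset_px: float | None = None,
) -> tuple[PoseTrack, GroundTruth]:
    """Simulate one trial's pose track and its ground truth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fps = params.frame_rate
    n = total_frames(design, params)
    for stim in design.stimuli:
        if stim.release_frame + int(round(120 * fps)) > n:
            raise DesignError(
                f"trial {design.embryo_id!r}: post window extends past the recording"
            )
    if embryo_offset_px is None:
        embryo_offset_px = float(rng.normal(0.0, params.embryo_offset_sd_px))

    ramp = max(int(round(params.event_ramp_s * fps)), 1)
    hold = int(round(params.event_hold_s * fps))
    width = 2 * ramp + hold
    L = int(round(30 * fps))
    n_post = int(round(design.post_duration_s / 30.0))

    # --- beak gap signal -------------------------------------------------
    gap = np.full(n, params.resting_gap_px + embryo_offset_px)
    pulse = _trapezoid(ramp, hold, 1.0)
    event_rows = []

    def add_event(start_frame: int, amplitude: float, stimulus: str) -> None:
        stop = min(start_frame + width, n)
        gap[start_frame:stop] += amplitude * pulse[: stop - start_frame]
        event_rows.append(
            {
                "stimulus": stimulus,
                "start_frame": start_frame,
                "amplitude_px": amplitude,
                "width_frames": width,
            }
        )

    # spontaneous openings anywhere in the recording
    n_spont = rng.poisson(params.spont_opening_rate_per_min * n / (60.0 * fps))
    for f in sorted(rng.integers(0, max(n - width, 1), size=n_spont)):
        add_event(int(f), params.spont_opening_amplitude_px, "spontaneous")

    # stimulus-evoked openings, decaying over post intervals
    for stim in design.stimuli:
        if stim.kind == "Pinch":
            rate0, amp0 = params.pinch_events_per_interval, params.pinch_amplitude_px
        else:
            rate0, amp0 = params.touch_events_per_interval, params.touch_amplitude_px
        if rate0 <= 0 or amp0 <= 0:
            continue
        for i in range(n_post):
            factor = params.decay_per_interval**i
            k = rng.poisson(rate0 * factor)
            starts = _place_events(
                rng, stim.release_frame + i * L, stim.release_frame + (i + 1) * L, k, width
            )
            for f in starts:
                add_event(f, amp0 * factor, stim.kind)

    truth_sums = _expected_interval_sums(gap, design, L, n_post)

    # --- landmark coordinates -------------------------------------------
    half = gap / 2.0
    dx = params.fulcrum_tip_offset_px
    fx, fy = _SKELETON["beak_fulcrum"]
    coords = {
        "beak_upper": np.column_stack([np.full(n, fx + dx), fy - half]),
        "beak_lower": np.column_stack([np.full(n, fx + dx), fy + half]),
        "beak_fulcrum": np.column_stack([np.full(n, fx), np.full(n, fy)]),
    }
    for label, base_key in (
        ("eye_corner", "eye_corner"),
        ("elbow", "elbow"),
        (params.leg_label, "leg"),
        (REFERENCE_LABEL, REFERENCE_LABEL),
    ):
        bx, by = _SKELETON[base_key]
        coords[label] = np.column_stack([np.full(n, bx), np.full(n, by)])

    # spontaneous motility bouts displace head and limb landmarks
    bout_len = max(int(round(params.bout_duration_s * fps)), 2)
    n_bouts = rng.poisson(params.bout_rate_per_min * n / (60.0 * fps))
    moving = ["eye_corner", "elbow", params.leg_label]
    for _ in range(n_bouts):
        f0 = int(rng.integers(0, max(n - bout_len, 1)))
        label = moving[int(rng.integers(len(moving)))]
        theta = rng.uniform(0, 2 * np.pi)
        envelope = np.sin(np.linspace(0, np.pi, bout_len)) * params.bout_amplitude_px
        wobble = np.sin(np.linspace(0, 4 * np.pi, bout_len)) * envelope
        coords[label][f0 : f0 + bout_len, 0] += wobble * math.cos(theta)
        coords[label][f0 : f0 + bout_len, 1] += wobble * math.sin(theta)

    # --- tracking degradation -------------------------------------------
    arrays: dict[str, np.ndarray] = {}
    dropouts: dict[str, np.ndarray] = {}
    outliers: dict[str, np.ndarray] = {}
    for label, xy in coords.items():
        xy = xy + rng.normal(0.0, params.noise_sd_px, size=(n, 2)) \
            if params.noise_sd_px > 0 else xy.copy()
        lik = rng.uniform(0.9, 1.0, size=n)

        drop = rng.random(n) < params.dropout_rate
        burst_starts = np.flatnonzero(rng.random(n) < params.burst_rate)
        for b0 in burst_starts:
            blen = 1 + rng.geometric(1.0 / params.burst_mean_len)
            drop[b0 : b0 + blen] = True
        drop_idx = np.flatnonzero(drop)
        if drop_idx.size:
            lik[drop_idx] = rng.uniform(0.0, 0.6, size=drop_idx.size)
            xy[drop_idx] += rng.normal(0.0, 10.0, size=(drop_idx.size, 2))
        dropouts[label] = drop_idx

        out_idx = np.flatnonzero(~drop & (rng.random(n) < params.outlier_rate))
        if out_idx.size:
            theta = rng.uniform(0, 2 * np.pi, size=out_idx.size)
            xy[out_idx, 0] += params.outlier_magnitude_px * np.cos(theta)
            xy[out_idx, 1] += params.outlier_magnitude_px * np.sin(theta)
        outliers[label] = out_idx

        arrays[label] = np.column_stack([xy, lik])

    track = build_track(
        design.embryo_id, arrays, frame_rate=fps, scorer="synthetic"
    )
    truth = GroundTruth(
        trial_id=design.embryo_id,
        embryo_offset_px=embryo_offset_px,
        events=pd.DataFrame(
            event_rows, columns=["stimulus", "start_frame", "amplitude_px", "width_frames"]
        ),
        dropouts=dropouts,
        outliers=outliers,
        expected_sums=truth_sums,
        gap_series=gap,
    )
    return track, truth


def ground_truth_annotations(truths: dict[str, "GroundTruth"]) -> pd.DataFrame:
    """Turn injected opening events into ethogram annotations.

    Stimulus-evoked openings are recorded as BeakOpening, the small
    spontaneous openings as Mandibulation — the simulator's analogue of
    an observer annotating the same video.
    """
    rows = []
    for trial_id, truth in truths.items():
        for _, ev in truth.events.iterrows():
            behavior = "Mandibulation" if ev["stimulus"] == "spontaneous" else "BeakOpening"
            rows.append(
                {"trial_id": trial_id, "behavior": behavior, "frame": int(ev["start_frame"])}
            )
    return pd.DataFrame(rows, columns=["trial_id", "behavior", "frame"])


@dataclass
class CohortSim:
    params: SimParams
    tracks: list[PoseTrack]
    designs: dict[str, TrialDesign]
    truths: dict[str, GroundTruth]
    manifest: pd.DataFrame


def simulate_cohort(
    params: SimParams,
    n: int | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> CohortSim:
    """Simulate ``n`` embryos with randomized stimulus order.

    Embryo-level resting-gap offsets are drawn once per embryo, giving the
    cohort a true random-intercept structure. With ``outdir`` set, writes
    one pose CSV per embryo, the cohort design YAML, the injected-event
    ground truth CSV and a manifest linking them.
    """
    n = params.n_embryos if n is None else n
    if n < 1:
        raise ValueError("cohort needs at least one embryo")
    root = np.random.default_rng(seed)
    offsets = root.normal(0.0, params.embryo_offset_sd_px, size=n)
    tracks, designs, truths, rows = [], {}, {}, []
    for i in range(n):
        embryo_id = f"e{i + 1:02d}"
        order = ("Pinch", "Touch") if root.random() < 0.5 else ("Touch", "Pinch")
        design = make_design(embryo_id, params, order)
        trial_rng = np.random.default_rng(root.integers(0, 2**31))
        track, truth = simulate_trial(
            params, design, trial_rng, embryo_offset_px=float(offsets[i])
        )
        tracks.append(track)
        designs[embryo_id] = design
        truths[embryo_id] = truth
        rows.append(
            {
                "embryo_id": embryo_id,
                "embryonic_day": params.embryonic_day,
                "group": params.group,
                "stimulus_order": "+".join(order),
                "n_frames": track.n_frames,
                "pose_file": f"{embryo_id}.csv",
            }
        )
    manifest = pd.DataFrame(rows)
    cohort = CohortSim(params, tracks, designs, truths, manifest)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for track in tracks:
            write_pose_csv(track, outdir / f"{track.trial_id}.csv")
        write_designs(designs.values(), outdir / "designs.yaml")
        pd.concat(
            [t.events.assign(trial_id=tid) for tid, t in truths.items()],
            ignore_index=True,
        ).to_csv(outdir / "ground_truth_events.csv", index=False)
        ground_truth_annotations(truths).to_csv(outdir / "annotations.csv", index=False)
        manifest.to_csv(outdir / "manifest.csv", index=False)
    return cohort


def noise_free(params: SimParams) -> SimParams:
    """Copy of ``params`` with every noise and degradation source off."""
    return replace(
        params,
        noise_sd_px=0.0,
        embryo_offset_sd_px=0.0,
        spont_opening_rate_per_min=0.0,
        bout_rate_per_min=0.0,
        dropout_rate=0.0,
        burst_rate=0.0,
        outlier_rate=0.0,
    )
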