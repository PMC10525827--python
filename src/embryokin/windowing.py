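"""Interval segmentation, imputation, exclusion and baseline statistics.

Each trial is evaluated in 30-s intervals (1500 frames at 50 frames/s; the
interval length is ``round(30 × frame_rate)`` in general). Per stimulus:

* four post-stimulus intervals (0–30, 30–60, 60–90, 90–120 s) begin at the
  moment the stimulating instrument leaves the beak (the release frame);
* four pre-stimulus intervals are tiled backward from stimulus onset; the
  **baseline** is the median of their interval sums.

Within an interval, the per-frame parameter values are summed. Missing
frames (likelihood cutoff or outlier exclusion) are handled in two steps:

* an interval with more than 5% missing frames is excluded outright
  (exactly 5% is retained — the rule is strict);
* otherwise each contiguous missing run is imputed with a single constant,
  the median of the nearest valid values on both sides — "half of the
  adjacent data", i.e. ``k = max(1, ceil(gap/2))`` neighbors per side,
  pooled (one-sided at interval edges).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from embryokin.errors import DesignError, ParameterError
from embryokin.kinematics import KinematicSeries
from embryokin.pose_io import STIMULUS_KINDS, TrialDesign

DEFAULT_INTERVAL_S = 30.0
MAX_MISSING_FRACTION = 0.05

#: collapsed baseline slot used for plotting/contrasts (the -30–0 s position)
BASELINE_SLOT = "BL"
POST_SLOTS = ("0-30", "30-60", "60-90", "90-120")


def interval_length(frame_rate: float, interval_s: float = DEFAULT_INTERVAL_S) -> int:
    """Frames per aggregation interval: round(30 s × frame rate) = 1500 at 50 fps."""
    if interval_s <= 0:
        raise ParameterError(f"interval length must be positive, got {interval_s} s")
    return int(round(interval_s * frame_rate))


@dataclass(frozen=True)
class Interval:
    """One 30-s slice of one kinematic series."""

    trial_id: str
    parameter: str
    window: str  # BaselinePinch | BaselineTouch | PostPinch | PostTouch
    label: str  # e.g. "-30-0", "0-30"
    start: int  # series index, inclusive
    stop: int  # exclusive
    is_baseline: bool


def _pre_label(i: int, interval_s: float) -> str:
    lo = -int((i + 1) * interval_s)
    hi = -int(i * interval_s)
    return f"{lo}-{hi}"


def segment(
    series: KinematicSeries,
    design: TrialDesign,
    interval_s: float = DEFAULT_INTERVAL_S,
    n_baseline_intervals: int = 4,
) -> list[Interval]:
    """Cut one kinematic series into baseline and post-stimulus intervals.

    Post intervals are aligned to the release frame of each stimulus; pre
    intervals are tiled backward from its onset. Raises
    :class:`DesignError` if a window does not fit inside the recording.
    """
    L = interval_length(series.frame_rate, interval_s)
    n_post = int(round(design.post_duration_s / interval_s))
    n = series.n
    out: list[Interval] = []
    for kind in STIMULUS_KINDS:
        stim = design.stimulus(kind)
        first_pre = stim.onset_frame - n_baseline_intervals * L
        if first_pre < 0:
            raise DesignError(
                f"trial {series.trial_id!r}: {kind} onset at frame {stim.onset_frame} "
                f"leaves no room for {n_baseline_intervals} pre-stimulus intervals of {L} frames"
            )
        for i in range(n_baseline_intervals):
            # i = 0 is the interval nearest the stimulus (-30–0 s)
            start = stim.onset_frame - (i + 1) * L
            out.append(
                Interval(
                    series.trial_id,
                    series.parameter,
                    f"Baseline{kind}",
                    _pre_label(i, interval_s),
                    start,
                    start + L,
                    True,
                )
            )
        last_stop = stim.release_frame + n_post * L
        if last_stop > n:
            raise DesignError(
                f"trial {series.trial_id!r}: {kind} post window ends at frame "
                f"{last_stop} but the series has only {n} values"
            )
        for i in range(n_post):
            start = stim.release_frame + i * L
            label = f"{int(i * interval_s)}-{int((i + 1) * interval_s)}"
            out.append(
                Interval(
                    series.trial_id,
                    series.parameter,
                    f"Post{kind}",
                    label,
                    start,
                    start + L,
                    False,
                )
            )
    return out


def exclusion_rule(
    values: np.ndarray, max_missing_fraction: float = MAX_MISSING_FRACTION
) -> bool:
    """True (exclude) iff strictly more than 5% of the interval is missing.

    75 of 1500 missing (exactly 5%) is retained; 76 is excluded.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return True
    return int(np.isnan(values).sum()) > max_missing_fraction * values.size


def impute_interval(values: np.ndarray) -> np.ndarray:
    """Fill every missing run with a local median of its neighbors.

    A contiguous run of ``g`` missing values is replaced by one constant:
    the median of the ``k = max(1, ceil(g/2))`` nearest originally-valid
    values on each side, pooled (at most ``2k`` values; one-sided when the
    run touches an interval edge). Observed values are never altered.
    """
    values = np.asarray(values, dtype=float)
    out = values.copy()
    nan = np.isnan(values)
    if not nan.any():
        return out
    valid_idx = np.flatnonzero(~nan)
    if valid_idx.size == 0:
        raise ValueError("interval has no valid values; it must be excluded, not imputed")
    # contiguous missing runs
    edges = np.diff(nan.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if nan[0]:
        starts.insert(0, 0)
    if nan[-1]:
        stops.append(len(values))
    for start, stop in zip(starts, stops):
        g = stop - start
        k = max(1, math.ceil(g / 2))
        left = valid_idx[valid_idx < start][-k:]
        right = valid_idx[valid_idx >= stop][:k]
        pool = values[np.concatenate([left, right])]
        out[start:stop] = np.median(pool)
    return out


def interval_sum(values: np.ndarray) -> float:
    """Arithmetic sum of an imputed (complete) interval."""
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("interval still contains missing values; impute or exclude first")
    return float(values.sum())


def baseline_value(
    sums: Sequence[float], excluded: Sequence[bool] | None = None
) -> float:
    """Median of the four pre-stimulus interval sums.

    Excluded intervals are dropped from the median; if all four are
    excluded the baseline is missing (NaN).
    """
    sums = np.asarray(sums, dtype=float)
    if excluded is not None:
        sums = sums[~np.asarray(excluded, dtype=bool)]
    sums = sums[~np.isnan(sums)]
    if sums.size == 0:
        return float("nan")
    return float(np.median(sums))


def summarize_trial(
    series: KinematicSeries,
    design: TrialDesign,
    interval_s: float = DEFAULT_INTERVAL_S,
    max_missing_fraction: float = MAX_MISSING_FRACTION,
) -> pd.DataFrame:
    """Per-interval summary of one kinematic series of one trial.

    One row per window × interval with the missing fraction (pre-
    imputation), the exclusion flag, the number of imputed frames and the
    interval sum (NaN when excluded).
    """
    rows = []
    for iv in segment(series, design, interval_s):
        chunk = series.values[iv.start : iv.stop]
        miss = float(np.isnan(chunk).mean()) if chunk.size else 1.0
        excl = exclusion_rule(chunk, max_missing_fraction)
        if excl:
            total = np.nan
            n_imp = 0
        else:
            filled = impute_interval(chunk)
            n_imp = int(np.isnan(chunk).sum())
            total = interval_sum(filled)
        rows.append(
            {
                "trial_id": iv.trial_id,
                "embryo_id": design.embryo_id,
                "embryonic_day": design.embryonic_day,
                "group": design.group,
                "parameter": iv.parameter,
                "window": iv.window,
                "interval": iv.label,
                "start_frame": iv.start,
                "end_frame": iv.stop,
                "missing_fraction": miss,
                "excluded": excl,
                "n_imputed": n_imp,
                "sum": total,
            }
        )
    return pd.DataFrame(rows)


def build_interval_table(
    summaries: Iterable[pd.DataFrame] | pd.DataFrame,
) -> pd.DataFrame:
    """Collapse per-interval summaries into the analysis table.

    Baseline constituents are replaced by a single ``BL`` slot per window
    carrying the median of the non-excluded pre-stimulus sums; excluded
    post intervals (and trials whose four baseline intervals are all
    excluded) are omitted. Rows: embryo × parameter × window × slot with
    the response ``sum``.
    """
    if isinstance(summaries, pd.DataFrame):
        summary = summaries
    else:
        frames = list(summaries)
        summary = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if summary.empty:
        return pd.DataFrame(
            columns=[
                "embryo_id", "embryonic_day", "group", "parameter",
                "window", "interval", "sum",
            ]
        )
    keys = ["embryo_id", "embryonic_day", "group", "parameter"]
    rows = []
    base = summary[summary["window"].str.startswith("Baseline")]
    for (embryo, ed, group, param, window), grp in base.groupby(
        keys + ["window"], sort=False
    ):
        bl = baseline_value(grp["sum"].to_numpy(), grp["excluded"].to_numpy())
        if not np.isnan(bl):
            rows.append(
                {
                    "embryo_id": embryo,
                    "embryonic_day": ed,
                    "group": group,
                    "parameter": param,
                    "window": window,
                    "interval": BASELINE_SLOT,
                    "sum": bl,
                }
            )
    post = summary[summary["window"].str.startswith("Post") & ~summary["excluded"]]
    for _, r in post.iterrows():
        rows.append(
            {
                "embryo_id": r["embryo_id"],
                "embryonic_day": r["embryonic_day"],
                "group": r["group"],
                "parameter": r["parameter"],
                "window": r["window"],
                "interval": r["interval"],
                "sum": r["sum"],
            }
        )
    return pd.DataFrame(rows)


def summarize_cohort(
    series_by_trial: Mapping[str, Sequence[KinematicSeries]],
    designs: Mapping[str, TrialDesign],
    interval_s: float = DEFAULT_INTERVAL_S,
    max_missing_fraction: float = MAX_MISSING_FRACTION,
) -> pd.DataFrame:
    """Concatenated :func:`summarize_trial` over a cohort."""
    frames = []
    for trial_id, series_list in series_by_trial.items():
        design = designs[trial_id]
        for series in series_list:
            frames.append(summarize_trial(series, design, interval_s, max_missing_fraction))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
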