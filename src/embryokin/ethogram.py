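"""Beak-movement ethogram: event counts and responder percentages.

Four discrete beak behaviors are annotated from video:

* **BeakShift** — small horizontal shift of upper against lower beak;
* **Mandibulation** — small repeated vertical opening, chewing-like;
* **BeakOpening** — single swift vertical opening;
* **WideBeakOpening** — single wide opening with the characteristic
  tongue movement.

Annotations are frame-stamped events per trial. Tallies report, per
embryonic-day group × window × 30-s interval × behavior, the event count,
the number of responders (embryos with at least one event) and the
responder percentage. For the manual observations the baseline window is
the single 30 s immediately before each stimulus; post windows are the
four 30-s intervals from stimulus release.

Percentages are rounded half away from zero to one decimal (13/16 →
81.3%, 3/16 → 18.8%, 1/16 → 6.3%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from embryokin.errors import FormatError, ParameterError
from embryokin.kinematics import KinematicSeries
from embryokin.pose_io import STIMULUS_KINDS, TrialDesign
from embryokin.windowing import DEFAULT_INTERVAL_S, interval_length

BEHAVIORS = ("BeakShift", "Mandibulation", "BeakOpening", "WideBeakOpening")


def responder_percentage(responders: int, group_n: int) -> float:
    """Share of embryos responding, in percent, half-away-from-zero at 1 decimal.

    Exact integer arithmetic avoids binary-float ties: 13/16 → 81.25 →
    81.3, not the 81.2 a banker's rounding would give.
    """
    if group_n <= 0:
        raise ParameterError(f"group size must be positive, got {group_n}")
    if not 0 <= responders <= group_n:
        raise ParameterError(f"responders {responders} outside [0, {group_n}]")
    num = 1000 * responders  # percentage in tenths
    q, rem = divmod(num, group_n)
    if 2 * rem >= group_n:
        q += 1
    return q / 10.0


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a behavior-event CSV with columns trial_id, behavior, frame."""
    path = Path(path)
    if path.stat().st_size == 0:
        return pd.DataFrame(columns=["trial_id", "behavior", "frame"])
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["trial_id", "behavior", "frame"])
    missing = {"trial_id", "behavior", "frame"} - set(df.columns)
    if missing:
        raise FormatError(f"annotation file lacks columns {sorted(missing)}")
    unknown = sorted(set(df["behavior"]) - set(BEHAVIORS))
    if unknown:
        raise FormatError(
            f"unknown behavior(s) {unknown}; recognized behaviors: {list(BEHAVIORS)}"
        )
    df = df.copy()
    df["frame"] = df["frame"].astype(int)
    if (df["frame"] < 0).any():
        raise FormatError("behavior event frames must be non-negative")
    return df[["trial_id", "behavior", "frame"]]


def _assign_window(
    frame: int, design: TrialDesign, L: int, n_post: int
) -> tuple[str, str] | None:
    """Map a frame stamp to (window, interval label), or None if outside all."""
    for kind in STIMULUS_KINDS:
        stim = design.stimulus(kind)
        if stim.onset_frame - L <= frame < stim.onset_frame:
            return f"Baseline{kind}", "-30-0"
        for i in range(n_post):
            start = stim.release_frame + i * L
            if start <= frame < start + L:
                return f"Post{kind}", f"{i * 30}-{(i + 1) * 30}"
    return None


@dataclass
class TallyResult:
    """Counts plus the events that fell outside every analysis window."""

    table: pd.DataFrame
    unassigned: pd.DataFrame = field(default_factory=pd.DataFrame)


def tally(
    events: pd.DataFrame,
    designs: Mapping[str, TrialDesign],
    n_by_group: Mapping[tuple[int, str], int] | None = None,
    frame_rate: float = 50.0,
    n_post_intervals: int = 4,
) -> TallyResult:
    """Count events and responders per ED group × window × interval × behavior.

    ``designs`` maps trial_id → design for every annotated trial. Group
    sizes default to the number of designs per (embryonic_day, group);
    pass ``n_by_group`` when the annotated trials are a subset of the
    group. Events outside every analysis window are returned in
    ``unassigned`` rather than counted.
    """
    for trial in events["trial_id"].unique() if len(events) else []:
        if trial not in designs:
            raise KeyError(f"no trial design for annotated trial {trial!r}")
    L = interval_length(frame_rate, DEFAULT_INTERVAL_S)

    group_of = {
        tid: (d.embryonic_day, d.group) for tid, d in designs.items()
    }
    if n_by_group is None:
        n_by_group = {}
        for key in group_of.values():
            n_by_group[key] = n_by_group.get(key, 0) + 1

    assigned_rows = []
    unassigned_rows = []
    for _, ev in events.iterrows():
        design = designs[ev["trial_id"]]
        slot = _assign_window(int(ev["frame"]), design, L, n_post_intervals)
        if slot is None:
            unassigned_rows.append(dict(ev))
            continue
        window, interval = slot
        ed, group = group_of[ev["trial_id"]]
        assigned_rows.append(
            {
                "embryonic_day": ed,
                "group": group,
                "trial_id": ev["trial_id"],
                "behavior": ev["behavior"],
                "window": window,
                "interval": interval,
            }
        )

    # enumerate all cells so zero-count rows appear for every observed group
    cells = []
    windows = [f"Baseline{k}" for k in STIMULUS_KINDS] + [f"Post{k}" for k in STIMULUS_KINDS]
    intervals_for = {
        w: (["-30-0"] if w.startswith("Baseline")
            else [f"{i * 30}-{(i + 1) * 30}" for i in range(n_post_intervals)])
        for w in windows
    }
    assigned = pd.DataFrame(
        assigned_rows,
        columns=["embryonic_day", "group", "trial_id", "behavior", "window", "interval"],
    )
    for (ed, group), n in sorted(n_by_group.items(), key=lambda kv: (kv[0][0], kv[0][1])):
        for behavior in BEHAVIORS:
            for window in windows:
                for interval in intervals_for[window]:
                    sub = assigned[
                        (assigned["embryonic_day"] == ed)
                        & (assigned["group"] == group)
                        & (assigned["behavior"] == behavior)
                        & (assigned["window"] == window)
                        & (assigned["interval"] == interval)
                    ]
                    responders = sub["trial_id"].nunique()
                    cells.append(
                        {
                            "embryonic_day": ed,
                            "group": group,
                            "behavior": behavior,
                            "window": window,
                            "interval": interval,
                            "event_count": len(sub),
                            "n": n,
                            "responders": responders,
                            "responder_pct": responder_percentage(responders, n),
                        }
                    )
    return TallyResult(
        table=pd.DataFrame(cells),
        unassigned=pd.DataFrame(unassigned_rows, columns=list(events.columns)),
    )


def table2_layout(tally_table: pd.DataFrame) -> pd.DataFrame:
    """Wide responder-percentage table: Baseline/Post(0-30) rows per behavior.

    Mirrors the conventional summary layout: for each behavior and stimulus,
    the single pre-stimulus 30 s and the first post-stimulus 30 s, with ED
    groups as columns.
    """
    sub = tally_table[
        (tally_table["interval"].isin(["-30-0", "0-30"]))
    ].copy()
    sub["phase"] = np.where(sub["window"].str.startswith("Baseline"), "Baseline", "Post")
    sub["stimulus"] = sub["window"].str.replace("Baseline", "").str.replace("Post", "")
    sub["ed_group"] = sub.apply(
        lambda r: f"ED{r['embryonic_day']}"
        + ("" if r["group"] == "plain" else f" {r['group']}"),
        axis=1,
    )
    wide = sub.pivot_table(
        index=["behavior", "phase", "stimulus"],
        columns="ed_group",
        values="responder_pct",
        aggfunc="first",
        sort=False,
    )
    return wide


def detect_candidate_openings(
    series: KinematicSeries,
    threshold: float,
    min_separation: int = 25,
) -> np.ndarray:
    """Advisory beak-opening candidates from the beak-distance series.

    Returns frames where the series crosses ``threshold`` upward (previous
    valid value below, current value at or above), debounced so that two
    candidates are at least ``min_separation`` frames apart. Candidates
    are an annotation aid only — the ethogram statistics use observer
    annotations, never these detections.
    """
    if threshold <= 0:
        raise ParameterError(f"threshold must be positive, got {threshold}")
    v = series.values
    above = v >= threshold  # NaN compares False: a missing frame is never "above"
    below = v < threshold
    crossings = np.flatnonzero(above[1:] & below[:-1]) + 1
    kept: list[int] = []
    for f in crossings:
        if not kept or f - kept[-1] >= min_separation:
            kept.append(int(f))
    return np.asarray(kept, dtype=int)


def write_annotations(events: pd.DataFrame, path: str | Path) -> None:
    events[["trial_id", "behavior", "frame"]].to_csv(path, index=False)
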