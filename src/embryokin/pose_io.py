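"""Pose-track and trial-design I/O.

Pose tracks follow the three-header-row CSV dialect emitted by markerless
pose-estimation software: row 1 ``scorer``, row 2 ``bodyparts``, row 3
``coords`` (an ``x``, ``y``, ``likelihood`` triplet per body part), then one
row per video frame with the frame index in the first column. Coordinates
are pixels in the y-down image convention; likelihoods are confidences in
[0, 1]. A cell may be missing (tracking dropout); missingness is carried as
NaN coordinates and owned by downstream QC rather than rejected at parse
time.

Trial designs describe the experimental timeline of one embryo: a baseline
recording (two minutes for embryonic days 15-18, three minutes for days
9-14), then a noxious mechanical pinch and a light-touch control applied in
randomized order, each followed by an observation window. The analysis
windows (pre-stimulus baseline intervals, post-stimulus intervals aligned
to stimulus release) all derive from these records.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from embryokin.errors import DesignError, FormatError, SchemeError, TrackValidationError

COORDS = ("x", "y", "likelihood")
HEADER_LEVELS = ("scorer", "bodyparts", "coords")

STIMULUS_KINDS = ("Pinch", "Touch")

#: Embryonic days studied; ED10 and ED11 were not part of the staging series.
VALID_EMBRYONIC_DAYS = frozenset({9, 12, 13, 14, 15, 16, 17, 18})


@dataclass
class PoseTrack:
    """Per-frame (x, y, likelihood) series for every tracked body part.

    ``data`` has a two-level column index ``(bodypart, coord)`` with coords
    ``x``, ``y``, ``likelihood`` and a contiguous 0-based frame index. A
    frame of a body part is *missing* when its x or y is NaN.
    """

    trial_id: str
    data: pd.DataFrame
    frame_rate: float = 50.0
    scorer: str = "embryokin"
    parse_report: dict[str, int] = field(default_factory=dict)

    # -- structure -----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def bodyparts(self) -> list[str]:
        return list(self.data.columns.get_level_values(0).unique())

    def _block(self) -> np.ndarray:
        """(n_frames, n_labels, 3) float view sharing memory with ``data``.

        Column order is label-major (x, y, likelihood) per label, which
        both constructors guarantee; the cache makes per-label access and
        masking O(1) in pandas overhead.
        """
        if getattr(self, "_arr", None) is None:
            arr = np.ascontiguousarray(self.data.to_numpy(dtype=float))
            object.__setattr__(self, "_arr", arr)
            self.data = pd.DataFrame(
                arr, index=self.data.index, columns=self.data.columns, copy=False
            )
            object.__setattr__(
                self, "_pos", {lab: i for i, lab in enumerate(self.bodyparts)}
            )
        n_labels = self._arr.shape[1] // 3 if self._arr.ndim == 2 else 0
        return self._arr.reshape(len(self.data), n_labels, 3)

    def _label_index(self, label: str) -> int:
        self._block()
        try:
            return self._pos[label]
        except KeyError:
            raise KeyError(f"body part {label!r} not in track {self.trial_id!r}") from None

    def xy(self, label: str) -> np.ndarray:
        """(n_frames, 2) float array of pixel coordinates; NaN where missing."""
        return self._block()[:, self._label_index(label), :2]

    def likelihood(self, label: str) -> np.ndarray:
        return self._block()[:, self._label_index(label), 2]

    def missing(self, label: str) -> np.ndarray:
        """Boolean mask, True where the body part has no usable coordinate."""
        return np.isnan(self.xy(label)).any(axis=1)

    # -- editing -------------------------------------------------------
    def copy(self) -> "PoseTrack":
        return replace(self, data=self.data.copy(), parse_report=dict(self.parse_report))

    def mask_frames(self, label: str, frames: np.ndarray | Sequence[int]) -> None:
        """Set the given frames of ``label`` to missing (in place)."""
        frames = np.asarray(frames, dtype=int)
        if frames.size == 0:
            return
        if frames.min() < 0 or frames.max() >= self.n_frames:
            raise IndexError(
                f"frame index out of range for track {self.trial_id!r} "
                f"(n_frames={self.n_frames})"
            )
        self._block()[frames, self._label_index(label), :2] = np.nan

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        idx = self.data.index
        if len(idx) and not np.array_equal(idx.to_numpy(), np.arange(len(idx))):
            raise TrackValidationError(
                f"track {self.trial_id!r}: frame indices must be contiguous from 0"
            )
        for label in self.bodyparts:
            cols = tuple(self.data[label].columns)
            if cols != COORDS:
                raise FormatError(
                    f"track {self.trial_id!r}, body part {label!r}: expected "
                    f"column triplet {COORDS}, found {cols}"
                )
            lik = self.likelihood(label)
            present = ~np.isnan(lik)
            bad = present & ((lik < 0) | (lik > 1))
            if bad.any():
                frame = int(np.flatnonzero(bad)[0])
                raise TrackValidationError(
                    f"track {self.trial_id!r}, body part {label!r}, frame {frame}: "
                    f"likelihood {lik[frame]} outside [0, 1]"
                )
            xy = self.xy(label)
            finite = np.isfinite(xy) | np.isnan(xy)
            if not finite.all():
                frame = int(np.flatnonzero(~finite.all(axis=1))[0])
                raise TrackValidationError(
                    f"track {self.trial_id!r}, body part {label!r}, frame {frame}: "
                    "non-finite coordinate"
                )

    def equals(self, other: "PoseTrack") -> bool:
        """Field-for-field equality (NaN-aware on the data block)."""
        return (
            self.trial_id == other.trial_id
            and self.frame_rate == other.frame_rate
            and self.bodyparts == other.bodyparts
            and self.n_frames == other.n_frames
            and bool(
                np.array_equal(
                    self.data.to_numpy(dtype=float),
                    other.data.to_numpy(dtype=float),
                    equal_nan=True,
                )
            )
        )


def build_track(
    trial_id: str,
    arrays: Mapping[str, np.ndarray],
    frame_rate: float = 50.0,
    scorer: str = "embryokin",
) -> PoseTrack:
    """Assemble a :class:`PoseTrack` from per-label (n, 3) arrays.

    Each array holds columns x, y, likelihood. Convenience constructor used
    by the simulator and by tests.
    """
    n = None
    for label, arr in arrays.items():
        arr = np.asarray(arr)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"array for {label!r} must be (n_frames, 3)")
        if n is None:
            n = arr.shape[0]
        elif arr.shape[0] != n:
            raise ValueError("all labels must have identical frame count")
    n = n or 0
    stacked = np.empty((n, 3 * len(arrays)))
    for j, (label, arr) in enumerate(arrays.items()):
        stacked[:, 3 * j : 3 * j + 3] = arr
        # canonical form: a masked frame carries likelihood 0
        bad = np.isnan(stacked[:, 3 * j : 3 * j + 2]).any(axis=1)
        stacked[bad, 3 * j + 2] = 0.0
    columns = pd.MultiIndex.from_product([list(arrays), COORDS])
    data = pd.DataFrame(stacked, index=pd.RangeIndex(n), columns=columns, copy=False)
    track = PoseTrack(trial_id=trial_id, data=data, frame_rate=frame_rate, scorer=scorer)
    track.validate()
    return track


# ---------------------------------------------------------------------------
# pose CSV dialect
# ---------------------------------------------------------------------------

def read_pose_csv(
    path: str | Path | io.IOBase,
    trial_id: str | None = None,
    frame_rate: float = 50.0,
) -> PoseTrack:
    """Read a three-header-row pose CSV into a :class:`PoseTrack`.

    Malformed numeric cells are masked (NaN) and counted per body part in
    ``track.parse_report``; they are never silently dropped, so ``n_frames``
    always equals the number of data rows.
    """
    try:
        raw = pd.read_csv(
            path, header=[0, 1, 2], index_col=0, float_precision="round_trip"
        )
    except (pd.errors.ParserError, ValueError, IndexError) as exc:
        raise FormatError(f"not a three-header-row pose CSV: {exc}") from exc
    if raw.columns.nlevels != 3:
        raise FormatError("pose CSV must have scorer/bodyparts/coords header rows")
    scorers = raw.columns.get_level_values(0).unique()
    if len(scorers) != 1:
        raise FormatError(f"expected a single scorer, found {list(scorers)}")
    scorer = str(scorers[0])

    bodyparts = list(dict.fromkeys(raw.columns.get_level_values(1)))
    parse_report: dict[str, int] = {}
    blocks = []
    for label in bodyparts:
        sub = raw.xs(label, axis=1, level=1)
        coords = tuple(sub.columns.get_level_values(1))
        if coords != COORDS:
            raise FormatError(
                f"body part {label!r}: expected (x, y, likelihood) columns, "
                f"found {coords}"
            )
        def _exact_float(v):
            # float() is correctly rounded, unlike pandas' fast to_numeric path
            try:
                return float(v)
            except (TypeError, ValueError):
                return np.nan

        numeric = sub.copy()
        for col in sub.columns:
            if sub[col].dtype == object:
                numeric[col] = sub[col].map(_exact_float)
        malformed = int((numeric.isna() & sub.notna()).to_numpy().sum())
        if malformed:
            parse_report[label] = malformed
        arr = numeric.to_numpy(dtype=float)
        # a cell lost to parsing has no usable coordinate: mask the frame
        bad_rows = np.isnan(arr[:, :2]).any(axis=1)
        arr[bad_rows, 0] = np.nan
        arr[bad_rows, 1] = np.nan
        blocks.append(arr)

    n = len(raw)
    data = pd.DataFrame(
        np.hstack(blocks) if blocks else np.empty((n, 0)),
        index=pd.RangeIndex(n),
        columns=pd.MultiIndex.from_product([bodyparts, COORDS]),
    )
    if trial_id is None:
        trial_id = Path(path).stem if isinstance(path, (str, Path)) else "track"
    track = PoseTrack(
        trial_id=trial_id,
        data=data,
        frame_rate=frame_rate,
        scorer=scorer,
        parse_report=parse_report,
    )
    track.validate()
    return track


def write_pose_csv(track: PoseTrack, path: str | Path | io.IOBase) -> None:
    """Write the three-header-row dialect.

    Masked frames are written with empty x/y cells and likelihood 0, the
    convention the readers of this dialect expect for unusable detections.
    """
    out = track.data.copy()
    for label in track.bodyparts:
        miss = track.missing(label)
        if miss.any():
            out.loc[miss, (label, "likelihood")] = 0.0
    out.columns = pd.MultiIndex.from_tuples(
        [(track.scorer, bp, c) for bp, c in out.columns], names=HEADER_LEVELS
    )
    out.index.name = None
    csv = out.to_csv()
    # pandas emits a spacer row between the header block and the data when
    # the column index is named; the dialect has none.
    lines = csv.splitlines()
    lines = [ln for i, ln in enumerate(lines) if not (i == 3 and ln.strip(",") == "")]
    text = "\n".join(lines) + "\n"
    if isinstance(path, (str, Path)):
        Path(path).write_text(text)
    else:
        path.write(text)


def read_pose_hdf5(
    path: str | Path,
    trial_id: str | None = None,
    frame_rate: float = 50.0,
    key: str | None = None,
) -> PoseTrack:
    """Read the equivalent HDF5 pose dialect (same contract as the CSV).

    The HDF5 flavor stores one pandas frame with the identical three-level
    (scorer, bodyparts, coords) column index.
    """
    raw = pd.read_hdf(path, key=key) if key else pd.read_hdf(path)
    if not isinstance(raw, pd.DataFrame) or raw.columns.nlevels != 3:
        raise FormatError("pose HDF5 must hold a scorer/bodyparts/coords frame")
    scorers = raw.columns.get_level_values(0).unique()
    if len(scorers) != 1:
        raise FormatError(f"expected a single scorer, found {list(scorers)}")
    bodyparts = list(dict.fromkeys(raw.columns.get_level_values(1)))
    arrays = {}
    for label in bodyparts:
        sub = raw.xs(label, axis=1, level=1)
        coords = tuple(sub.columns.get_level_values(1))
        if coords != COORDS:
            raise FormatError(
                f"body part {label!r}: expected (x, y, likelihood) columns, found {coords}"
            )
        arrays[label] = sub.to_numpy(dtype=float)
    if trial_id is None:
        trial_id = Path(path).stem
    track = build_track(
        trial_id, arrays, frame_rate=frame_rate, scorer=str(scorers[0])
    )
    return track


# ---------------------------------------------------------------------------
# body-part scheme
# ---------------------------------------------------------------------------

BEAK_ROLES = ("beak_upper", "beak_lower", "beak_fulcrum")
MOVEMENT_ROLES = ("eye_corner", "elbow", "leg")


@dataclass(frozen=True)
class BodypartScheme:
    """Maps analysis roles onto the raw body-part labels of a track.

    The leg landmark is the metatarsus from ED12 on; at ED9 the tarsus is
    used instead because the metatarsal tissue is translucent and tracks
    poorly, so ``leg_kind`` must be ``"tarsus"`` for ED9 trials.
    """

    beak_upper: str
    beak_lower: str
    beak_fulcrum: str
    eye_corner: str | None = None
    elbow: str | None = None
    leg: str | None = None
    leg_kind: str = "metatarsus"
    reference_points: tuple[str, ...] = ()

    def __post_init__(self):
        beak = [self.beak_upper, self.beak_lower, self.beak_fulcrum]
        if len(set(beak)) != 3:
            raise SchemeError(f"beak roles must map to distinct labels, got {beak}")
        if self.leg_kind not in ("metatarsus", "tarsus"):
            raise SchemeError(f"leg_kind must be metatarsus or tarsus, got {self.leg_kind!r}")

    def role_map(self) -> dict[str, str]:
        roles = {
            "beak_upper": self.beak_upper,
            "beak_lower": self.beak_lower,
            "beak_fulcrum": self.beak_fulcrum,
        }
        for role in MOVEMENT_ROLES:
            label = getattr(self, role)
            if label is not None:
                roles[role] = label
        return roles


class BoundTrack:
    """Role-resolved view over a :class:`PoseTrack`.

    ``coords("beak_upper")`` returns the series of whatever label the scheme
    mapped to that role; reference-point labels resolve to themselves.
    """

    def __init__(self, track: PoseTrack, scheme: BodypartScheme):
        self.track = track
        self.scheme = scheme
        self._roles = scheme.role_map()

    @property
    def trial_id(self) -> str:
        return self.track.trial_id

    @property
    def frame_rate(self) -> float:
        return self.track.frame_rate

    @property
    def n_frames(self) -> int:
        return self.track.n_frames

    def resolve(self, role: str) -> str:
        if role in self._roles:
            return self._roles[role]
        if role in self.scheme.reference_points:
            return role
        raise SchemeError(
            f"role {role!r} is not bound; bound roles: {sorted(self._roles)}, "
            f"reference points: {list(self.scheme.reference_points)}"
        )

    def coords(self, role: str) -> np.ndarray:
        return self.track.xy(self.resolve(role))

    def missing(self, role: str) -> np.ndarray:
        return self.track.missing(self.resolve(role))


def bind_scheme(
    track: PoseTrack,
    scheme: BodypartScheme,
    embryonic_day: int | None = None,
) -> BoundTrack:
    """Bind a scheme to a track, checking label presence and the ED9 leg rule."""
    labels = set(track.bodyparts)
    wanted = set(scheme.role_map().values()) | set(scheme.reference_points)
    absent = sorted(wanted - labels)
    if absent:
        raise SchemeError(
            f"track {track.trial_id!r} lacks labels {absent}; present: {sorted(labels)}"
        )
    if embryonic_day == 9 and scheme.leg is not None and scheme.leg_kind != "tarsus":
        raise SchemeError(
            "ED9 leg movement must be assessed at the tarsus "
            f"(scheme maps leg to the {scheme.leg_kind})"
        )
    return BoundTrack(track, scheme)


# ---------------------------------------------------------------------------
# trial design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusRecord:
    kind: str  # "Pinch" (noxious mechanical) or "Touch" (light-touch control)
    onset_frame: int
    release_frame: int

    def __post_init__(self):
        if self.kind not in STIMULUS_KINDS:
            raise DesignError(f"stimulus kind must be one of {STIMULUS_KINDS}, got {self.kind!r}")
        if self.release_frame < self.onset_frame:
            raise DesignError(
                f"{self.kind}: release frame {self.release_frame} precedes "
                f"onset frame {self.onset_frame}"
            )


def default_baseline_duration_s(embryonic_day: int) -> float:
    """Baseline recording length: 120 s at ED15-18, 180 s at ED9-14."""
    return 120.0 if embryonic_day >= 15 else 180.0


@dataclass(frozen=True)
class TrialDesign:
    """Timeline of one embryo's trial: one Pinch and one Touch in some order."""

    embryo_id: str
    embryonic_day: int
    stimuli: tuple[StimulusRecord, StimulusRecord]
    group: str = "plain"
    baseline_duration_s: float | None = None
    post_duration_s: float = 120.0

    def __post_init__(self):
        if self.embryonic_day not in VALID_EMBRYONIC_DAYS:
            raise DesignError(
                f"embryonic day must be in {sorted(VALID_EMBRYONIC_DAYS)}, "
                f"got {self.embryonic_day}"
            )
        kinds = sorted(s.kind for s in self.stimuli)
        if kinds != ["Pinch", "Touch"]:
            raise DesignError(f"design needs exactly one Pinch and one Touch, got {kinds}")
        first, second = sorted(self.stimuli, key=lambda s: s.onset_frame)
        if first.release_frame >= second.onset_frame:
            raise DesignError(
                f"embryo {self.embryo_id!r}: stimulus windows overlap "
                f"({first.kind} release {first.release_frame} >= "
                f"{second.kind} onset {second.onset_frame})"
            )
        if self.baseline_duration_s is None:
            object.__setattr__(
                self, "baseline_duration_s", default_baseline_duration_s(self.embryonic_day)
            )

    def stimulus(self, kind: str) -> StimulusRecord:
        for s in self.stimuli:
            if s.kind == kind:
                return s
        raise KeyError(kind)

    @property
    def trial_id(self) -> str:
        return self.embryo_id


def _design_to_dict(d: TrialDesign) -> dict:
    return {
        "embryo_id": d.embryo_id,
        "embryonic_day": int(d.embryonic_day),
        "group": d.group,
        "baseline_duration_s": float(d.baseline_duration_s),
        "post_duration_s": float(d.post_duration_s),
        "stimuli": [
            {
                "kind": s.kind,
                "onset_frame": int(s.onset_frame),
                "release_frame": int(s.release_frame),
            }
            for s in d.stimuli
        ],
    }


def _design_from_dict(rec: dict) -> TrialDesign:
    try:
        stimuli = tuple(
            StimulusRecord(s["kind"], int(s["onset_frame"]), int(s["release_frame"]))
            for s in rec["stimuli"]
        )
        return TrialDesign(
            embryo_id=str(rec["embryo_id"]),
            embryonic_day=int(rec["embryonic_day"]),
            stimuli=stimuli,  # type: ignore[arg-type]
            group=rec.get("group", "plain"),
            baseline_duration_s=rec.get("baseline_duration_s"),
            post_duration_s=rec.get("post_duration_s", 120.0),
        )
    except KeyError as exc:
        raise FormatError(f"trial design record missing field {exc}") from exc


def write_designs(designs: Iterable[TrialDesign], path: str | Path) -> None:
    """Write a cohort's trial designs as one YAML document."""
    doc = {"designs": [_design_to_dict(d) for d in designs]}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_designs(path: str | Path) -> list[TrialDesign]:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "designs" not in doc:
        raise FormatError("trial-design file must be a mapping with a 'designs' list")
    return [_design_from_dict(rec) for rec in doc["designs"]]
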