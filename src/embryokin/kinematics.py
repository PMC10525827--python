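"""Per-frame kinematic parameters.

Three parameters quantify embryo movement from the tracked landmarks:

* **beak distance** — Euclidean gap in pixels between the upper and lower
  beak tips, ``d = sqrt((xu - xl)^2 + (yu - yl)^2)``, one value per frame;
* **beak angle** — unsigned angle in degrees at the beak fulcrum P0
  between the rays P0→P1 (upper tip) and P0→P2 (lower tip), computed from
  the unit vectors n1, n2 as ``atan2(|det[n2 n1]|, n2·n1)`` and converted
  to degrees, hence in [0, 180];
* **movement** — Euclidean displacement in pixels of one landmark between
  strictly consecutive frames; entry ``t`` spans frames ``t`` and
  ``t + 1``, so the series has ``n_frames - 1`` entries. Displacement is
  never computed across a masked gap.

Every parameter propagates missingness: a frame's value is missing
whenever any landmark it depends on is missing that frame. A degenerate
angle frame (P1 or P2 coincides with P0) is missing as well — the angle is
undefined there and a substituted 0 would bias interval sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from embryokin.pose_io import BoundTrack


@dataclass
class KinematicSeries:
    """One per-frame parameter for one trial; NaN marks missing frames."""

    trial_id: str
    parameter: str
    unit: str  # "px" or "deg"
    values: np.ndarray
    frame_rate: float

    @property
    def n(self) -> int:
        return len(self.values)

    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": self.trial_id,
                "parameter": self.parameter,
                "frame": np.arange(self.n),
                "value": self.values,
            }
        )


def beak_distance(view: BoundTrack) -> KinematicSeries:
    """Pixel gap between the upper and lower beak tips, per frame."""
    upper = view.coords("beak_upper")
    lower = view.coords("beak_lower")
    diff = upper - lower
    # literal sqrt-of-squares: bit-reproducible against scalar recomputation
    values = np.sqrt(diff[:, 0] * diff[:, 0] + diff[:, 1] * diff[:, 1])
    return KinematicSeries(view.trial_id, "beak_distance", "px", values, view.frame_rate)


def beak_angle(view: BoundTrack) -> KinematicSeries:
    """Unsigned fulcrum angle between the beak tips, in degrees.

    Uses the numerically stable four-quadrant form on the unit vectors:
    ``atan2(|n2_x n1_y - n2_y n1_x|, n2·n1)``. The absolute determinant
    makes the result orientation-free, so it lands in [0, 180] regardless
    of labeling order or image-axis convention.
    """
    p0 = view.coords("beak_fulcrum")
    p1 = view.coords("beak_upper")
    p2 = view.coords("beak_lower")
    v1 = p1 - p0
    v2 = p2 - p0
    n1len = np.hypot(v1[:, 0], v1[:, 1])
    n2len = np.hypot(v2[:, 0], v2[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        n1 = v1 / n1len[:, None]
        n2 = v2 / n2len[:, None]
        det = n2[:, 0] * n1[:, 1] - n2[:, 1] * n1[:, 0]
        dot = n2[:, 0] * n1[:, 0] + n2[:, 1] * n1[:, 1]
        values = np.degrees(np.arctan2(np.abs(det), dot))
    values[(n1len == 0) | (n2len == 0)] = np.nan
    return KinematicSeries(view.trial_id, "beak_angle", "deg", values, view.frame_rate)


def movement(view: BoundTrack, role: str) -> KinematicSeries:
    """Frame-to-frame displacement of one landmark, in pixels.

    ``role`` is one of the movement roles (eye_corner, elbow, leg) or a
    reference-point label. Entry ``t`` is missing if frame ``t`` or
    ``t + 1`` of the landmark is missing.
    """
    xy = view.coords(role)
    diff = xy[1:] - xy[:-1]
    values = np.sqrt(diff[:, 0] * diff[:, 0] + diff[:, 1] * diff[:, 1])
    return KinematicSeries(
        view.trial_id, f"movement:{role}", "px", values, view.frame_rate
    )


def all_parameters(view: BoundTrack, roles: tuple[str, ...] | None = None) -> list[KinematicSeries]:
    """Beak distance, beak angle, and movement for every bound movement role."""
    series = [beak_distance(view), beak_angle(view)]
    if roles is None:
        roles = tuple(
            r for r in ("eye_corner", "elbow", "leg") if getattr(view.scheme, r) is not None
        )
    for role in roles:
        series.append(movement(view, role))
    return series
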