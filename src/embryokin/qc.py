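"""Quality control preceding all kinematics.

Two mechanisms mask unreliable detections before any parameter is
computed:

* a likelihood cutoff (default 0.75): a frame whose confidence falls
  below the cutoff is treated as missing;
* outlier exclusion: frames whose coordinates sit far outside the body
  part's spatial data cluster. Such screening is traditionally done by
  eye, excluding offending frames by hand; here the screen is reproducible —
  either an explicit per-label frame list, or a robust distance rule that
  flags frames more than ``k`` scaled-MAD units from the label's spatial
  median. Flags are advisory until applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from embryokin.errors import ParameterError
from embryokin.pose_io import PoseTrack

DEFAULT_LIKELIHOOD_CUTOFF = 0.75

#: consistency factor making the MAD estimate the SD under normality
_MAD_SCALE = 1.4826


@dataclass
class QCReport:
    """Per-label masking bookkeeping for one track."""

    trial_id: str
    n_frames: int
    cutoff_masked: dict[str, int] = field(default_factory=dict)
    outlier_masked: dict[str, int] = field(default_factory=dict)
    missing_fraction: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        labels = sorted(
            set(self.cutoff_masked) | set(self.outlier_masked) | set(self.missing_fraction)
        )
        return pd.DataFrame(
            {
                "trial_id": self.trial_id,
                "bodypart": labels,
                "cutoff_masked": [self.cutoff_masked.get(b, 0) for b in labels],
                "outlier_masked": [self.outlier_masked.get(b, 0) for b in labels],
                "missing_fraction": [self.missing_fraction.get(b, 0.0) for b in labels],
            }
        )


def _refresh_fractions(track: PoseTrack, report: QCReport) -> None:
    n = max(track.n_frames, 1)
    miss = np.isnan(track._block()[:, :, :2]).any(axis=2).sum(axis=0)
    for j, label in enumerate(track.bodyparts):
        report.missing_fraction[label] = float(miss[j]) / n


def apply_likelihood_cutoff(
    track: PoseTrack,
    cutoff: float = DEFAULT_LIKELIHOOD_CUTOFF,
    report: QCReport | None = None,
) -> tuple[PoseTrack, QCReport]:
    """Mask every frame whose likelihood is strictly below ``cutoff``.

    A frame at exactly the cutoff is retained. Returns a new track; the
    input is untouched. Likelihood values themselves are preserved, so the
    operation is monotone: raising the cutoff can only mask more frames.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ParameterError(f"likelihood cutoff must lie in [0, 1], got {cutoff}")
    out = track.copy()
    if report is None:
        report = QCReport(trial_id=track.trial_id, n_frames=track.n_frames)
    block = out._block()  # (n, labels, 3), shared with out.data
    lik = block[:, :, 2]
    already = np.isnan(block[:, :, :2]).any(axis=2)
    low = ~already & ~np.isnan(lik) & (lik < cutoff)
    block[:, :, 0][low] = np.nan
    block[:, :, 1][low] = np.nan
    counts = low.sum(axis=0)
    for j, label in enumerate(out.bodyparts):
        report.cutoff_masked[label] = report.cutoff_masked.get(label, 0) + int(counts[j])
    _refresh_fractions(out, report)
    return out, report


def flag_outliers(
    track: PoseTrack,
    manual: Mapping[str, Sequence[int]] | None = None,
    k: float = 6.0,
    labels: Sequence[str] | None = None,
) -> dict[str, np.ndarray]:
    """Flag frames lying outside a body part's spatial data cluster.

    ``manual`` frame lists pass through verbatim (validated against the
    frame range). Otherwise each label's cluster is screened with a robust
    rule: a frame is flagged when (a) its standardized distance from the
    spatial median exceeds ``k``, standardizing each axis by its scaled
    median absolute deviation, and (b) it is a temporal discontinuity —
    the jumps into and out of the frame both exceed ``k`` times the robust
    scale of the label's frame-to-frame displacements. Condition (b)
    separates single-frame tracking teleports from genuine movement,
    which changes position smoothly even when it strays far from the
    spatial median. An axis whose MAD is zero (stationary coordinate) is
    skipped, and a label with both MADs zero is never flagged, so pinned
    reference points cannot generate false positives.
    """
    if manual is not None:
        flags = {}
        for label, frames in manual.items():
            frames = np.asarray(sorted(set(int(f) for f in frames)), dtype=int)
            if frames.size and (frames.min() < 0 or frames.max() >= track.n_frames):
                raise IndexError(
                    f"manual outlier frame out of range for {label!r} "
                    f"(n_frames={track.n_frames})"
                )
            flags[label] = frames
        return flags

    if k <= 0:
        raise ParameterError(f"outlier threshold k must be positive, got {k}")
    flags = {}
    for label in labels if labels is not None else track.bodyparts:
        xy = track.xy(label)
        ok = ~np.isnan(xy).any(axis=1)
        if ok.sum() < 3:
            flags[label] = np.empty(0, dtype=int)
            continue
        pts = xy[ok]
        med = np.median(pts, axis=0)
        mad = np.median(np.abs(pts - med), axis=0) * _MAD_SCALE
        live = mad > 0
        if not live.any():
            flags[label] = np.empty(0, dtype=int)
            continue
        z2 = np.zeros(len(pts))
        for ax in np.flatnonzero(live):
            z2 += ((pts[:, ax] - med[ax]) / mad[ax]) ** 2
        far = np.sqrt(z2) > k

        # temporal discontinuity between consecutive valid frames
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        step_scale = np.median(steps) + np.median(np.abs(steps - np.median(steps))) * _MAD_SCALE \
            if steps.size else 0.0
        if step_scale == 0:
            jumpy = steps > 0  # any motion of an otherwise frozen label is a jump
        else:
            jumpy = steps > k * step_scale
        jump_in = np.concatenate([[True], jumpy])  # first frame: no way in, treat as jump
        jump_out = np.concatenate([jumpy, [True]])
        flags[label] = np.flatnonzero(ok)[far & jump_in & jump_out]
    return flags


def apply_exclusions(
    track: PoseTrack,
    flags: Mapping[str, np.ndarray | Sequence[int]],
    report: QCReport | None = None,
) -> tuple[PoseTrack, QCReport]:
    """Mask flagged (label, frame) entries. Idempotent; returns a new track."""
    out = track.copy()
    if report is None:
        report = QCReport(trial_id=track.trial_id, n_frames=track.n_frames)
    for label, frames in flags.items():
        frames = np.asarray(frames, dtype=int)
        if frames.size:
            xy = out.xy(label)
            newly = frames[~np.isnan(xy[frames]).any(axis=1)]
        else:
            newly = frames
        out.mask_frames(label, newly)
        report.outlier_masked[label] = report.outlier_masked.get(label, 0) + int(newly.size)
    _refresh_fractions(out, report)
    return out, report


def export_cluster_scatter(
    track: PoseTrack,
    outdir,
    flags: Mapping[str, np.ndarray] | None = None,
    labels: Sequence[str] | None = None,
) -> list:
    """Static x-y scatter per body part for visual audit of the data clusters.

    Mirrors the visual screening step: one PNG per label, with any flagged
    outlier frames highlighted. Returns the written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for label in labels if labels is not None else track.bodyparts:
        xy = track.xy(label)
        ok = ~np.isnan(xy).any(axis=1)
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(xy[ok, 0], xy[ok, 1], s=2, alpha=0.4, label="frames")
        if flags and label in flags and len(flags[label]):
            fx = xy[np.asarray(flags[label], dtype=int)]
            ax.scatter(fx[:, 0], fx[:, 1], s=14, color="red", label="flagged")
            ax.legend(frameon=False, fontsize=8)
        ax.invert_yaxis()  # image convention: y grows downward
        ax.set_xlabel("x [px]")
        ax.set_ylabel("y [px]")
        ax.set_title(f"{track.trial_id}: {label}")
        path = outdir / f"{track.trial_id}_{label}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written


def preprocess(
    track: PoseTrack,
    cutoff: float = DEFAULT_LIKELIHOOD_CUTOFF,
    outlier_k: float | None = 6.0,
    manual: Mapping[str, Sequence[int]] | None = None,
    labels: Sequence[str] | None = None,
) -> tuple[PoseTrack, QCReport]:
    """Cutoff then outlier exclusion, sharing one report.

    ``labels`` restricts the automatic outlier screen to the body parts
    that feed the downstream analysis; the cutoff always applies to all.
    """
    out, report = apply_likelihood_cutoff(track, cutoff)
    if manual is not None:
        flags = flag_outliers(out, manual=manual)
        out, report = apply_exclusions(out, flags, report)
    elif outlier_k is not None:
        flags = flag_outliers(out, k=outlier_k, labels=labels)
        out, report = apply_exclusions(out, flags, report)
    return out, report
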