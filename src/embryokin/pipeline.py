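"""End-to-end orchestration: simulate/load → QC → kinematics → intervals →
contrasts → ethogram tally, with a run manifest.

A run is deterministic given its seed and writes each artifact exactly
once into the run directory:

* ``qc_report.csv`` — per-trial, per-label masking counts;
* ``kinematics.csv`` — tidy per-frame parameter values;
* ``intervals.csv`` — per 30-s interval sums, missing fractions, flags;
* ``contrasts.csv`` — window contrasts (mixed model and/or permutation);
* ``tally.csv`` — ethogram counts and responder percentages;
* ``manifest.yaml`` — every analysis parameter and package version.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from embryokin import __version__
from embryokin.errors import EmbryokinError, ParameterError
from embryokin.ethogram import tally
from embryokin.kinematics import KinematicSeries, all_parameters
from embryokin.pose_io import bind_scheme, read_designs, read_pose_csv
from embryokin.qc import preprocess
from embryokin.simulate import (
    SimParams,
    ground_truth_annotations,
    scheme_for,
    simulate_cohort,
)
from embryokin.stats import (
    default_comparisons,
    fit_repeated_model,
    marginal_contrasts,
    permutation_contrasts,
)
from embryokin.windowing import build_interval_table, summarize_cohort


@dataclass
class RunConfig:
    """All knobs of one reproducible pipeline run."""

    outdir: str = "run"
    seed: int = 0
    input_dir: str | None = None  # read pose CSVs + designs.yaml instead of simulating
    annotations: str | None = None  # observer event CSV; default: ground-truth events
    n_embryos: int = 16
    embryonic_day: int = 16
    frame_rate: float = 50.0
    likelihood_cutoff: float = 0.75
    outlier_k: float | None = 6.0
    interval_s: float = 30.0
    max_missing_fraction: float = 0.05
    alpha: float = 0.05
    stats_method: str = "both"  # lmm | perm | both
    n_perm: int = 2000
    sim_overrides: dict = field(default_factory=dict)
    force: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.likelihood_cutoff <= 1.0:
            raise ParameterError(
                f"likelihood cutoff must lie in [0, 1], got {self.likelihood_cutoff}"
            )
        if self.stats_method not in ("lmm", "perm", "both"):
            raise ParameterError(f"unknown stats method {self.stats_method!r}")
        if not 0 < self.alpha < 1:
            raise ParameterError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.interval_s <= 0:
            raise ParameterError(f"interval length must be positive, got {self.interval_s}")


class StageError(EmbryokinError):
    """Wraps a failure with the pipeline stage (and trial) where it occurred."""


def _stage(stage: str, trial: str | None = None):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                where = f"stage {stage!r}" + (f", trial {trial!r}" if trial else "")
                raise StageError(f"{where}: {exc}") from exc
            return False

    return _Ctx()


def _write_once(df_or_text, path: Path, force: bool) -> None:
    if path.exists() and not force:
        raise FileExistsError(f"{path} already exists; outputs are write-once per run")
    if isinstance(df_or_text, pd.DataFrame):
        df_or_text.to_csv(path, index=False)
    else:
        path.write_text(df_or_text)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the result bundle in memory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- inputs ----------------------------------------------------------
    params = SimParams(
        n_embryos=config.n_embryos,
        embryonic_day=config.embryonic_day,
        frame_rate=config.frame_rate,
        **config.sim_overrides,
    )
    scheme = scheme_for(params)
    annotations = None
    if config.input_dir is not None:
        with _stage("load"):
            indir = Path(config.input_dir)
            designs = {d.embryo_id: d for d in read_designs(indir / "designs.yaml")}
            tracks = [
                read_pose_csv(indir / f"{tid}.csv", trial_id=tid,
                              frame_rate=config.frame_rate)
                for tid in designs
            ]
    else:
        with _stage("simulate"):
            cohort = simulate_cohort(params, seed=config.seed)
            tracks, designs = cohort.tracks, cohort.designs
            annotations = ground_truth_annotations(cohort.truths)

    # --- QC --------------------------------------------------------------
    clean_tracks = []
    qc_frames = []
    for track in tracks:
        with _stage("preprocess", track.trial_id):
            clean, report = preprocess(
                track, cutoff=config.likelihood_cutoff, outlier_k=config.outlier_k
            )
            clean_tracks.append(clean)
            qc_frames.append(report.to_frame())
    qc_table = pd.concat(qc_frames, ignore_index=True)

    # --- kinematics ------------------------------------------------------
    series_by_trial: dict[str, list[KinematicSeries]] = {}
    kin_frames = []
    for clean in clean_tracks:
        with _stage("kinematics", clean.trial_id):
            design = designs[clean.trial_id]
            view = bind_scheme(clean, scheme, embryonic_day=design.embryonic_day)
            series = all_parameters(view)
            series_by_trial[clean.trial_id] = series
            kin_frames.extend(s.to_frame() for s in series)
    kin_table = pd.concat(kin_frames, ignore_index=True)

    # --- windowing -------------------------------------------------------
    with _stage("aggregate"):
        summary = summarize_cohort(
            series_by_trial, designs, config.interval_s, config.max_missing_fraction
        )
        interval_table = build_interval_table(summary)

    # --- statistics ------------------------------------------------------
    contrast_frames = []
    for parameter in sorted(interval_table["parameter"].unique()):
        sub = interval_table[interval_table["parameter"] == parameter]
        comparisons = default_comparisons("PostPinch")
        present = set(sub["window"].astype(str) + ":" + sub["interval"].astype(str))
        comparisons = [c for c in comparisons if c[0] in present and c[1] in present]
        if not comparisons:
            continue
        with _stage("stats"):
            if config.stats_method in ("lmm", "both"):
                model = fit_repeated_model(sub, parameter=parameter)
                lmm = marginal_contrasts(model, comparisons, alpha=config.alpha)
                lmm.insert(0, "method", "lmm")
                contrast_frames.append(lmm)
            if config.stats_method in ("perm", "both"):
                perm = permutation_contrasts(
                    sub, comparisons, n_perm=config.n_perm,
                    seed=config.seed, parameter=parameter, alpha=config.alpha,
                )
                perm.insert(0, "method", "perm")
                contrast_frames.append(perm)
    contrast_table = (
        pd.concat(contrast_frames, ignore_index=True) if contrast_frames else pd.DataFrame()
    )

    # --- ethogram --------------------------------------------------------
    with _stage("ethogram"):
        if config.annotations is not None:
            from embryokin.ethogram import read_annotations

            annotations = read_annotations(config.annotations)
        if annotations is None or annotations.empty:
            tally_table = pd.DataFrame()
        else:
            result = tally(annotations, designs, frame_rate=config.frame_rate)
            tally_table = result.table

    # --- outputs ---------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_embryos": len(tracks),
        "embryonic_day": config.embryonic_day,
        "frame_rate": config.frame_rate,
        "likelihood_cutoff": config.likelihood_cutoff,
        "outlier_k": config.outlier_k,
        "interval_s": config.interval_s,
        "frames_per_interval": int(round(config.interval_s * config.frame_rate)),
        "max_missing_fraction": config.max_missing_fraction,
        "alpha": config.alpha,
        "stats_method": config.stats_method,
        "n_perm": config.n_perm,
        "input_dir": config.input_dir,
        "sim_overrides": dict(config.sim_overrides),
    }
    _write_once(qc_table, outdir / "qc_report.csv", config.force)
    _write_once(kin_table, outdir / "kinematics.csv", config.force)
    _write_once(summary, outdir / "intervals.csv", config.force)
    _write_once(contrast_table, outdir / "contrasts.csv", config.force)
    _write_once(tally_table, outdir / "tally.csv", config.force)
    _write_once(yaml.safe_dump(manifest, sort_keys=True), outdir / "manifest.yaml", config.force)
    return {
        "qc": qc_table,
        "kinematics": kin_table,
        "intervals": summary,
        "interval_table": interval_table,
        "contrasts": contrast_table,
        "tally": tally_table,
        "manifest": manifest,
    }
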