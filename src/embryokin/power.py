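"""Simulation-based calibration of the analysis chain.

Two questions a repeated-measures pipeline must answer before its
contrasts can be trusted:

* **Power / parameter recovery** — when a pinch-evoked beak-opening
  response of known size is injected into a simulated cohort, does the
  full chain (likelihood cutoff → outlier screen → beak distance → 30-s
  interval sums → baseline median → paired contrasts) recover it as a
  significant pinch-vs-baseline and pinch-vs-touch difference at 0–30 s?
* **Type-I calibration** — under a true null (no condition difference),
  does the paired sign-flip permutation test reject at its nominal rate?

Both are answered by running the real pipeline on the generator's output,
never by shortcuts through internal state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from embryokin.kinematics import beak_distance
from embryokin.pose_io import bind_scheme
from embryokin.qc import preprocess
from embryokin.simulate import SimParams, scheme_for, simulate_cohort
from embryokin.stats import permutation_contrast, permutation_contrasts
from embryokin.windowing import build_interval_table, summarize_cohort

PINCH_RECOVERY_COMPARISONS = (
    ("PostPinch:0-30", "BaselinePinch:BL"),
    ("PostPinch:0-30", "PostTouch:0-30"),
)

#: body parts whose clusters matter for the beak-distance chain
_BEAK_LABELS = ("beak_upper", "beak_lower", "beak_fulcrum")


def beak_interval_table(
    params: SimParams,
    seed: int,
    cutoff: float = 0.75,
    outlier_k: float | None = 6.0,
) -> pd.DataFrame:
    """Simulate a cohort and push it through QC → beak distance → intervals."""
    cohort = simulate_cohort(params, seed=seed)
    scheme = scheme_for(params)
    series = {}
    for track in cohort.tracks:
        clean, _ = preprocess(track, cutoff=cutoff, outlier_k=outlier_k,
                              labels=_BEAK_LABELS)
        view = bind_scheme(clean, scheme, embryonic_day=params.embryonic_day)
        series[track.trial_id] = [beak_distance(view)]
    summary = summarize_cohort(series, cohort.designs)
    return build_interval_table(summary)


def pinch_recovery_replicate(
    seed: int,
    params: SimParams | None = None,
    n_perm: int = 500,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One simulated cohort: adjusted p-values for the 0–30 s pinch contrasts."""
    params = params or SimParams()
    table = beak_interval_table(params, seed)
    return permutation_contrasts(
        table,
        list(PINCH_RECOVERY_COMPARISONS),
        n_perm=n_perm,
        seed=seed,
        parameter="beak_distance",
        alpha=alpha,
    )


def pinch_recovery_rate(
    n_replicates: int = 200,
    base_seed: int = 0,
    params: SimParams | None = None,
    n_perm: int = 500,
    alpha: float = 0.05,
) -> dict:
    """Fraction of replicate cohorts where both 0–30 s contrasts are significant."""
    both = 0
    vs_baseline = 0
    vs_touch = 0
    for i in range(n_replicates):
        res = pinch_recovery_replicate(base_seed + i, params, n_perm, alpha)
        sig = res["significant"].to_numpy()
        vs_baseline += int(sig[0])
        vs_touch += int(sig[1])
        both += int(sig.all())
    return {
        "n_replicates": n_replicates,
        "power_both": both / n_replicates,
        "power_vs_baseline": vs_baseline / n_replicates,
        "power_vs_touch": vs_touch / n_replicates,
    }


def _null_table(rng: np.random.Generator, n_embryos: int) -> pd.DataFrame:
    """Paired interval sums with embryo offsets but no condition effect."""
    offsets = rng.normal(0.0, 2.0, size=n_embryos)
    rows = []
    for i in range(n_embryos):
        for cell in ("PostPinch:0-30", "BaselinePinch:BL"):
            window, interval = cell.split(":")
            rows.append(
                {
                    "embryo_id": f"e{i:02d}",
                    "window": window,
                    "interval": interval,
                    "sum": 30000.0 + 1500.0 * offsets[i] + rng.normal(0.0, 300.0),
                }
            )
    return pd.DataFrame(rows)


def permutation_type_i_error(
    n_replicates: int = 1000,
    seed: int = 0,
    n_embryos: int = 16,
    n_perm: int = 500,
    alpha: float = 0.05,
) -> dict:
    """Empirical rejection rate of the paired permutation test under the null.

    Each replicate draws paired interval sums with embryo-level offsets but
    identical condition means, then tests pinch-post against baseline. The
    returned rate should sit inside the binomial sampling band around
    ``alpha``.
    """
    root = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        table = _null_table(root, n_embryos)
        res = permutation_contrast(
            table,
            ("PostPinch:0-30", "BaselinePinch:BL"),
            n_perm=n_perm,
            seed=int(root.integers(0, 2**31)),
        )
        rejections += int(res["p"] < alpha)
    rate = rejections / n_replicates
    se = float(np.sqrt(alpha * (1 - alpha) / n_replicates))
    return {
        "n_replicates": n_replicates,
        "alpha": alpha,
        "rejection_rate": rate,
        "binomial_ci_low": alpha - 1.96 * se,
        "binomial_ci_high": alpha + 1.96 * se,
    }
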