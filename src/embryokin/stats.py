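"""Repeated-measures contrasts between analysis windows.

Interval sums from one embryo are correlated, so window × interval cell
means are estimated with a linear mixed model: response = interval sum,
fixed effect = cell (one mean per window × interval combination), random
intercept = embryo. Pairwise differences of the estimated cell means are
then tested with a family-wise multiplicity adjustment in the style of
Tukey's method: each contrast's p-value is referred to the distribution of
the maximum absolute t statistic over the declared comparison family,
evaluated under the joint multivariate-t law implied by the estimated
contrast correlations.

Robust (Huberized) mixed-model fits are a common choice for data like
these; here the model is an ordinary REML fit, and a paired sign-flip
permutation test is provided as the distribution-free robust companion:
within-embryo differences are randomly sign-flipped, and max-|T| over a
family yields family-wise adjusted p-values without distributional
assumptions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.regression.mixed_linear_model import MixedLM

from embryokin.errors import DegenerateDesignError, ParameterError

DEFAULT_ALPHA = 0.05

Comparison = tuple[str, str]  # (cell_a, cell_b): estimate = mean_a - mean_b


def cell_label(window: str, interval: str) -> str:
    return f"{window}:{interval}"


@dataclass
class FittedCellMeans:
    """Cell means and their covariance from the mixed-model fit."""

    parameter: str
    cells: list[str]
    means: np.ndarray  # (k,)
    cov: np.ndarray  # (k, k) covariance of the estimated means
    df: float  # denominator degrees of freedom for t references
    resid_var: float
    embryo_var: float  # random-intercept variance
    n_embryos: int
    n_obs: int
    converged: bool = True
    extra: dict = field(default_factory=dict)

    def mean(self, cell: str) -> float:
        return float(self.means[self._index(cell)])

    def _index(self, cell: str) -> int:
        try:
            return self.cells.index(cell)
        except ValueError:
            raise ValueError(
                f"cell {cell!r} not present in the fitted model; "
                f"available cells: {self.cells}"
            ) from None


def _cells_column(table: pd.DataFrame) -> pd.Series:
    return table["window"].astype(str) + ":" + table["interval"].astype(str)


def fit_repeated_model(
    table: pd.DataFrame,
    parameter: str | None = None,
) -> FittedCellMeans:
    """Fit the random-intercept cell-means model to an interval table.

    ``table`` needs columns ``embryo_id``, ``window``, ``interval`` and
    ``sum`` (plus ``parameter`` if several parameters are stacked).
    Excluded intervals must already be absent. At least two embryos are
    required; with one embryo the random intercept is confounded with the
    residual and the design is degenerate.
    """
    df = table.copy()
    if parameter is not None:
        df = df[df["parameter"] == parameter]
    elif "parameter" in df.columns:
        params = df["parameter"].unique()
        if len(params) > 1:
            raise ValueError(
                f"table mixes parameters {list(params)}; pass parameter= to select one"
            )
        parameter = params[0] if len(params) else "value"
    df = df.dropna(subset=["sum"])
    n_embryos = df["embryo_id"].nunique()
    if n_embryos < 2:
        raise DegenerateDesignError(
            f"mixed model needs >= 2 embryos, got {n_embryos}: the embryo random "
            "intercept cannot be separated from the residual"
        )
    cells_series = _cells_column(df)
    cells = sorted(cells_series.unique())
    exog = pd.get_dummies(
        pd.Categorical(cells_series, categories=cells), dtype=float
    ).to_numpy()
    endog = df["sum"].to_numpy(dtype=float)
    groups = df["embryo_id"].to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(endog, exog, groups=groups)
        result = model.fit(reml=True, method=["lbfgs", "bfgs"])
    means = np.asarray(result.fe_params, dtype=float)
    cov = np.asarray(result.cov_params())[: len(cells), : len(cells)]
    resid_var = float(result.scale)
    # statsmodels reports cov_re on the response scale
    embryo_var = float(np.asarray(result.cov_re).ravel()[0]) if result.cov_re.size else 0.0
    # containment-style denominator df: observations minus cells minus embryos
    ddf = max(float(len(df) - len(cells) - (n_embryos - 1)), 1.0)
    return FittedCellMeans(
        parameter=parameter or "value",
        cells=cells,
        means=means,
        cov=cov,
        df=ddf,
        resid_var=resid_var,
        embryo_var=embryo_var,
        n_embryos=int(n_embryos),
        n_obs=int(len(df)),
        converged=bool(result.converged),
    )


def _max_t_adjust(tstats: np.ndarray, corr: np.ndarray, df: float) -> np.ndarray:
    """P(max_j |T_j| >= |t_i|) under the joint multivariate-t with correlation ``corr``."""
    m = len(tstats)
    out = np.empty(m)
    dist = st.multivariate_t(shape=corr, df=df, allow_singular=True)
    for i, t in enumerate(np.abs(tstats)):
        if not np.isfinite(t):
            out[i] = 0.0 if t > 0 else 1.0
            continue
        # QMC integration; fixed random_state keeps results reproducible
        p_inside = float(
            dist.cdf(np.full(m, t), lower_limit=np.full(m, -t), random_state=12345)
        )
        out[i] = min(max(1.0 - p_inside, 0.0), 1.0)
    return out


def marginal_contrasts(
    model: FittedCellMeans,
    comparisons: Sequence[Comparison],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Pairwise differences of cell means with family-wise adjustment.

    Each requested comparison ``(cell_a, cell_b)`` yields the estimate
    ``mean_a - mean_b``, its standard error, an unadjusted two-sided
    t-based p-value, and a Tukey-style adjusted p-value over the whole
    family (single-comparison families are left unadjusted). The
    ``significant`` flag is ``p_adj < alpha``.
    """
    if not comparisons:
        return pd.DataFrame(
            columns=[
                "parameter", "cell_a", "cell_b", "estimate", "se", "t", "df",
                "p_unadj", "p_adj", "significant",
            ]
        )
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    k = len(model.cells)
    C = np.zeros((len(comparisons), k))
    for i, (a, b) in enumerate(comparisons):
        C[i, model._index(a)] = 1.0
        C[i, model._index(b)] = -1.0
    est = C @ model.means
    vcov = C @ model.cov @ C.T
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, est / se, np.where(est == 0, 0.0, np.inf))
    p_unadj = 2.0 * st.t.sf(np.abs(tstat), model.df)

    if len(comparisons) == 1:
        p_adj = p_unadj.copy()
    else:
        d = np.where(se > 0, se, 1.0)
        corr = vcov / np.outer(d, d)
        corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(corr, 1.0)
        p_adj = _max_t_adjust(tstat, corr, model.df)
        p_adj = np.maximum(p_adj, p_unadj)  # adjustment can only be conservative
    return pd.DataFrame(
        {
            "parameter": model.parameter,
            "cell_a": [c[0] for c in comparisons],
            "cell_b": [c[1] for c in comparisons],
            "estimate": est,
            "se": se,
            "t": tstat,
            "df": model.df,
            "p_unadj": p_unadj,
            "p_adj": np.minimum(p_adj, 1.0),
            "significant": np.minimum(p_adj, 1.0) < alpha,
        }
    )


# ---------------------------------------------------------------------------
# paired sign-flip permutation
# ---------------------------------------------------------------------------

def _paired_diffs(
    table: pd.DataFrame, comparison: Comparison, parameter: str | None
) -> tuple[np.ndarray, list]:
    df = table.copy()
    if parameter is not None:
        df = df[df["parameter"] == parameter]
    cells = _cells_column(df)
    a, b = comparison
    da = df[cells == a].set_index("embryo_id")["sum"]
    db = df[cells == b].set_index("embryo_id")["sum"]
    common = sorted(set(da.index) & set(db.index))
    if not common:
        raise ValueError(f"no embryo has data in both {a!r} and {b!r}")
    diffs = (da.loc[common] - db.loc[common]).to_numpy(dtype=float)
    return diffs, common


def permutation_contrast(
    table: pd.DataFrame,
    comparison: Comparison,
    n_perm: int = 10000,
    seed: int | None = None,
    parameter: str | None = None,
) -> dict:
    """Paired sign-flip permutation test of one within-embryo comparison.

    The statistic is the mean within-embryo difference. Under the null of
    exchangeable signs, each embryo's difference is flipped with
    probability 1/2; ``p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ParameterError(f"n_perm must be at least 100, got {n_perm}")
    diffs, embryos = _paired_diffs(table, comparison, parameter)
    rng = np.random.default_rng(seed)
    t_obs = float(diffs.mean())
    flips = rng.integers(0, 2, size=(n_perm, diffs.size)) * 2 - 1
    t_perm = (flips * diffs).mean(axis=1)
    p = (1.0 + np.count_nonzero(np.abs(t_perm) >= abs(t_obs))) / (1.0 + n_perm)
    return {
        "comparison": comparison,
        "estimate": t_obs,
        "p": float(p),
        "n_embryos": len(embryos),
        "n_perm": int(n_perm),
    }


def permutation_contrasts(
    table: pd.DataFrame,
    comparisons: Sequence[Comparison],
    n_perm: int = 10000,
    seed: int | None = None,
    parameter: str | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Family of paired permutation tests with max-|T| family-wise adjustment.

    One shared set of sign flips (per embryo, consistent across
    comparisons) drives every test; the adjusted p-value refers each
    observed statistic to the permutation distribution of the familywise
    maximum, controlling the family-wise error rate strongly.
    """
    if n_perm < 100:
        raise ParameterError(f"n_perm must be at least 100, got {n_perm}")
    per_comp = [_paired_diffs(table, c, parameter) for c in comparisons]
    embryos = sorted({e for _, em in per_comp for e in em})
    index = {e: i for i, e in enumerate(embryos)}
    rng = np.random.default_rng(seed)
    flips = rng.integers(0, 2, size=(n_perm, len(embryos))) * 2 - 1

    t_obs = np.empty(len(comparisons))
    t_perm = np.empty((n_perm, len(comparisons)))
    scale = np.empty(len(comparisons))
    for j, (diffs, em) in enumerate(per_comp):
        cols = [index[e] for e in em]
        t_obs[j] = diffs.mean()
        t_perm[:, j] = (flips[:, cols] * diffs).mean(axis=1)
        s = t_perm[:, j].std()
        scale[j] = s if s > 0 else 1.0
    z_obs = np.abs(t_obs) / scale
    z_perm = np.abs(t_perm) / scale
    max_z = z_perm.max(axis=1)
    p_unadj = (1.0 + np.count_nonzero(z_perm >= z_obs, axis=0)) / (1.0 + n_perm)
    p_adj = np.array(
        [(1.0 + np.count_nonzero(max_z >= z)) / (1.0 + n_perm) for z in z_obs]
    )
    p_adj = np.maximum(p_adj, p_unadj)
    return pd.DataFrame(
        {
            "parameter": parameter,
            "cell_a": [c[0] for c in comparisons],
            "cell_b": [c[1] for c in comparisons],
            "estimate": t_obs,
            "p_unadj": p_unadj,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
            "n_perm": n_perm,
        }
    )


def default_comparisons(post_window: str = "PostPinch") -> list[Comparison]:
    """The standard contrast family for one parameter.

    Every post-stimulus interval of the pinch window against the pinch
    baseline slot, and against the same interval after the control touch.
    """
    from embryokin.windowing import BASELINE_SLOT, POST_SLOTS

    other = "PostTouch" if post_window == "PostPinch" else "PostPinch"
    baseline = "BaselinePinch" if post_window == "PostPinch" else "BaselineTouch"
    comps: list[Comparison] = []
    for slot in POST_SLOTS:
        comps.append((cell_label(post_window, slot), cell_label(baseline, BASELINE_SLOT)))
        comps.append((cell_label(post_window, slot), cell_label(other, slot)))
    return comps
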