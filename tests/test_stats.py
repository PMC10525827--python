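import numpy as np
import pandas as pd
import pytest

from embryokin.errors import DegenerateDesignError, ParameterError
from embryokin.stats import (
    default_comparisons,
    fit_repeated_model,
    marginal_contrasts,
    permutation_contrast,
    permutation_contrasts,
)

CELLS = ["BaselinePinch:BL", "PostPinch:0-30", "PostTouch:0-30"]


def make_table(rng, n_embryos=16, effects=None, embryo_sd=2.0, noise_sd=1.0, cells=CELLS):
    """Interval table with known cell means and embryo offsets."""
    effects = effects or {}
    rows = []
    for i in range(n_embryos):
        offset = rng.normal(0, embryo_sd)
        for cell in cells:
            window, interval = cell.split(":")
            rows.append(
                {
                    "embryo_id": f"e{i:02d}",
                    "parameter": "beak_distance",
                    "window": window,
                    "interval": interval,
                    "sum": 100.0 + effects.get(cell, 0.0) + offset + rng.normal(0, noise_sd),
                }
            )
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_two_identical_embryos_recover_exact_cell_means(self):
        rows = []
        means = {"BaselinePinch:BL": 10.0, "PostPinch:0-30": 30.0}
        for embryo in ("a", "b"):
            for cell, mu in means.items():
                window, interval = cell.split(":")
                rows.append(
                    {"embryo_id": embryo, "window": window, "interval": interval, "sum": mu}
                )
        model = fit_repeated_model(pd.DataFrame(rows))
        for cell, mu in means.items():
            assert model.mean(cell) == pytest.approx(mu, abs=1e-6)

    def test_single_embryo_is_degenerate(self):
        df = pd.DataFrame(
            {
                "embryo_id": ["a"] * 3,
                "window": ["PostPinch"] * 3,
                "interval": ["0-30", "30-60", "60-90"],
                "sum": [1.0, 2.0, 3.0],
            }
        )
        with pytest.raises(DegenerateDesignError):
            fit_repeated_model(df)

    def test_embryo_offsets_yield_positive_intercept_variance(self, rng):
        table = make_table(rng, n_embryos=20, embryo_sd=5.0, noise_sd=1.0)
        model = fit_repeated_model(table, parameter="beak_distance")
        assert model.embryo_var > 1.0  # true 25
        assert model.resid_var == pytest.approx(1.0, rel=0.8)

    def test_zero_effect_cohort_estimates_cover_zero(self, rng):
        table = make_table(rng, n_embryos=16)
        model = fit_repeated_model(table, parameter="beak_distance")
        res = marginal_contrasts(model, [("PostPinch:0-30", "BaselinePinch:BL")])
        est, se = res["estimate"].iloc[0], res["se"].iloc[0]
        assert abs(est) < 4 * se

    def test_missing_cell_is_named_in_error(self, rng):
        table = make_table(rng, cells=CELLS[:2])
        model = fit_repeated_model(table, parameter="beak_distance")
        with pytest.raises(ValueError, match="PostTouch:0-30"):
            marginal_contrasts(model, [("PostPinch:0-30", "PostTouch:0-30")])


class TestMarginalContrasts:
    def test_single_comparison_unadjusted(self, rng):
        table = make_table(rng, effects={"PostPinch:0-30": 3.0})
        model = fit_repeated_model(table, parameter="beak_distance")
        res = marginal_contrasts(model, [("PostPinch:0-30", "BaselinePinch:BL")])
        assert res["p_adj"].iloc[0] == res["p_unadj"].iloc[0]

    def test_adjusted_p_monotone_in_family_size(self, rng):
        table = make_table(rng, effects={"PostPinch:0-30": 2.0})
        model = fit_repeated_model(table, parameter="beak_distance")
        comp = ("PostPinch:0-30", "BaselinePinch:BL")
        previous = 0.0
        for m in (1, 2, 4):
            res = marginal_contrasts(model, [comp] * m)
            p = res["p_adj"].iloc[0]
            assert p >= previous - 1e-9
            assert p >= res["p_unadj"].iloc[0] - 1e-12
            previous = p

    def test_injected_effect_detected_and_decays(self, rng):
        cells = CELLS + ["PostPinch:30-60", "PostTouch:30-60", "PostPinch:90-120",
                         "PostTouch:90-120"]
        table = make_table(
            rng,
            effects={"PostPinch:0-30": 10.0, "PostPinch:30-60": 5.0},
            cells=cells,
        )
        model = fit_repeated_model(table, parameter="beak_distance")
        comps = [
            ("PostPinch:0-30", "BaselinePinch:BL"),
            ("PostPinch:30-60", "BaselinePinch:BL"),
            ("PostPinch:90-120", "BaselinePinch:BL"),
        ]
        res = marginal_contrasts(model, comps)
        assert bool(res["significant"].iloc[0])
        assert not bool(res["significant"].iloc[2])
        assert res["p_adj"].iloc[0] < res["p_adj"].iloc[1] < res["p_adj"].iloc[2]


class TestPermutation:
    def test_identical_condition_vectors_give_p_one(self, rng):
        table = make_table(rng, noise_sd=0.0, embryo_sd=3.0)
        # both cells equal per embryo -> all diffs zero
        res = permutation_contrast(
            table, ("PostPinch:0-30", "BaselinePinch:BL"), n_perm=200, seed=1
        )
        assert res["p"] == 1.0

    def test_small_n_perm_rejected(self, rng):
        table = make_table(rng)
        with pytest.raises(ParameterError):
            permutation_contrast(table, ("PostPinch:0-30", "BaselinePinch:BL"), n_perm=50)

    def test_affine_response_rescaling_leaves_p_unchanged(self, rng):
        table = make_table(rng, effects={"PostPinch:0-30": 2.0})
        scaled = table.copy()
        scaled["sum"] = 3.7 * scaled["sum"] + 11.0
        comp = ("PostPinch:0-30", "BaselinePinch:BL")
        p1 = permutation_contrast(table, comp, n_perm=500, seed=7)["p"]
        p2 = permutation_contrast(scaled, comp, n_perm=500, seed=7)["p"]
        assert p1 == p2

    def test_embryo_row_order_is_irrelevant(self, rng):
        table = make_table(rng, effects={"PostPinch:0-30": 2.0})
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        comp = ("PostPinch:0-30", "BaselinePinch:BL")
        assert (
            permutation_contrast(table, comp, n_perm=300, seed=5)["p"]
            == permutation_contrast(shuffled, comp, n_perm=300, seed=5)["p"]
        )

    def test_strong_effect_detected_with_high_power(self, rng):
        hits = 0
        for i in range(20):
            table = make_table(rng, effects={"PostPinch:0-30": 3.0}, noise_sd=1.0)
            res = permutation_contrast(
                table, ("PostPinch:0-30", "BaselinePinch:BL"), n_perm=300, seed=i
            )
            hits += res["p"] < 0.05
        assert hits >= 18

    def test_family_adjustment_dominates_single_tests(self, rng):
        table = make_table(rng, effects={"PostPinch:0-30": 2.0})
        comps = [
            ("PostPinch:0-30", "BaselinePinch:BL"),
            ("PostPinch:0-30", "PostTouch:0-30"),
        ]
        res = permutation_contrasts(table, comps, n_perm=500, seed=3)
        assert (res["p_adj"] >= res["p_unadj"] - 1e-12).all()


class TestCrossMethodAgreement:
    def test_mixed_model_and_permutation_agree_on_sign(self, rng):
        table = make_table(
            rng,
            n_embryos=16,
            effects={"PostPinch:0-30": 4.0, "PostTouch:0-30": -1.0},
        )
        comps = default_comparisons()[:2]
        model = fit_repeated_model(table, parameter="beak_distance")
        lmm = marginal_contrasts(model, comps)
        perm = permutation_contrasts(table, comps, n_perm=500, seed=11,
                                     parameter="beak_distance")
        assert (np.sign(lmm["estimate"]) == np.sign(perm["estimate"])).all()
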