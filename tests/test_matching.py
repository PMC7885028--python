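import numpy as np
import pandas as pd
import pytest

from conftest import COVARIATES, confounded_config, make_landscape, null_config
from oracles import logit_mle_gridsearch, reference_greedy_match
from paimpact.forest_change import compute_loss
from paimpact.matching import (
    MatchedPairs,
    PropensityFit,
    fit_propensity,
    match_national,
    match_regional,
    nearest_neighbor_match,
)
from paimpact.synthetic_landscape import generate_landscape


def manual_fit(scores: dict, treated: dict, sd: float) -> PropensityFit:
    return PropensityFit(
        covariate_names=[],
        coefficients=pd.Series(dtype=float),
        scores=pd.Series(scores, dtype=float),
        treated=pd.Series(treated, dtype=bool),
        score_sd=sd,
    )


class TestFitPropensity:
    def test_intercept_only_equals_prevalence(self):
        # identical covariates for everyone: score = treated fraction
        ls = make_landscape(
            [True] * 2 + [False] * 18, covariates={"a": np.ones(20)}
        )
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_propensity(ls, ["a"])
        np.testing.assert_allclose(fit.scores, 0.10, atol=1e-9)

    def test_exact_twins_get_equal_scores(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=10)
        ls = make_landscape(
            [True] * 10 + [False] * 10,
            covariates={"a": np.concatenate([vals, vals])},
        )
        fit = fit_propensity(ls, ["a"])
        np.testing.assert_allclose(
            fit.scores.iloc[:10].to_numpy(), fit.scores.iloc[10:].to_numpy(), atol=1e-9
        )

    def test_coefficients_match_gridsearch_mle(self):
        x = np.array([-1.2, -0.4, 0.1, 0.3, 0.8, 1.5])
        y = [False, True, False, True, False, True]
        ls = make_landscape(y, covariates={"a": x})
        fit = fit_propensity(ls, ["a"])
        oracle = logit_mle_gridsearch(x, np.asarray(y, float))
        assert fit.coefficients["const"] == pytest.approx(oracle[0], abs=1e-4)
        assert fit.coefficients["a"] == pytest.approx(oracle[1], abs=1e-4)

    def test_no_treated_rejected(self):
        ls = make_landscape([False] * 6, covariates={"a": np.arange(6.0)})
        with pytest.raises(ValueError):
            fit_propensity(ls, ["a"])

    def test_separation_falls_back_to_ridge(self):
        x = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        ls = make_landscape([False] * 3 + [True] * 3, covariates={"a": x})
        with pytest.warns(UserWarning, match="ridge"):
            fit = fit_propensity(ls, ["a"])
        assert fit.ridged
        assert fit.scores.between(0, 1).all()


class TestNearestNeighbor:
    def test_nearest_inside_caliper(self):
        fit = manual_fit({0: 0.50, 1: 0.49, 2: 0.20}, {0: True, 1: False, 2: False}, 0.2)
        mp = nearest_neighbor_match(fit, 0.25)
        assert mp.n_pairs == 1
        assert mp.pairs.loc[0, "control_id"] == 1
        assert mp.pairs.loc[0, "distance"] == pytest.approx(0.01)

    def test_caliper_rejection(self):
        fit = manual_fit({0: 0.90, 1: 0.50}, {0: True, 1: False}, 0.10)
        mp = nearest_neighbor_match(fit, 0.25)
        assert mp.n_pairs == 0
        assert mp.n_unmatched_treated == 1

    def test_matches_reference_on_crafted_ties(self):
        # three treated, three controls with exact ties; descending-score
        # greedy with id tie-breaks
        scores = {0: 0.75, 1: 0.75, 2: 0.25, 10: 0.5, 11: 0.5, 12: 0.25}
        treated = {0: True, 1: True, 2: True, 10: False, 11: False, 12: False}
        fit = manual_fit(scores, treated, sd=1.0)
        mp = nearest_neighbor_match(fit, 0.25)
        expect = reference_greedy_match(
            [(0, 0.75), (1, 0.75), (2, 0.25)],
            [(10, 0.5), (11, 0.5), (12, 0.25)],
            0.25 * 1.0,
        )
        got = list(mp.pairs[["treated_id", "control_id", "distance"]].itertuples(index=False, name=None))
        assert sorted(got) == sorted(expect)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_reference_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_t = rng.integers(1, 8)
        n_c = rng.integers(1, 12)
        t_ids = list(range(n_t))
        c_ids = list(range(100, 100 + n_c))
        scores = {i: round(rng.random(), 2) for i in t_ids + c_ids}
        treated = {i: i < 100 for i in t_ids + c_ids}
        sd = 0.25
        fit = manual_fit(scores, treated, sd)
        mp = nearest_neighbor_match(fit, 0.25)
        expect = reference_greedy_match(
            [(i, scores[i]) for i in t_ids], [(i, scores[i]) for i in c_ids], 0.25 * sd
        )
        got = list(mp.pairs[["treated_id", "control_id", "distance"]].itertuples(index=False, name=None))
        assert len(got) == len(expect)
        for (gt, gc, gd), (et, ec, ed) in zip(got, expect):
            assert (gt, gc) == (et, ec)
            assert gd == pytest.approx(ed, abs=1e-12)

    def test_without_replacement_and_caliper_invariants(self):
        rng = np.random.default_rng(7)
        scores = {i: rng.random() for i in range(200)}
        treated = {i: i < 60 for i in range(200)}
        fit = manual_fit(scores, treated, sd=float(np.std(list(scores.values()), ddof=1)))
        mp = nearest_neighbor_match(fit, 0.25)
        assert mp.pairs["control_id"].is_unique
        assert mp.pairs["treated_id"].is_unique
        assert (mp.pairs["distance"] <= mp.caliper + 1e-12).all()

    def test_duplicate_control_rejected_by_invariant(self):
        pairs = pd.DataFrame(
            {"pair_id": [0, 1], "treated_id": [1, 2], "control_id": [5, 5], "distance": [0.0, 0.0]}
        )
        with pytest.raises(ValueError, match="reused"):
            MatchedPairs(pairs, caliper=1.0, n_unmatched_treated=0)


class TestMatchNational:
    def test_exact_twins_all_matched_distance_zero(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=15)
        ls = make_landscape(
            [True] * 15 + [False] * 15,
            covariates={"a": np.concatenate([vals, vals])},
        )
        mp = match_national(ls, ["a"])
        assert mp.n_pairs == 15
        assert np.allclose(mp.pairs["distance"], 0.0, atol=1e-9)

    def test_null_landscape_equal_outcomes(self):
        diffs = []
        for seed in range(5):
            landscape, _ = generate_landscape(null_config(seed=seed, grid=22))
            lt = compute_loss(landscape)
            mp = match_national(landscape, ["elevation", "slope"], lt)
            loss = lt.loss
            diffs.append(loss[mp.treated_ids].mean() - loss[mp.control_ids].mean())
        assert abs(np.mean(diffs)) < 0.006

    def test_matching_reduces_score_gap(self, confounded_landscape, confounded_loss):
        landscape, _ = confounded_landscape
        fit = fit_propensity(landscape, COVARIATES)
        mp = match_national(landscape, COVARIATES, confounded_loss)
        pre = abs(fit.scores[fit.treated].mean() - fit.scores[~fit.treated].mean())
        post = abs(
            fit.scores[mp.treated_ids].mean() - fit.scores[mp.control_ids].mean()
        )
        assert post < pre

    def test_controls_never_protected(self, confounded_landscape, confounded_loss):
        landscape, _ = confounded_landscape
        mp = match_national(landscape, COVARIATES, confounded_loss)
        prot = landscape.cells.set_index("cell_id")["protected"]
        assert not prot.loc[mp.control_ids].any()

    def test_unusable_cells_excluded(self, confounded_landscape):
        landscape, _ = confounded_landscape
        landscape = landscape.copy()
        drop = landscape.cells["cell_id"].iloc[:50]
        landscape.cells.loc[drop.index, "forest_2000"] = np.nan
        lt = compute_loss(landscape)
        mp = match_national(landscape, COVARIATES, lt)
        assert not set(drop) & set(mp.matched_ids)


class TestMatchRegional:
    def test_exact_subsetting_same_region(self, confounded_landscape, confounded_loss):
        landscape, _ = confounded_landscape
        region = landscape.cells.set_index("cell_id")["region_id"]
        per = match_regional(landscape, COVARIATES, "exact_subsetting", confounded_loss)
        for reg, mp in per.items():
            if mp.n_pairs == 0:
                continue
            assert (region.loc[mp.treated_ids].to_numpy() == reg).all()
            assert (region.loc[mp.control_ids].to_numpy() == reg).all()

    def test_subsetting_can_cross_regions(self):
        # craft: treated in region 0 whose nearest score neighbor lives in
        # region 1 (identical covariate), while region-0 controls are far
        ls = make_landscape(
            [True, False, False],
            covariates={"a": [1.0, 1.0, -2.0]},
            region=[0, 1, 0],
        )
        per = match_regional(ls, ["a"], "subsetting")
        mp = per[0]
        assert mp.n_pairs == 1
        assert mp.pairs.loc[0, "control_id"] == 1  # region-1 control

    def test_submatching_excludes_region_dummies(self, confounded_landscape, confounded_loss):
        landscape, _ = confounded_landscape
        per = match_regional(landscape, COVARIATES, "submatching", confounded_loss)
        region = landscape.cells.set_index("cell_id")["region_id"]
        for reg, mp in per.items():
            if mp.n_pairs:
                assert (region.loc[mp.matched_ids] == reg).all()

    def test_unknown_procedure(self, confounded_landscape):
        landscape, _ = confounded_landscape
        with pytest.raises(ValueError):
            match_regional(landscape, COVARIATES, "bogus")
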