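"""Fitness analyses: GLMs, proportion tests, silique models, rank test."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from vernadyn import fitness
from vernadyn.fitness import (
    precocious_bolting_model,
    rank_test,
    silique_models,
    summarize_genotypes,
    survival_proportion_test,
)
from vernadyn.simulate import SimulationConfig, simulate_fitness


def _plants(pcts, flcs, n=40, rng=None):
    rows = []
    for i, (pct, flc) in enumerate(zip(pcts, flcs)):
        k = int(round(pct / 100 * n))
        for j in range(n):
            rows.append((f"g{i}", j < k, True, 5, 100, flc))
    return pd.DataFrame(rows, columns=[
        "genotype", "bolted_before_winter", "survived", "rosette_branches",
        "siliques", "autumn_flc"])


class TestPrecociousBolting:
    def test_r2_one_when_percentages_exactly_linear(self):
        flcs = [1.0, 2.0, 3.0, 4.0]
        pcts = [80.0, 60.0, 40.0, 20.0]  # exactly linear in FLC
        out = precocious_bolting_model(_plants(pcts, flcs, n=10))
        assert out["r2"] == pytest.approx(1.0, abs=1e-12)
        assert out["linreg_slope"] == pytest.approx(-20.0, abs=1e-9)

    def test_glm_slope_sign_negative_for_declining_bolting(self):
        flcs = [0.5, 1.5, 3.0, 5.0]
        pcts = [90.0, 60.0, 30.0, 10.0]
        out = precocious_bolting_model(_plants(pcts, flcs, n=50))
        assert not out["separation"]
        assert out["glm_slope"] < 0
        assert out["glm_slope_p"] < 0.001

    def test_all_zero_bolting_flags_separation(self):
        out = precocious_bolting_model(_plants([0, 0, 0], [1.0, 2.0, 3.0]))
        assert out["separation"]
        assert np.isnan(out["glm_slope"])

    def test_too_few_genotypes_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            precocious_bolting_model(_plants([10, 20], [1.0, 2.0]))


class TestSurvivalProportions:
    def test_identical_proportions_give_p_one(self):
        out = survival_proportion_test((5, 10), (5, 10))
        assert out["p"] == pytest.approx(1.0)

    def test_extreme_table_close_to_fisher(self):
        chi2 = survival_proportion_test((0, 10), (10, 10))
        fisher = survival_proportion_test((0, 10), (10, 10), method="fisher")
        assert chi2["p"] < 0.001 and fisher["p"] < 0.001
        # chi-square approximation agrees with the exact test in order
        # of magnitude for this extreme split
        assert abs(np.log10(chi2["p"]) - np.log10(fisher["p"])) < 2.0

    def test_symmetry_under_arm_swap(self):
        a = survival_proportion_test((12, 30), (24, 40))
        b = survival_proportion_test((24, 40), (12, 30))
        assert a["p"] == pytest.approx(b["p"], rel=1e-12)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 1"):
            survival_proportion_test((0, 0), (1, 2))


class TestSiliqueModels:
    def _summaries(self, n=8):
        postvern = np.linspace(20, 60, n)
        surv = np.linspace(30, 90, n)[::-1]
        rng = np.random.default_rng(0)
        surv = rng.permutation(surv)  # break collinearity with postvern
        total = 500.0 - 5.0 * postvern + 10.0 * surv
        return pd.DataFrame({
            "genotype": [f"g{i}" for i in range(n)],
            "mean_siliques_survivors": 50.0 + 4.0 * np.arange(n),
            "mean_rosette_branches": 10.0 + np.arange(n),
            "postvern_m": postvern,
            "pct_survival": surv,
            "total_siliques": total,
        })

    def test_exact_coefficients_and_adjusted_r2_one(self):
        out = silique_models(self._summaries(), reduce=False)
        tm = out["total_model"]
        assert tm["coef"]["postvern_m"] == pytest.approx(-5.0, abs=1e-8)
        assert tm["coef"]["pct_survival"] == pytest.approx(10.0, abs=1e-8)
        assert tm["adj_r2"] == pytest.approx(1.0, abs=1e-10)

    def test_adjusted_r2_closed_form(self, rng):
        s = self._summaries()
        s["total_siliques"] += rng.normal(0, 40, len(s))
        out = silique_models(s, reduce=False)
        tm = out["total_model"]
        n, p = tm["n"], 2
        assert tm["adj_r2"] == pytest.approx(
            1 - (1 - tm["r2"]) * (n - 1) / (n - p - 1), abs=1e-12)

    def test_permuted_predictor_rarely_explains_variance(self, rng):
        s = self._summaries(10)
        r2s = []
        for _ in range(200):
            shuffled = s.copy()
            shuffled["total_siliques"] = rng.permutation(
                shuffled["total_siliques"].to_numpy())
            out = silique_models(shuffled, reduce=False)
            tm = out["total_model"]
            assert tm["adj_r2"] <= tm["r2"] + 1e-12
            r2s.append(tm["r2"])
        assert np.mean(r2s) < 0.3

    def test_backward_elimination_logged(self, rng):
        s = self._summaries()
        # make survival pure noise so it can be dropped
        s["total_siliques"] = 500.0 - 5.0 * s["postvern_m"] \
            + rng.normal(0, 10, len(s))
        out = silique_models(s)
        assert out["reduction_log"]
        assert "minimal_model" in out

    def test_collinear_predictors_refuse_reduction(self):
        s = self._summaries()
        s["pct_survival"] = 2.0 * s["postvern_m"]  # exactly collinear
        out = silique_models(s)
        assert any("collinear" in step for step in out["reduction_log"])

    def test_poisson_recovers_generating_coefficients(self, rng):
        branches = rng.integers(0, 20, 500)
        lam = np.exp(1.0 + 0.1 * branches)
        plants = pd.DataFrame({
            "genotype": "g", "bolted_before_winter": False, "survived": True,
            "rosette_branches": branches, "siliques": rng.poisson(lam),
            "autumn_flc": 1.0, "postvern_m": 30.0})
        out = silique_models(self._summaries(), plants=plants)
        pois = out["poisson_plant_level"]
        assert pois["coef"]["rosette_branches"] == pytest.approx(
            0.1, abs=3 * pois["se"]["rosette_branches"])

    def test_too_few_genotypes_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            silique_models(self._summaries(3))


class TestRankTest:
    def test_identical_groups_p_one_with_ties(self):
        out = rank_test([1, 2, 3], [1, 2, 3])
        assert out["p"] == pytest.approx(1.0) and out["method"] == "exact"

    def test_smallest_attainable_two_sided_p_at_3v3(self):
        out = rank_test([1, 2, 3], [10, 20, 30])
        assert out["p"] == pytest.approx(0.1)

    def test_scale_invariance(self):
        a = rank_test([1, 5, 9, 2], [3, 8, 11])
        b = rank_test([10, 50, 90, 20], [30, 80, 110])
        assert a["u"] == b["u"] and a["p"] == b["p"]

    def test_exact_branch_equals_full_permutation_enumeration(self, rng):
        for _ in range(5):
            x = rng.integers(0, 6, 4).astype(float)  # ties likely
            y = rng.integers(0, 6, 3).astype(float)
            mine = rank_test(x, y)
            # oracle: every permutation of the pooled values
            from scipy.stats import rankdata
            pooled = np.concatenate([x, y])
            n1 = len(x)
            obs_u = mine["u"]
            us = []
            for perm in permutations(range(len(pooled)), len(pooled)):
                ranks = rankdata(pooled[list(perm)])
                us.append(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
            us = np.array(us)
            p_lo = np.mean(us <= obs_u)
            p_hi = np.mean(us >= obs_u)
            expected = min(1.0, 2 * min(p_lo, p_hi))
            assert mine["p"] == pytest.approx(expected, abs=1e-12)

    def test_large_samples_use_normal_approximation(self, rng):
        out = rank_test(rng.normal(0, 1, 15), rng.normal(1, 1, 15))
        assert out["method"] == "normal-approx"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            rank_test([], [1.0])


class TestSummaries:
    def test_percentages_and_survivor_means(self):
        plants = simulate_fitness(SimulationConfig(seed=13))
        summ = summarize_genotypes(plants)
        assert summ["pct_bolted_before_winter"].between(0, 100).all()
        assert summ["pct_survival"].between(0, 100).all()
        g = plants[plants.genotype == summ["genotype"].iloc[0]]
        expected = g.loc[g.survived, "siliques"].mean()
        assert summ["mean_siliques_survivors"].iloc[0] == pytest.approx(expected)
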