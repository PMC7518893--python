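"""Group statistics: Dunnett, mixed-model slopes, CV equality, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from vernadyn import groupstats
from vernadyn.groupstats import (
    bh_adjust,
    cv_equality_test,
    dunnett_vs_control,
    mixed_slope_contrasts,
    variability_report,
)


class TestDunnett:
    def test_two_groups_reduce_to_pooled_t_test(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        res = dunnett_vs_control({"ctrl": a, "trt": b}, "ctrl",
                                 mc_draws=2_000_000, seed=0)
        t_p = stats.ttest_ind(b, a).pvalue
        assert res["p_adj"].iloc[0] == pytest.approx(t_p, abs=2e-3)

    def test_matches_scipy_dunnett(self, rng):
        groups = {g: rng.normal(m, 1, 7)
                  for g, m in [("c", 0.0), ("a", 0.8), ("b", -0.4), ("d", 0.1)]}
        mine = dunnett_vs_control(groups, "c", mc_draws=500_000, seed=1)
        ref = stats.dunnett(groups["a"], groups["b"], groups["d"],
                            control=groups["c"])
        assert np.allclose(mine["p_adj"].to_numpy(), ref.pvalue, atol=5e-3)

    def test_zero_residual_variance_rejected(self):
        with pytest.raises(ValueError, match="zero residual variance"):
            dunnett_vs_control({"a": [1.0, 1.0], "b": [1.0, 1.0]}, "a")

    def test_missing_control_and_small_groups_rejected(self):
        with pytest.raises(ValueError, match="control"):
            dunnett_vs_control({"a": [1, 2], "b": [1, 2]}, "zz")
        with pytest.raises(ValueError, match="fewer than 2"):
            dunnett_vs_control({"a": [1, 2], "b": [1.0]}, "a")

    def test_deterministic_given_seed(self, rng):
        groups = {g: rng.normal(0, 1, 6) for g in "abc"}
        r1 = dunnett_vs_control(groups, "a", mc_draws=50_000, seed=3)
        r2 = dunnett_vs_control(groups, "a", mc_draws=50_000, seed=3)
        pd.testing.assert_frame_equal(r1, r2)


def _slope_data(slopes, days=(0, 10, 20, 30), n_blocks=3, reps=2,
                block_eff=None, noise=None, rng=None):
    rows = []
    for g, slope in slopes.items():
        for d in days:
            for b in range(n_blocks):
                for _ in range(reps):
                    y = 5.0 + slope * d
                    if block_eff is not None:
                        y += block_eff[b]
                    if noise is not None:
                        y += rng.normal(0, noise)
                    rows.append((g, d, b, y))
    return pd.DataFrame(rows, columns=["genotype", "day", "block", "value_au"])


class TestMixedSlopes:
    def test_zero_noise_interaction_exact(self):
        df = _slope_data({"ref": -0.2, "alt": -0.3})
        res = mixed_slope_contrasts(df, reference="ref")
        assert res["estimate"].iloc[0] == pytest.approx(-0.1, abs=1e-8)

    def test_reduces_to_ols_ancova_when_block_variance_zero(self, rng):
        df = _slope_data({"ref": -0.2, "alt": -0.25}, noise=0.2, rng=rng)
        res = mixed_slope_contrasts(df, reference="ref")
        # OLS oracle with the same design (centered day, treatment coding)
        dayc = df["day"] - df["day"].mean()
        ind = (df["genotype"] == "alt").astype(float)
        X = np.column_stack([np.ones(len(df)), dayc, ind, ind * dayc])
        beta, *_ = np.linalg.lstsq(X, df["value_au"], rcond=None)
        assert res["estimate"].iloc[0] == pytest.approx(beta[3], abs=1e-6)

    def test_matches_statsmodels_mixedlm(self, rng):
        block_eff = rng.normal(0, 0.3, 3)
        df = _slope_data({"ref": -0.2, "alt": -0.25}, block_eff=block_eff,
                         noise=0.2, rng=rng)
        res = mixed_slope_contrasts(df, reference="ref")
        import statsmodels.formula.api as smf
        df2 = df.copy()
        df2["dayc"] = df2["day"] - df2["day"].mean()
        m = smf.mixedlm("value_au ~ C(genotype, Treatment('ref')) * dayc",
                        df2, groups=df2["block"]).fit(reml=True)
        sm_est = m.params["C(genotype, Treatment('ref'))[T.alt]:dayc"]
        sm_block_var = float(m.cov_re.iloc[0, 0])
        assert res["estimate"].iloc[0] == pytest.approx(sm_est, abs=1e-5)
        assert res.attrs["sigma2_block"] == pytest.approx(sm_block_var, rel=0.05,
                                                          abs=1e-4)
        assert res.attrs["sigma2_resid"] == pytest.approx(m.scale, rel=0.05)

    def test_satterthwaite_df_between_bounds(self, rng):
        block_eff = rng.normal(0, 0.3, 3)
        df = _slope_data({"ref": -0.2, "alt": -0.25}, block_eff=block_eff,
                         noise=0.2, rng=rng)
        res = mixed_slope_contrasts(df, reference="ref")
        assert 1.0 <= res["df"].iloc[0]

    def test_single_block_falls_back_to_ols_with_warning(self, rng):
        df = _slope_data({"ref": -0.2, "alt": -0.25}, n_blocks=1, reps=6,
                         noise=0.1, rng=rng)
        res = mixed_slope_contrasts(df, reference="ref")
        assert any("single block" in w for w in res.attrs["warnings"])
        assert res["df"].iloc[0] == len(df) - 4

    def test_missing_reference_rejected(self):
        df = _slope_data({"a": -0.2, "b": -0.3})
        with pytest.raises(ValueError, match="reference"):
            mixed_slope_contrasts(df, reference="zz")


class TestCVEquality:
    def test_identical_cvs_give_zero_statistic(self):
        res = cv_equality_test([[1, 2, 3], [2, 4, 6]])
        assert res.statistic == 0.0 and res.p == 1.0

    @given(k=st.floats(0.01, 100.0))
    @settings(max_examples=40, deadline=None)
    def test_invariant_to_positive_rescaling(self, k):
        g1, g2 = [1.0, 2.0, 4.0], [3.0, 3.5, 5.0, 6.0]
        base = cv_equality_test([g1, g2])
        scaled = cv_equality_test([np.asarray(g1) * k, g2])
        assert scaled.statistic == pytest.approx(base.statistic, rel=1e-9)
        assert scaled.p == pytest.approx(base.p, rel=1e-9)

    def test_statistic_formula_by_hand(self):
        g1, g2 = np.array([1.0, 2.0, 3.0]), np.array([10.0, 11.0, 12.0, 13.0])
        res = cv_equality_test([g1, g2])
        cv1 = g1.std(ddof=1) / g1.mean()
        cv2 = g2.std(ddof=1) / g2.mean()
        cvbar = (2 * cv1 + 3 * cv2) / 5
        d = (2 * (cv1 - cvbar) ** 2 + 3 * (cv2 - cvbar) ** 2) \
            / (cvbar**2 * (0.5 + cvbar**2))
        assert res.statistic == pytest.approx(d, rel=1e-12)
        assert res.df == 1
        assert res.p == pytest.approx(stats.chi2.sf(d, 1), rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="mean 0"):
            cv_equality_test([[1.0, -1.0], [1.0, 2.0]])
        with pytest.raises(ValueError, match="n < 2"):
            cv_equality_test([[1.0], [1.0, 2.0]])


def _bh_bruteforce(p, q):
    """Literal step-up definition, independent of the implementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    kmax = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            kmax = k
    reject[order[:kmax]] = True
    adjusted = np.empty(m)
    for idx, rank in zip(order, range(1, m + 1)):
        adjusted[idx] = min(min(m * p[order[j - 1]] / j
                                for j in range(rank, m + 1)), 1.0)
    return reject, adjusted


class TestBH:
    def test_spec_example_all_rejected(self):
        reject, adjusted = bh_adjust([0.01, 0.04, 0.03, 0.005], q=0.05)
        assert reject.all()

    def test_all_ones(self):
        reject, adjusted = bh_adjust([1.0, 1.0, 1.0])
        assert not reject.any() and (adjusted == 1.0).all()

    def test_equals_bruteforce_on_random_vectors(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 12))
            p = np.round(rng.random(m), 3)  # induce ties
            r1, a1 = bh_adjust(p, q=0.05)
            r2, a2 = _bh_bruteforce(p, q=0.05)
            assert np.array_equal(r1, r2)
            assert np.allclose(a1, a2, atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.random(50)
        _, adjusted = bh_adjust(p)
        _, sm_adj, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(adjusted, sm_adj, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            bh_adjust([0.5, 1.2])


class TestVariabilityReport:
    def _features(self, rng, start_cv=0.5, rate_cv=0.1, n=10, site="A"):
        starts = 10.0 * (1 + rng.normal(0, start_cv, n))
        rates = -0.2 * (1 + rng.normal(0, rate_cv, n))
        return pd.DataFrame({
            "genotype": [f"g{i}" for i in range(n)],
            "site": site, "year": 2014,
            "start_mean": np.abs(starts),
            "rate_vindep": rates,
            "rate_vdep": rates * 1.5,
        })

    def test_detects_more_variable_starting_levels(self, rng):
        feats = self._features(rng)
        cvs, tests = variability_report(feats)
        row = tests[tests.comparison.str.startswith("starting-vs-vindep")]
        assert row["p"].iloc[0] < 0.01

    def test_power_against_fivefold_cv_difference(self):
        # starting levels 5x more variable (cv) than rates, 10 genotypes:
        # the starting-vs-rate test should reject at p < 0.01 nearly
        # always.  cv levels are kept moderate (0.25 vs 0.05) so the
        # normal noise model cannot produce negative abundances, which
        # would distort the nominal cv of the simulated truth.
        rng = np.random.default_rng(99)
        hits = 0
        n_seeds = 200
        for _ in range(n_seeds):
            feats = self._features(rng, start_cv=0.25, rate_cv=0.05, n=10)
            _, tests = variability_report(feats)
            row = tests[tests.comparison.str.startswith("starting-vs-vindep")]
            hits += row["p"].iloc[0] < 0.01
        assert hits / n_seeds >= 0.95

    def test_rates_enter_as_magnitudes(self, rng):
        feats = self._features(rng)
        cvs, _ = variability_report(feats)
        assert (cvs["cv"].dropna() > 0).all()

    def test_identical_sites_give_p_one(self, rng):
        a = self._features(rng, site="A")
        b = a.copy()
        b["site"] = "B"
        _, tests = variability_report(pd.concat([a, b]))
        between = tests[tests.comparison.str.startswith("site-vs-site")]
        assert np.allclose(between["p"].to_numpy(), 1.0)

    def test_label_permutation_leaves_cvs_unchanged(self, rng):
        feats = self._features(rng)
        cvs1, _ = variability_report(feats)
        shuffled = feats.copy()
        shuffled["genotype"] = rng.permutation(shuffled["genotype"].to_numpy())
        cvs2, _ = variability_report(shuffled)
        pd.testing.assert_frame_equal(cvs1, cvs2)

    def test_small_group_skipped_with_note(self):
        feats = pd.DataFrame({
            "genotype": ["g1"], "site": "A", "year": 2014,
            "start_mean": [10.0], "rate_vindep": [-0.2]})
        _, tests = variability_report(feats)
        assert tests["note"].str.contains("skipped").all()
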