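"""Monte-Carlo calibration and parameter-recovery studies.

Each function simulates many small experiments under known truth and
measures a frequency property of the corresponding estimator: confidence
-interval coverage for the decay features, the post-vern slope and the
GLMs; detection accuracy for the induction breakpoint; type-I error for
the CV-equality test; family-wise error for the Dunnett procedure.  These
studies back the package's correctness claims and are re-run by the
acceptance script; problem sizes are chosen to finish in minutes on one
CPU.

Truth values for the recovery studies are fixed once so the noiseless
two-phase trajectory stays strictly positive over the sampled window (a
validity requirement for a linear decline, since abundances are floored
at zero).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import decay, fitness, groupstats, induction, postvern
from .simulate import GenotypeParams, SimulationConfig, simulate_expression

__all__ = [
    "two_phase_recovery_study",
    "breakpoint_detection_study",
    "cv_type1_study",
    "dunnett_fwer_study",
    "mixed_model_coverage_study",
    "postvern_recovery_study",
    "glm_coverage_study",
]

# study conditions for two-phase recovery: 6 replicates, 4 timepoints per
# phase, multiplicative log-normal replicate noise of sd 0.2
RECOVERY_TRUTH = dict(S=20.0, r1=0.2, r2=0.15, breakpoint=45.0)
RECOVERY_DAYS = (10, 20, 30, 40, 50, 60, 70, 80)


def _t_ci(est: float, se: float, df: float, level: float = 0.95):
    half = stats.t.ppf(0.5 + level / 2, df) * se
    return est - half, est + half


def two_phase_recovery_study(n_seeds: int = 500, seed: int = 0) -> dict:
    """95% CI coverage for starting level and both phase rates.

    The starting-level truth is the noiseless trajectory at the first
    field timepoint (the feature's definition), not the day-0 intercept.
    """
    tr = RECOVERY_TRUTH
    true_start = tr["S"] - tr["r1"] * RECOVERY_DAYS[0]
    hits = {"start": 0, "r1": 0, "r2": 0}
    n_rep = 6
    for i in range(n_seeds):
        cfg = SimulationConfig(
            genotypes=[GenotypeParams("g", tr["S"], tr["r1"], tr["r2"])],
            timepoints=RECOVERY_DAYS, breakpoint_day=tr["breakpoint"],
            n_replicates=n_rep, n_blocks=1, noise_sd_log=0.2,
            block_sd_log=0.0, seed=seed + i,
        )
        expr, _ = simulate_expression(cfg)
        feats = decay.extract_features(
            expr, breakpoint=tr["breakpoint"]).iloc[0]
        lo, hi = _t_ci(feats["start_mean"], feats["start_se"], n_rep - 1)
        hits["start"] += lo <= true_start <= hi
        n_phase = 4 * n_rep
        lo, hi = _t_ci(feats["rate_vindep"], feats["rate_vindep_se"], n_phase - 2)
        hits["r1"] += lo <= -tr["r1"] <= hi
        lo, hi = _t_ci(feats["rate_vdep"], feats["rate_vdep_se"], n_phase - 2)
        hits["r2"] += lo <= -tr["r2"] <= hi
    return {k: v / n_seeds for k, v in hits.items()} | {"n_seeds": n_seeds}


def breakpoint_detection_study(
    n_seeds: int = 500,
    seed: int = 0,
    true_day: float = 46.0,
    interval: float = 7.0,
) -> dict:
    """Fraction of noisy runs detecting induction within one sampling interval."""
    days = np.arange(20, 95, interval)
    hits = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(
            genotypes=[GenotypeParams("ColFRI", 10.0, 0.05, 0.1)],
            timepoints=tuple(days), breakpoint_day=true_day,
            n_replicates=6, n_blocks=3, noise_sd_log=0.2, block_sd_log=0.0,
            vin3_baseline=0.05, vin3_induced=1.0, seed=seed + i,
        )
        expr, _ = simulate_expression(cfg)
        est = induction.detect_induction_from_table(expr)
        if est.detected and abs(est.day - true_day) <= interval:
            hits += 1
    return {"hit_rate": hits / n_seeds, "n_seeds": n_seeds,
            "interval_days": interval}


def cv_type1_study(
    n_sims: int = 2000,
    n: int = 20,
    k: int = 2,
    cv: float = 0.15,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error of the CV-equality test with equal true CVs."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        groups = [rng.normal(1.0, cv, n) for _ in range(k)]
        rejections += groupstats.cv_equality_test(groups).p < alpha
    return {"type1": rejections / n_sims, "n_sims": n_sims, "n": n, "k": k}


def dunnett_fwer_study(
    n_sims: int = 2000,
    k: int = 4,
    n: int = 6,
    alpha: float = 0.05,
    mc_draws: int = 10_000,
    seed: int = 0,
) -> dict:
    """Family-wise error of the Dunnett procedure under the global null."""
    rng = np.random.default_rng(seed)
    fw_errors = 0
    for i in range(n_sims):
        data = {f"g{j}": rng.normal(0.0, 1.0, n) for j in range(k)}
        res = groupstats.dunnett_vs_control(
            data, control="g0", alpha=alpha, mc_draws=mc_draws,
            seed=seed + 1_000_000 + i)
        fw_errors += bool((res["p_adj"] < alpha).any())
    return {"fwer": fw_errors / n_sims, "n_sims": n_sims}


def mixed_model_coverage_study(
    n_seeds: int = 500,
    seed: int = 0,
    slope_diff: float = 0.05,
    resid_sd: float = 0.2,
    block_sd: float = 0.1,
    n_blocks: int = 3,
) -> dict:
    """95% CI coverage of the genotype x day interaction in the REML model."""
    days = np.array([0.0, 10.0, 20.0, 30.0])
    reps = 2  # per block per genotype per day
    base_slope = -0.2
    rng = np.random.default_rng(seed)
    hits = 0
    rows_geno = np.repeat(["ref", "alt"], len(days) * n_blocks * reps)
    rows_day = np.tile(np.repeat(days, n_blocks * reps), 2)
    rows_block = np.tile(np.tile(np.repeat(np.arange(n_blocks), reps), len(days)), 2)
    slope = np.where(rows_geno == "ref", base_slope, base_slope + slope_diff)
    for _ in range(n_seeds):
        blk_eff = rng.normal(0.0, block_sd, n_blocks)
        y = 5.0 + slope * rows_day + blk_eff[rows_block] \
            + rng.normal(0.0, resid_sd, len(rows_day))
        df = pd.DataFrame({"genotype": rows_geno, "day": rows_day,
                           "block": rows_block, "value_au": y})
        res = groupstats.mixed_slope_contrasts(df, reference="ref").iloc[0]
        lo, hi = _t_ci(res["estimate"], res["se"], res["df"])
        hits += lo <= slope_diff <= hi
    return {"coverage": hits / n_seeds, "n_seeds": n_seeds}


def postvern_recovery_study(
    n_seeds: int = 500,
    seed: int = 0,
    m: float = 40.0,
    c: float = 20.0,
    noise_sd: float = 5.0,
    n_plants: int = 12,
) -> dict:
    """95% CI coverage for the post-vern slope from 4 transfer dates."""
    flc = np.array([0.5, 1.0, 2.0, 3.0])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_seeds):
        mean_bolt = [
            float(np.mean(m * f + c + rng.normal(0.0, noise_sd, n_plants)))
            for f in flc
        ]
        fit = postvern.fit_postvern(list(zip(flc, mean_bolt)))
        lo, hi = _t_ci(fit.m, fit.se_m, fit.n_points - 2)
        hits += lo <= m <= hi
    return {"coverage": hits / n_seeds, "n_seeds": n_seeds}


def glm_coverage_study(n_seeds: int = 500, seed: int = 0) -> dict:
    """Wald 95% CI coverage for the Poisson and binomial-logit GLMs."""
    import statsmodels.api as sm

    rng = np.random.default_rng(seed)
    alpha_true, beta_true = 1.0, 0.1      # log lambda = 1 + 0.1 * branches
    a_true, b_true = 1.0, 0.5             # logit p = 1 - 0.5 * flc
    n = 200
    pois_hits = logit_hits = 0
    branches = rng.integers(0, 21, n)
    flc = rng.uniform(0.0, 6.0, n)
    Xp = sm.add_constant(branches.astype(float))
    Xl = sm.add_constant(flc)
    for _ in range(n_seeds):
        y = rng.poisson(np.exp(alpha_true + beta_true * branches))
        fit = sm.GLM(y, Xp, family=sm.families.Poisson()).fit()
        lo, hi = fit.params[1] - 1.96 * fit.bse[1], fit.params[1] + 1.96 * fit.bse[1]
        pois_hits += lo <= beta_true <= hi
        p = 1.0 / (1.0 + np.exp(-(a_true - b_true * flc)))
        yb = (rng.random(n) < p).astype(float)
        fitb = sm.GLM(yb, Xl, family=sm.families.Binomial()).fit()
        lo, hi = fitb.params[1] - 1.96 * fitb.bse[1], fitb.params[1] + 1.96 * fitb.bse[1]
        logit_hits += lo <= -b_true <= hi
    return {"poisson_coverage": pois_hits / n_seeds,
            "logit_coverage": logit_hits / n_seeds, "n_seeds": n_seeds}
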