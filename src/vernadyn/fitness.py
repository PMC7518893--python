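"""Overwinter fitness analyses: precocious bolting, survival, fecundity.

Links the autumn FLC level of each genotype to the chain of fitness
consequences observed in a warm-autumn field season: plants with low FLC
bolt precociously before winter, precocious bolters survive worse, and
among survivors silique production tracks rosette branching, which in
turn declines with the genotype's FLC-post-vern value.  Proportion data
are modelled with binomial-logit GLMs, counts with Poisson GLMs, and
genotype-level summaries with ordinary least squares, including a
backward-elimination "minimal adequate model" reduction.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "summarize_genotypes",
    "precocious_bolting_model",
    "survival_proportion_test",
    "silique_models",
    "rank_test",
]


def summarize_genotypes(plants: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype fitness summary from the plant-level census table."""
    rows = []
    for g, grp in plants.groupby("genotype", sort=False):
        surv = grp["survived"].astype(bool)
        rec = {
            "genotype": g,
            "n_plants": len(grp),
            "pct_bolted_before_winter": 100.0 * grp["bolted_before_winter"].mean(),
            "pct_survival": 100.0 * surv.mean(),
            "mean_siliques_survivors":
                float(grp.loc[surv, "siliques"].mean()) if surv.any() else np.nan,
            "total_siliques": float(grp["siliques"].sum()),
            "mean_rosette_branches":
                float(grp.loc[surv, "rosette_branches"].mean()) if surv.any() else np.nan,
        }
        for extra in ("autumn_flc", "postvern_m"):
            if extra in grp:
                rec[extra] = float(grp[extra].iloc[0])
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Precocious bolting vs autumn FLC
# ---------------------------------------------------------------------------

def precocious_bolting_model(
    plants: pd.DataFrame,
    autumn_flc: pd.Series | None = None,
) -> dict:
    """Bolting-before-winter as a function of autumn FLC expression.

    Two complementary summaries: a plant-level binomial GLM (logit link)
    of the bolting indicator on the genotype's autumn FLC, and a
    genotype-level linear regression of the bolting percentage on FLC
    (slope, R-squared, p).  Perfect separation in the GLM is flagged
    rather than raised.
    """
    df = plants.copy()
    if autumn_flc is not None:
        df = df.drop(columns=["autumn_flc"], errors="ignore").join(
            autumn_flc.rename("autumn_flc"), on="genotype")
    if df["autumn_flc"].isna().any():
        raise ValueError("autumn FLC missing for some genotypes")
    if df["genotype"].nunique() < 3:
        raise ValueError("need >= 3 genotypes")

    y = df["bolted_before_winter"].astype(float).to_numpy()
    X = sm.add_constant(df["autumn_flc"].astype(float).to_numpy())
    out: dict = {"separation": False}
    try:
        with np.errstate(all="ignore"):
            glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        fitted = glm.fittedvalues
        if np.any(fitted < 1e-10) or np.any(fitted > 1 - 1e-10) or \
                not np.all(np.isfinite(glm.bse)):
            raise ValueError("fitted probabilities at the boundary")
        out.update(glm_intercept=float(glm.params[0]),
                   glm_slope=float(glm.params[1]),
                   glm_slope_se=float(glm.bse[1]),
                   glm_slope_p=float(glm.pvalues[1]))
    except Exception as err:  # separation or non-convergence
        out["separation"] = True
        out["separation_note"] = (
            f"logit model inestimable ({err}); consider a penalized "
            "(Firth-type) fit or exact methods")
        out.update(glm_intercept=np.nan, glm_slope=np.nan,
                   glm_slope_se=np.nan, glm_slope_p=np.nan)

    summ = (df.groupby("genotype")
              .agg(pct=("bolted_before_winter", lambda v: 100.0 * v.mean()),
                   flc=("autumn_flc", "first")))
    res = stats.linregress(summ["flc"], summ["pct"])
    out.update(r2=float(res.rvalue**2), linreg_slope=float(res.slope),
               linreg_p=float(res.pvalue), n_genotypes=len(summ))
    return out


# ---------------------------------------------------------------------------
# Survival of bolted vs non-bolted plants
# ---------------------------------------------------------------------------

def survival_proportion_test(
    bolted: tuple[int, int],
    not_bolted: tuple[int, int],
    correction: bool = False,
    method: str = "chi2",
) -> dict:
    """Two-proportion test of equal survival in bolted vs non-bolted arms.

    ``bolted``/``not_bolted`` are (survivors, n) pairs.  ``method="chi2"``
    is the standard two-proportion chi-square (score) test, optionally
    with continuity correction; ``method="fisher"`` gives the exact test.
    """
    (s1, n1), (s2, n2) = bolted, not_bolted
    if n1 < 1 or n2 < 1:
        raise ValueError("both arms need n >= 1")
    if not (0 <= s1 <= n1 and 0 <= s2 <= n2):
        raise ValueError("successes must lie in [0, n]")
    p1, p2 = s1 / n1, s2 / n2
    if method == "fisher":
        table = [[s1, n1 - s1], [s2, n2 - s2]]
        stat, p = stats.fisher_exact(table)
    elif method == "chi2":
        table = np.array([[s1, n1 - s1], [s2, n2 - s2]], dtype=float)
        if np.any(table.sum(axis=0) == 0):
            stat, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
            stat = float(chi2)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"statistic": float(stat), "p": float(p),
            "prop_bolted": p1, "prop_not_bolted": p2, "method": method}


# ---------------------------------------------------------------------------
# Silique production models
# ---------------------------------------------------------------------------

def _ols(y, X, names):
    model = sm.OLS(y, sm.add_constant(X)).fit()
    k = X.shape[1] if X.ndim == 2 else 1
    n = len(y)
    r2 = float(model.rsquared)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    return {
        "coef": {"const": float(model.params[0]),
                 **{nm: float(b) for nm, b in zip(names, model.params[1:])}},
        "p": {"const": float(model.pvalues[0]),
              **{nm: float(v) for nm, v in zip(names, model.pvalues[1:])}},
        "r2": r2,
        "adj_r2": float(adj),
        "model_p": float(model.f_pvalue),
        "n": n,
    }


def silique_models(
    summaries: pd.DataFrame,
    plants: pd.DataFrame | None = None,
    reduce: bool = True,
) -> dict:
    """Genotype-level fecundity regressions, plus a plant-level Poisson option.

    (i)  mean siliques among survivors ~ mean rosette branches;
    (ii) mean rosette branches ~ FLC-post-vern m;
    (iii) total siliques ~ FLC-post-vern m + % survival (adjusted R2),
          with a logged backward-elimination reduction to the minimal
          adequate model.  When ``plants`` is given, a Poisson GLM of
          plant-level silique counts on rosette branches is also fitted.
    """
    s = summaries
    need = ["mean_siliques_survivors", "mean_rosette_branches",
            "postvern_m", "total_siliques", "pct_survival"]
    missing = [c for c in need if c not in s]
    if missing:
        raise ValueError(f"summary table lacks columns: {missing}")
    if len(s) < 4:
        raise ValueError("need >= 4 genotypes for the two-predictor model")

    out: dict = {}
    ok = s[["mean_siliques_survivors", "mean_rosette_branches"]].notna().all(axis=1)
    out["siliques_vs_branches"] = _ols(
        s.loc[ok, "mean_siliques_survivors"].to_numpy(),
        s.loc[ok, ["mean_rosette_branches"]].to_numpy(),
        ["mean_rosette_branches"])
    ok = s[["mean_rosette_branches", "postvern_m"]].notna().all(axis=1)
    out["branches_vs_postvern"] = _ols(
        s.loc[ok, "mean_rosette_branches"].to_numpy(),
        s.loc[ok, ["postvern_m"]].to_numpy(),
        ["postvern_m"])

    preds = ["postvern_m", "pct_survival"]
    ok = s[["total_siliques"] + preds].notna().all(axis=1)
    X = s.loc[ok, preds].to_numpy(dtype=float)
    y = s.loc[ok, "total_siliques"].to_numpy(dtype=float)
    cond = np.linalg.cond(np.column_stack([np.ones(len(X)), X]))
    full = _ols(y, X, preds)
    full["condition_number"] = float(cond)
    out["total_model"] = full
    steps = []
    if cond > 1e8:
        steps.append(f"collinear predictors (condition number {cond:.3g}); "
                     "auto-reduction refused")
    elif reduce:
        current = list(preds)
        current_fit = full
        while len(current) > 1:
            worst = max(current, key=lambda nm: current_fit["p"][nm])
            reduced = [nm for nm in current if nm != worst]
            fit_red = _ols(y, s.loc[ok, reduced].to_numpy(dtype=float), reduced)
            if fit_red["model_p"] < current_fit["model_p"]:
                steps.append(f"dropped {worst} (p={current_fit['p'][worst]:.3g}): "
                             f"model p {current_fit['model_p']:.3g} -> "
                             f"{fit_red['model_p']:.3g}")
                current, current_fit = reduced, fit_red
            else:
                steps.append(f"kept {worst}: dropping it does not improve "
                             f"model p ({current_fit['model_p']:.3g} -> "
                             f"{fit_red['model_p']:.3g})")
                break
        out["minimal_model"] = current_fit
        out["minimal_model_terms"] = current
    out["reduction_log"] = steps

    if plants is not None:
        surv = plants[plants["survived"].astype(bool)]
        Xp = sm.add_constant(surv["rosette_branches"].astype(float).to_numpy())
        pois = sm.GLM(surv["siliques"].astype(float).to_numpy(), Xp,
                      family=sm.families.Poisson()).fit()
        out["poisson_plant_level"] = {
            "coef": {"const": float(pois.params[0]),
                     "rosette_branches": float(pois.params[1])},
            "se": {"const": float(pois.bse[0]),
                   "rosette_branches": float(pois.bse[1])},
            "p": {"const": float(pois.pvalues[0]),
                  "rosette_branches": float(pois.pvalues[1])},
            "n": int(pois.nobs),
        }
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney rank test
# ---------------------------------------------------------------------------

def rank_test(x, y, exact_max_n: int = 20) -> dict:
    """Two-sided Mann-Whitney U test with tie handling.

    For combined samples of at most ``exact_max_n`` observations the null
    distribution of U is enumerated exactly over all assignments of the
    pooled (mid-)ranks, which remains valid under ties; larger samples use
    the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if n1 + n2 <= exact_max_n:
        us = np.array([
            ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
            for idx in combinations(range(n1 + n2), n1)
        ])
        # null distribution is symmetric about n1*n2/2 even under ties
        p_lo = np.mean(us <= u1)
        p_hi = np.mean(us >= u1)
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        method = "exact"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        p = float(res.pvalue)
        method = "normal-approx"
    return {"u": u1, "p": float(p), "method": method, "n1": n1, "n2": n2}
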