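"""Comparative statistics across genotypes.

Four tools used throughout the analysis:

* Dunnett many-to-one comparisons of genotype means against a control
  (Col FRI), with the multiplicity adjustment evaluated by seeded
  Monte-Carlo over the equicoordinate multivariate-t distribution of the
  maximum absolute contrast statistic.
* Mixed-model slope contrasts: shutdown-rate differences tested as
  genotype x timepoint interactions in a REML random-intercept (block)
  model with Satterthwaite degrees of freedom, timepoints centered to
  mean 0.
* The asymptotic (Feltz-Miller) test of equality of coefficients of
  variation across groups.
* Benjamini-Hochberg step-up FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mixedlm import RandomInterceptModel

__all__ = [
    "dunnett_vs_control",
    "mixed_slope_contrasts",
    "CVTestResult",
    "cv_equality_test",
    "bh_adjust",
    "variability_report",
]


# ---------------------------------------------------------------------------
# Dunnett many-to-one
# ---------------------------------------------------------------------------

def _as_group_dict(data) -> dict:
    if isinstance(data, pd.DataFrame):
        return {g: grp.iloc[:, -1].to_numpy(dtype=float)
                for g, grp in data.groupby(data.columns[0], sort=False)}
    return {k: np.asarray(v, dtype=float) for k, v in dict(data).items()}


def dunnett_vs_control(
    data,
    control: str,
    alpha: float = 0.05,
    mc_draws: int = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare every group mean against the control group's mean.

    ``data`` is a mapping of group label -> values (or a two-column
    DataFrame of (group, value)).  A one-way fixed-effects model with
    pooled residual variance supplies the t statistics; the adjusted p for
    each contrast is P(max_j |T_j| >= |t_i|) under the joint null, with
    the multivariate-t probability evaluated by ``mc_draws`` seeded draws.
    The Monte-Carlo standard error of each adjusted p is reported.
    """
    groups = _as_group_dict(data)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if control not in groups:
        raise ValueError(f"control group {control!r} not present")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    labels = [g for g in groups if g != control]
    y0 = groups[control]
    n0 = len(y0)
    n_tot = sum(len(v) for v in groups.values())
    k = len(groups)
    nu = n_tot - k
    ss = sum(float(np.sum((v - v.mean()) ** 2)) for v in groups.values())
    s2 = ss / nu
    if s2 <= 0:
        raise ValueError("zero residual variance: all groups are constant")

    ns = np.array([len(groups[g]) for g in labels], dtype=float)
    diffs = np.array([groups[g].mean() - y0.mean() for g in labels])
    ses = np.sqrt(s2 * (1.0 / ns + 1.0 / n0))
    ts = diffs / ses

    # correlation structure: corr_ij = lam_i * lam_j
    lam = (1.0 / np.sqrt(n0)) / np.sqrt(1.0 / ns + 1.0 / n0)
    rng = np.random.default_rng(seed)
    max_abs_t = np.empty(mc_draws)
    chunk = 50_000
    done = 0
    while done < mc_draws:
        m = min(chunk, mc_draws - done)
        z0 = rng.standard_normal(m)
        e = rng.standard_normal((m, len(labels)))
        z = lam[None, :] * z0[:, None] + np.sqrt(1 - lam**2)[None, :] * e
        w = rng.chisquare(nu, m) / nu
        max_abs_t[done:done + m] = np.abs(z / np.sqrt(w)[:, None]).max(axis=1)
        done += m
    p_adj = np.array([np.mean(max_abs_t >= abs(t)) for t in ts])
    mc_se = np.sqrt(p_adj * (1 - p_adj) / mc_draws)

    out = pd.DataFrame({
        "group": labels,
        "estimate": diffs,
        "se": ses,
        "t": ts,
        "p_adj": p_adj,
        "mc_se": mc_se,
        "significant": p_adj < alpha,
    })
    out.attrs.update(control=control, alpha=alpha, df=nu, mc_draws=mc_draws)
    return out


# ---------------------------------------------------------------------------
# Mixed-model slope contrasts
# ---------------------------------------------------------------------------

def mixed_slope_contrasts(
    data: pd.DataFrame,
    reference: str,
    value_col: str = "value_au",
) -> pd.DataFrame:
    """Test genotype differences in shutdown slope against a reference.

    Fits value ~ genotype + day + genotype:day with a random intercept per
    block by REML, after centering day to mean 0.  Each genotype:day
    interaction (slope difference vs the reference genotype) is reported
    with its Satterthwaite-approximated denominator df, t and p, plus the
    block and residual variance components.  With a single block the model
    degenerates to fixed-effects OLS (residual df) and a warning column
    records the fallback.
    """
    df = data.copy()
    genos = list(pd.unique(df["genotype"]))
    if reference not in genos:
        raise ValueError(f"reference genotype {reference!r} not present")
    if len(genos) < 2:
        raise ValueError("need at least two genotypes")
    if df["day"].nunique() < 2:
        raise ValueError("need at least two distinct days")
    others = [g for g in genos if g != reference]

    dayc = df["day"].astype(float) - df["day"].astype(float).mean()
    X_cols = [np.ones(len(df)), dayc.to_numpy()]
    names = ["intercept", "day"]
    for g in others:
        ind = (df["genotype"] == g).astype(float).to_numpy()
        X_cols += [ind, ind * dayc.to_numpy()]
        names += [f"geno[{g}]", f"slope_diff[{g}]"]
    X = np.column_stack(X_cols)
    y = df[value_col].to_numpy(dtype=float)

    n_blocks = df["block"].nunique() if "block" in df else 1
    warns: list[str] = []
    if n_blocks < 2:
        warns.append("single block: fell back to fixed-effects OLS")
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dfres = len(y) - X.shape[1]
        s2 = float(resid @ resid) / dfres
        cov = s2 * np.linalg.inv(X.T @ X)
        rows = []
        for g in others:
            j = names.index(f"slope_diff[{g}]")
            est, se = beta[j], np.sqrt(cov[j, j])
            t = est / se
            rows.append((g, est, se, float(dfres), t, 2 * stats.t.sf(abs(t), dfres)))
        out = pd.DataFrame(rows, columns=["genotype", "estimate", "se", "df", "t", "p"])
        out.attrs.update(sigma2_block=0.0, sigma2_resid=s2,
                         reference=reference, warnings=warns)
        return out

    model = RandomInterceptModel(y, X, df["block"].to_numpy())
    fit = model.fit()
    rows = []
    for g in others:
        c = np.zeros(X.shape[1])
        c[names.index(f"slope_diff[{g}]")] = 1.0
        r = fit.contrast(c)
        rows.append((g, r["estimate"], r["se"], r["df"], r["t"], r["p"]))
    out = pd.DataFrame(rows, columns=["genotype", "estimate", "se", "df", "t", "p"])
    out.attrs.update(sigma2_block=fit.sigma2_block, sigma2_resid=fit.sigma2_resid,
                     reference=reference, warnings=warns + fit.warnings)
    return out


# ---------------------------------------------------------------------------
# CV-equality (Feltz-Miller asymptotic) test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVTestResult:
    labels: tuple
    n: tuple
    mean: tuple
    sd: tuple
    cv: tuple
    statistic: float
    df: int
    p: float


def cv_equality_test(groups) -> CVTestResult:
    """Asymptotic chi-square test of equal coefficients of variation.

    With per-group cv_i = sd_i/mean_i and the (n_i - 1)-weighted pooled
    cv-bar, the statistic

        D = sum_i (n_i - 1) (cv_i - cv-bar)^2 / (cv-bar^2 (0.5 + cv-bar^2))

    is referred to chi-square with k - 1 degrees of freedom.  Invariant to
    rescaling any group by a positive constant.
    """
    if isinstance(groups, dict):
        labels, arrays = zip(*groups.items())
    else:
        arrays = tuple(groups)
        labels = tuple(range(len(arrays)))
    arrays = [np.asarray(a, dtype=float) for a in arrays]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    ns, means, sds, cvs = [], [], [], []
    for lab, a in zip(labels, arrays):
        if len(a) < 2:
            raise ValueError(f"group {lab!r} has n < 2")
        m = float(a.mean())
        if m == 0:
            raise ValueError(f"group {lab!r} has mean 0; cv undefined")
        ns.append(len(a))
        means.append(m)
        sds.append(float(a.std(ddof=1)))
        cvs.append(sds[-1] / m)
    ns_a = np.asarray(ns, dtype=float)
    cvs_a = np.asarray(cvs)
    w = ns_a - 1.0
    cvbar = float(np.sum(w * cvs_a) / np.sum(w))
    k = len(arrays)
    if cvbar == 0:
        statistic, p = 0.0, 1.0
    else:
        statistic = float(np.sum(w * (cvs_a - cvbar) ** 2)
                          / (cvbar**2 * (0.5 + cvbar**2)))
        p = float(stats.chi2.sf(statistic, k - 1))
    return CVTestResult(tuple(labels), tuple(ns), tuple(means), tuple(sds),
                        tuple(cvs), statistic, k - 1, p)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_adjust(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-up FDR control; returns (reject flags, adjusted p) in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    # adjusted p: running minimum from the largest rank downwards
    adj_sorted = np.minimum.accumulate((m * ranked / np.arange(1, m + 1))[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    passing = np.flatnonzero(ranked <= np.arange(1, m + 1) * q / m)
    reject_sorted = np.zeros(m, dtype=bool)
    if passing.size:
        reject_sorted[: passing.max() + 1] = True
    reject = np.empty(m, dtype=bool)
    adjusted = np.empty(m)
    reject[order] = reject_sorted
    adjusted[order] = adj_sorted
    return reject, adjusted


# ---------------------------------------------------------------------------
# Variability report (CV comparisons across features and sites)
# ---------------------------------------------------------------------------

_FEATURE_COLS = {
    "starting": "start_mean",
    "vindep": "rate_vindep",
    "vdep": "rate_vdep",
    "combined": "combined_rate",
}


def _feature_long(features: pd.DataFrame) -> pd.DataFrame:
    """Genotype-level feature values in long form; rates as magnitudes."""
    features = features.reset_index(drop=True)
    rows = []
    site = features["site"] if "site" in features else pd.Series("site", index=features.index)
    year = features["year"] if "year" in features else pd.Series(0, index=features.index)
    for feat, col in _FEATURE_COLS.items():
        if col not in features:
            continue
        vals = features[col].astype(float)
        vals = vals if feat == "starting" else vals.abs()
        keep = vals.notna()
        for i in features.index[keep]:
            rows.append((features.loc[i, "genotype"], site.loc[i], year.loc[i],
                         feat, float(vals.loc[i])))
    return pd.DataFrame(rows, columns=["genotype", "site", "year", "feature", "value"])


def variability_report(
    features: pd.DataFrame,
    grouping: dict[str, list] | None = None,
    q: float = 0.05,
    min_group: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CVs of decay features per site-year, with CV-equality tests.

    ``features`` is the frame from :func:`vernadyn.decay.extract_features`
    (rates enter as magnitudes).  ``grouping`` maps scheme names to
    genotype subsets (e.g. accessions / NILs / combined); by default one
    scheme over all genotypes.  Two families of tests are run per scheme:
    starting-levels-vs-each-rate within a site-year, and site-vs-site per
    feature, all BH-corrected together at FDR ``q``.  Comparisons with a
    group below ``min_group`` genotype values are reported as skipped.
    """
    long = _feature_long(features)
    schemes = grouping or {"all": sorted(long["genotype"].unique())}
    cv_rows, test_rows = [], []
    for scheme, genos in schemes.items():
        sub = long[long["genotype"].isin(genos)]
        for (site, year, feat), grp in sub.groupby(["site", "year", "feature"]):
            v = grp["value"].to_numpy()
            if len(v) >= 2 and v.mean() != 0:
                cv = float(v.std(ddof=1) / v.mean())
            else:
                cv = np.nan
            cv_rows.append((scheme, site, year, feat, len(v),
                            float(v.mean()) if len(v) else np.nan,
                            float(v.std(ddof=1)) if len(v) >= 2 else np.nan, cv))
        # starting vs rates within each site-year
        for (site, year), grp in sub.groupby(["site", "year"]):
            by_feat = {f: g["value"].to_numpy() for f, g in grp.groupby("feature")}
            start = by_feat.get("starting")
            for feat in ("vindep", "vdep", "combined"):
                other = by_feat.get(feat)
                if other is None or start is None:
                    continue
                test_rows.append(_run_cv_test(
                    scheme, f"starting-vs-{feat} @ {site} {year}",
                    {"starting": start, feat: other}, min_group))
        # site-vs-site per feature
        for feat, grp in sub.groupby("feature"):
            by_site = {f"{s} {y}": g["value"].to_numpy()
                       for (s, y), g in grp.groupby(["site", "year"])}
            if len(by_site) >= 2:
                test_rows.append(_run_cv_test(
                    scheme, f"site-vs-site ({feat})", by_site, min_group))

    cvs = pd.DataFrame(cv_rows, columns=["scheme", "site", "year", "feature",
                                         "n", "mean", "sd", "cv"])
    tests = pd.DataFrame(test_rows, columns=["scheme", "comparison", "groups",
                                             "statistic", "df", "p", "note"])
    tests["p_adj"] = np.nan
    tests["reject"] = False
    ok = tests["p"].notna()
    if ok.any():
        reject, adj = bh_adjust(tests.loc[ok, "p"].to_numpy(), q=q)
        tests.loc[ok, "p_adj"] = adj
        tests.loc[ok, "reject"] = reject
    tests.attrs["rates_as_magnitudes"] = True
    tests.attrs["fdr_q"] = q
    return cvs, tests


def _run_cv_test(scheme, comparison, groups: dict, min_group: int):
    small = [k for k, v in groups.items() if len(v) < min_group]
    if small:
        return (scheme, comparison, ";".join(groups), np.nan, np.nan, np.nan,
                f"skipped: group(s) below minimum size: {','.join(map(str, small))}")
    try:
        res = cv_equality_test(groups)
    except ValueError as err:
        return (scheme, comparison, ";".join(groups), np.nan, np.nan, np.nan,
                f"skipped: {err}")
    return (scheme, comparison, ";".join(groups), res.statistic, res.df, res.p, "")
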