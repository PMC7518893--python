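"""The FLC-post-vern statistic: days-to-bolting per unit of FLC at transfer.

For each genotype and site, mean days-to-bolting of plants transferred
from the field to warm inductive conditions is regressed on mean FLC
abundance at the time of transfer:

    days to bolting = m * [FLC mRNA] + c

The slope m is the FLC-post-vern value: for a given FLC level at
transfer, a genotype with larger m flowers later.  Fits on exactly two
transfer dates return the exact slope and intercept but no standard
error; fits whose slope p-value exceeds 0.1 (or is unavailable) are
flagged unreliable.  Per-site values are averaged unrounded across sites;
half-up rounding to one decimal is applied only for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PostVernFit",
    "fit_postvern",
    "average_postvern",
    "postvern_points",
    "postvern_table",
    "round_half_up",
]


@dataclass(frozen=True)
class PostVernFit:
    genotype: str
    site: str
    m: float | None
    c: float | None
    se_m: float | None
    p_m: float | None
    n_points: int
    reliable: bool
    reason: str = ""


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (1.25 -> 1.3), as used for report tables."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def fit_postvern(
    points,
    genotype: str = "",
    site: str = "",
    degenerate_tol: float = 1e-12,
) -> PostVernFit:
    """OLS of mean bolting time on mean FLC at transfer.

    ``points`` is a sequence of (mean FLC a.u., mean days-to-bolting)
    pairs, one per transfer date, censored transfers excluded upstream.
    With exactly two points the slope and intercept are exact but se/p are
    unavailable and the fit is flagged unreliable.  Genotypes with no FLC
    spread across transfers (the low-FLC case where bolting differences
    cannot be resolved) return an inestimable result rather than a fit.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (FLC, bolting) points")
    x, y = pts[:, 0], pts[:, 1]
    if float(np.ptp(x)) <= degenerate_tol:
        return PostVernFit(genotype, site, None, None, None, None, len(x),
                           False, "inestimable (no FLC spread)")
    if len(x) == 2:
        m = float((y[1] - y[0]) / (x[1] - x[0]))
        c = float(y[0] - m * x[0])
        return PostVernFit(genotype, site, m, c, None, None, 2, False,
                           "two-point fit: no standard error is calculable")
    res = stats.linregress(x, y)
    p = float(res.pvalue)
    reliable = p <= 0.1
    return PostVernFit(
        genotype, site, float(res.slope), float(res.intercept),
        float(res.stderr), p, len(x), reliable,
        "" if reliable else f"unreliable (p={p:.3g} > 0.1)",
    )


def average_postvern(site_fits) -> dict:
    """Cross-site arithmetic mean of the available per-site m values.

    ``site_fits`` is a sequence of :class:`PostVernFit` (or bare m
    values).  Single-site genotypes return that site's m.
    """
    ms, sites = [], []
    for f in site_fits:
        if isinstance(f, PostVernFit):
            if f.m is not None:
                ms.append(f.m)
                sites.append(f.site)
        elif f is not None and np.isfinite(f):
            ms.append(float(f))
            sites.append("")
    if not ms:
        raise ValueError("no site fit with an estimable m")
    return {"average_m": float(np.mean(ms)), "n_sites": len(ms), "sites": sites}


def postvern_points(
    bolting: pd.DataFrame,
    expression_at_transfer: pd.DataFrame | None = None,
    genotype: str | None = None,
) -> tuple[np.ndarray, dict]:
    """Genotype-level (mean FLC, mean bolting) pairs per transfer date.

    Censored (DNF) and dead plants are excluded from the bolting means;
    the exclusion count is returned alongside.  FLC at transfer comes from
    a ``flc_at_transfer`` column when present, else from joining
    ``expression_at_transfer`` (genotype, day, value_au) on the transfer day.
    """
    df = bolting if genotype is None else bolting[bolting["genotype"] == genotype]
    excluded = 0
    if "dnf" in df:
        excluded += int(df["dnf"].sum())
        df = df[~df["dnf"].astype(bool)]
    if "dead" in df:
        excluded += int(df["dead"].sum())
        df = df[~df["dead"].astype(bool)]
    df = df[df["days_to_bolting"].notna()]
    mean_bolt = df.groupby("transfer_day")["days_to_bolting"].mean()
    if "flc_at_transfer" in df:
        mean_flc = df.groupby("transfer_day")["flc_at_transfer"].mean()
    else:
        if expression_at_transfer is None:
            raise ValueError(
                "no flc_at_transfer column and no expression table supplied"
            )
        sub = expression_at_transfer
        if genotype is not None:
            sub = sub[sub["genotype"] == genotype]
        mean_flc = sub.groupby("day")["value_au"].mean()
        mean_flc.index.name = "transfer_day"
    joined = pd.concat([mean_flc.rename("flc"), mean_bolt.rename("bolt")],
                       axis=1).dropna()
    pts = joined[["flc", "bolt"]].to_numpy()
    return pts, {"n_excluded": excluded, "transfer_days": joined.index.tolist()}


def postvern_table(
    bolting: pd.DataFrame,
    expression_at_transfer: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-genotype, per-site post-vern fits plus the cross-site average.

    Mirrors the report-table layout: one row per genotype with per-site m,
    se and p, the unrounded cross-site average, and a display-rounded
    average (half-up, one decimal).
    """
    fits: dict[str, list[PostVernFit]] = {}
    site_col = bolting["site"] if "site" in bolting else pd.Series("site", index=bolting.index)
    for (g, site), grp in bolting.groupby([bolting["genotype"], site_col]):
        try:
            pts, info = postvern_points(grp, expression_at_transfer, genotype=None)
            fit = fit_postvern(pts, genotype=g, site=site)
        except ValueError as err:
            fit = PostVernFit(g, site, None, None, None, None, 0, False, str(err))
        fits.setdefault(g, []).append(fit)

    rows = []
    for g, site_fits in fits.items():
        rec: dict = {"genotype": g}
        for f in site_fits:
            rec[f"m_{f.site}"] = f.m
            rec[f"se_{f.site}"] = f.se_m
            rec[f"p_{f.site}"] = f.p_m
            rec[f"reliable_{f.site}"] = f.reliable
        try:
            avg = average_postvern(site_fits)
            rec["average_m"] = avg["average_m"]
            rec["average_m_display"] = round_half_up(avg["average_m"], 1)
            rec["n_sites"] = avg["n_sites"]
        except ValueError as err:
            rec["average_m"] = np.nan
            rec["average_m_display"] = np.nan
            rec["n_sites"] = 0
            rec["note"] = str(err)
        rows.append(rec)
    return pd.DataFrame(rows)
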