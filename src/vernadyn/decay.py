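"""Decay-feature extraction: starting level and phase-specific shutdown rates.

Each genotype x site x year expression time course is summarised by three
features: the mean FLC abundance at the first field timepoint (starting
level), the slope of decline before VIN3 induction (VIN3-independent
rate) and the slope after it (VIN3-dependent rate).  When the two phases
are not separable (VIN3 induced from the outset) a single combined rate
is fitted, optionally excluding late timepoints where spring reactivation
sets in.  Slopes come from ordinary least squares on replicate-level
points, on the linear scale by default (rates in a.u./day); a log scale
is available for exponential-decay fitting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["starting_level", "fit_phase_rate", "extract_features"]


def starting_level(
    expression: pd.DataFrame,
    gene: str = "FLC",
    value_col: str = "value_au",
) -> pd.DataFrame:
    """Mean +/- se of replicate values at the earliest sampled day per genotype."""
    sub = expression[expression["gene"] == gene] if "gene" in expression else expression
    if len(sub) == 0:
        raise ValueError(f"no expression rows for gene {gene!r}")
    first_day = sub["day"].min()
    rows = []
    for g, grp in sub.groupby("genotype", sort=False):
        at_first = grp[grp["day"] == first_day][value_col].dropna()
        if len(at_first) == 0:
            raise ValueError(
                f"genotype {g!r} has no records at the first timepoint "
                f"(day {first_day})"
            )
        n = len(at_first)
        mean = float(at_first.mean())
        se = float(at_first.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append((g, first_day, mean, se, n))
    return pd.DataFrame(
        rows, columns=["genotype", "day", "start_mean", "start_se", "start_n"]
    )


def fit_phase_rate(
    days,
    values,
    window: tuple[float, float] | None = None,
    scale: str = "linear",
) -> dict:
    """OLS slope of value (or log value) on day within a window.

    Returns a dict with slope, se, intercept, p, n points and number of
    distinct days.  Declining series give negative slopes.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if window is not None:
        lo, hi = window
        keep = (days >= lo) & (days <= hi)
        days, values = days[keep], values[keep]
    ok = np.isfinite(days) & np.isfinite(values)
    days, values = days[ok], values[ok]
    n_days = len(np.unique(days))
    if n_days < 2:
        raise ValueError(
            f"phase window has {n_days} distinct day(s); >= 2 required"
        )
    if scale == "log":
        bad = np.flatnonzero(values <= 0)
        if bad.size:
            raise ValueError(
                "log-scale fit requires positive values; offending records at "
                f"positions {bad.tolist()} (days {days[bad].tolist()})"
            )
        y = np.log(values)
    elif scale == "linear":
        y = values
    else:
        raise ValueError(f"unknown scale {scale!r}")
    res = stats.linregress(days, y)
    return {
        "slope": float(res.slope),
        "se": float(res.stderr) if len(days) > 2 else np.nan,
        "intercept": float(res.intercept),
        "p": float(res.pvalue) if len(days) > 2 else np.nan,
        "n": int(len(days)),
        "n_days": int(n_days),
    }


def _safe_fit(days, values, scale):
    try:
        return fit_phase_rate(days, values, scale=scale), ""
    except ValueError as err:
        return None, str(err)


def extract_features(
    expression: pd.DataFrame,
    breakpoint=None,
    mode: str = "two_phase",
    scale: str = "linear",
    exclusion_after_day: float | None = None,
    gene: str = "FLC",
    boundary: str | None = None,
) -> pd.DataFrame:
    """Per-genotype decay features from a tidy expression table.

    ``breakpoint`` may be a number of days or a
    :class:`~vernadyn.induction.BreakpointEstimate`; required when
    ``mode="two_phase"``.  ``boundary`` controls which window owns the
    breakpoint day itself: ``"pre"`` places it in the VIN3-independent
    window (the default for a fixed day, read as the last slow-phase
    day), ``"post"`` in the VIN3-dependent window (the default for a
    detected estimate, whose day is the first with VIN3 already high).  In
    ``combined`` mode a single rate is fitted over all days, dropping
    measurements after ``exclusion_after_day`` (late-winter reactivation).
    Phase windows with fewer than two distinct days yield NaN features
    with the reason recorded in the ``note`` column, never a silent NaN.
    """
    if mode not in ("two_phase", "combined"):
        raise ValueError(f"unknown mode {mode!r}")
    bp_day = getattr(breakpoint, "day", breakpoint)
    if boundary is None:
        boundary = "post" if hasattr(breakpoint, "day") else "pre"
    if mode == "two_phase":
        if bp_day is None:
            raise ValueError("two_phase mode requires a breakpoint day")
        bp_day = float(bp_day)
    if boundary not in ("pre", "post"):
        raise ValueError(f"unknown boundary convention {boundary!r}")

    sub = expression[expression["gene"] == gene] if "gene" in expression else expression
    starts = starting_level(sub, gene=gene).set_index("genotype")

    rows = []
    group_cols = [c for c in ("site", "year") if c in sub.columns]
    for g, grp in sub.groupby("genotype", sort=False):
        days = grp["day"].to_numpy(dtype=float)
        vals = grp["value_au"].to_numpy(dtype=float)
        if exclusion_after_day is not None:
            keep = days <= exclusion_after_day
            days, vals = days[keep], vals[keep]
        notes = []
        rec = {
            "genotype": g,
            **{c: grp[c].iloc[0] for c in group_cols},
            "start_mean": starts.loc[g, "start_mean"],
            "start_se": starts.loc[g, "start_se"],
            "start_n": starts.loc[g, "start_n"],
            "rate_vindep": np.nan, "rate_vindep_se": np.nan,
            "rate_vdep": np.nan, "rate_vdep_se": np.nan,
            "combined_rate": np.nan, "combined_rate_se": np.nan,
            "mode": mode, "scale": scale,
            "breakpoint_day": bp_day if mode == "two_phase" else np.nan,
            "exclusion_after_day": exclusion_after_day,
        }
        if mode == "two_phase":
            pre = days <= bp_day if boundary == "pre" else days < bp_day
            fit, why = _safe_fit(days[pre], vals[pre], scale)
            if fit:
                rec["rate_vindep"] = fit["slope"]
                rec["rate_vindep_se"] = fit["se"]
            else:
                notes.append(f"VIN3-independent rate unavailable: {why}")
            fit, why = _safe_fit(days[~pre], vals[~pre], scale)
            if fit:
                rec["rate_vdep"] = fit["slope"]
                rec["rate_vdep_se"] = fit["se"]
            else:
                notes.append(f"VIN3-dependent rate unavailable: {why}")
        else:
            fit, why = _safe_fit(days, vals, scale)
            if fit:
                rec["combined_rate"] = fit["slope"]
                rec["combined_rate_se"] = fit["se"]
            else:
                notes.append(f"combined rate unavailable: {why}")
        rec["note"] = "; ".join(notes)
        rows.append(rec)
    return pd.DataFrame(rows)
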