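"""Detection of the VIN3 induction day that splits the two fitting phases.

VIN3 is essentially off through early autumn and rises sharply once cold
accumulates; the day of substantial upregulation separates the
VIN3-independent and VIN3-dependent phases of FLC shutdown.  The rule
implemented here is threshold-based: a baseline is taken as the median of
the first few genotype-mean values, and induction is called at the first
sampled day whose value exceeds max(baseline x fold, an absolute floor)
for a run of consecutive timepoints.  The breakpoint is estimated from a
reference genotype and shared across genotypes at a site, since induction
timing is driven by the site's temperature profile.  A fixed day may be
supplied instead wherever a breakpoint is accepted downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BreakpointEstimate", "detect_induction", "detect_induction_from_table"]


@dataclass(frozen=True)
class BreakpointEstimate:
    day: float | None
    baseline: float
    threshold: float
    method: str
    supported: bool
    detected: bool

    def __bool__(self) -> bool:  # truthiness == was induction found
        return self.detected


def detect_induction(
    days,
    values,
    baseline_points: int = 3,
    fold: float = 3.0,
    min_consecutive: int = 2,
    abs_floor: float = 0.05,
) -> BreakpointEstimate:
    """Find the first day of sustained induction in a mean VIN3 series.

    ``days``/``values`` are the genotype-mean series, days strictly
    increasing, values >= 0.  Returns a no-induction-detected estimate
    (``detected=False``, ``day=None``) when no day qualifies — mutants with
    delayed VIN3 are an expected input, not an error.  Setting
    ``abs_floor=0`` disables the absolute floor, making the rule invariant
    to rescaling the series.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.ndim != 1 or days.shape != values.shape:
        raise ValueError("days and values must be 1-D and equally long")
    if not np.all(np.diff(days) > 0):
        raise ValueError("days must be strictly increasing")
    if np.any(values < 0):
        raise ValueError("values must be >= 0")
    if baseline_points < 1 or min_consecutive < 1:
        raise ValueError("baseline_points and min_consecutive must be >= 1")
    if len(days) < baseline_points + min_consecutive:
        raise ValueError(
            f"need >= baseline_points + min_consecutive = "
            f"{baseline_points + min_consecutive} timepoints, got {len(days)}"
        )
    if fold <= 0:
        raise ValueError("fold must be > 0")

    baseline = float(np.median(values[:baseline_points]))
    threshold = max(baseline * fold, abs_floor)
    above = values > threshold
    day = None
    for i in range(len(days) - min_consecutive + 1):
        if above[i: i + min_consecutive].all():
            day = float(days[i])
            break
    if day is None:
        return BreakpointEstimate(None, baseline, threshold,
                                  "threshold-crossing", False, False)
    supported = int(np.sum(days >= day)) >= 2
    return BreakpointEstimate(day, baseline, threshold,
                              "threshold-crossing", supported, True)


def detect_induction_from_table(
    expression: pd.DataFrame,
    gene: str = "VIN3",
    reference_genotype: str = "ColFRI",
    **kwargs,
) -> BreakpointEstimate:
    """Aggregate replicates to genotype means and run :func:`detect_induction`."""
    sub = expression[(expression["gene"] == gene)
                     & (expression["genotype"] == reference_genotype)]
    if len(sub) == 0:
        raise ValueError(
            f"no rows for gene={gene!r}, genotype={reference_genotype!r}"
        )
    series = sub.groupby("day")["value_au"].mean().sort_index()
    return detect_induction(series.index.to_numpy(), series.to_numpy(), **kwargs)
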