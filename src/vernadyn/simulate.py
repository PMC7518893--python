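"""Synthetic field-experiment generator with known ground truth.

Emulates the design of a multi-site Arabidopsis vernalization field study:
FLC transcript abundance declining through autumn/winter in two phases
split by the day of VIN3 induction, warm-transfer bolting experiments in
which days-to-bolting is linear in FLC at transfer, and an overwinter
fitness census (precocious bolting, survival, branching, siliques).

Every simulated table is paired with a truth table so downstream fitting
stages can be tested for parameter recovery without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeParams",
    "SimulationConfig",
    "default_genotypes",
    "mean_trajectory",
    "simulate_expression",
    "simulate_transfers",
    "simulate_fitness",
    "truth_table",
]


@dataclass(frozen=True)
class GenotypeParams:
    """Ground-truth parameters for one genotype.

    ``starting_level`` is the FLC abundance (a.u.) at day 0; ``rate_vindep``
    and ``rate_vdep`` are decline magnitudes (a.u./day in linear mode,
    /day in exponential mode) before and after the VIN3-induction
    breakpoint.  ``postvern_m``/``postvern_c`` parameterise the warm-transfer
    bolting response days-to-bolting = m * FLC(t_transfer) + c.  The
    remaining fields drive the overwinter fitness census.
    """

    genotype_id: str
    starting_level: float
    rate_vindep: float
    rate_vdep: float
    postvern_m: float = 37.0
    postvern_c: float = 20.0
    precocity_logit_slope: float = 1.0
    survival_penalty_logit: float = 1.0
    branch_base: float = 12.0
    branch_postvern_slope: float = 0.15

    def __post_init__(self) -> None:
        if not self.starting_level > 0:
            raise ValueError(
                f"starting_level must be > 0 for {self.genotype_id!r}, "
                f"got {self.starting_level}"
            )
        for name in ("rate_vindep", "rate_vdep"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(
                    f"{name} must be finite and >= 0 for {self.genotype_id!r}, got {v}"
                )


def default_genotypes() -> list[GenotypeParams]:
    """Six genotypes spanning the haplotype behaviours seen in the field.

    Rapidly-vernalizing (RV-like) genotypes start lower and shut down
    faster; slowly-vernalizing (SV-like) genotypes start higher and are
    slower in *both* phases.  The early phase is slower than the
    VIN3-dependent phase in a.u./day for the reference-like genotypes
    (slow-then-fast shutdown), while levels remain positive across a
    ~110-day sampling window.
    """
    return [
        GenotypeParams("ColFRI", 10.0, 0.05, 0.20, postvern_m=37.8, postvern_c=20.0,
                       precocity_logit_slope=0.6, branch_base=12.0),
        GenotypeParams("vin3-like", 11.0, 0.05, 0.05, postvern_m=59.1, postvern_c=22.0,
                       precocity_logit_slope=0.6, branch_base=8.0),
        GenotypeParams("RV-NIL", 7.0, 0.06, 0.115, postvern_m=36.7, postvern_c=19.0,
                       precocity_logit_slope=0.6, branch_base=11.0),
        GenotypeParams("SV-NIL", 16.0, 0.04, 0.30, postvern_m=24.0, postvern_c=20.0,
                       precocity_logit_slope=0.6, branch_base=14.0),
        GenotypeParams("RV-acc", 5.0, 0.05, 0.07, postvern_m=32.4, postvern_c=15.0,
                       precocity_logit_slope=0.6, branch_base=10.0),
        GenotypeParams("SV-acc", 20.0, 0.05, 0.15, postvern_m=49.0, postvern_c=25.0,
                       precocity_logit_slope=0.6, branch_base=13.0),
    ]


@dataclass
class SimulationConfig:
    """Design of one simulated site-year.

    Defaults mirror the field-study design: six replicates in three
    randomised blocks per genotype and timepoint, twelve plants per
    warm-transfer date, 36 plants in the overwinter census, and a
    Norwich-like VIN3 induction day of 48 days after sowing.
    """

    genotypes: list[GenotypeParams] = field(default_factory=default_genotypes)
    timepoints: Sequence[int] = (21, 28, 35, 42, 48, 55, 62, 69, 76, 83, 90, 97)
    breakpoint_day: float = 48.0
    n_replicates: int = 6
    n_blocks: int = 3
    noise_sd_log: float = 0.2
    block_sd_log: float = 0.1
    transfer_days: Sequence[int] = (48, 62, 76, 90)
    n_transfer_plants: int = 12
    bolting_noise_sd: float = 5.0
    max_followup_days: float = 205.0
    seed: int = 0
    decline: str = "linear"  # or "exponential"
    floor: float = 0.01
    site: str = "NorthSweden"
    year: int = 2016
    # VIN3 marker series
    vin3_baseline: float = 0.05
    vin3_induced: float = 1.5
    # overwinter fitness census
    n_fitness_plants: int = 36
    autumn_census_day: int = 42
    precocity_intercept: float = 2.0
    survival_base_logit: float = 0.7
    branch_noise_sd: float = 1.5
    silique_alpha: float = 3.0
    silique_beta: float = 0.12

    def validate(self, two_phase: bool = True) -> None:
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.ndim != 1 or len(tp) < 2 or not np.all(np.diff(tp) > 0):
            raise ValueError("timepoints must be a strictly increasing sequence")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.noise_sd_log < 0 or self.block_sd_log < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.bolting_noise_sd < 0:
            raise ValueError("bolting_noise_sd must be >= 0")
        if self.decline not in ("linear", "exponential"):
            raise ValueError(f"unknown decline mode {self.decline!r}")
        if two_phase:
            n_pre = int(np.sum(tp <= self.breakpoint_day))
            n_post = int(np.sum(tp > self.breakpoint_day))
            if n_pre < 2 or n_post < 2:
                raise ValueError(
                    "two-phase simulation requires >= 2 timepoints on each side "
                    f"of breakpoint_day={self.breakpoint_day} "
                    f"(got {n_pre} before, {n_post} after)"
                )


def mean_trajectory(
    t,
    starting_level: float,
    rate_vindep: float,
    rate_vdep: float,
    breakpoint_day: float,
    decline: str = "linear",
    floor: float = 0.01,
):
    """Noiseless piecewise FLC trajectory, continuous at the breakpoint.

    Linear mode: E(t) = S - r1*t for t <= T*, then E(T*) - r2*(t - T*).
    Exponential mode: S*exp(-r1*t), then E(T*)*exp(-r2*(t - T*)).
    Values are truncated below at ``floor``.
    """
    t = np.asarray(t, dtype=float)
    S, r1, r2, T = starting_level, rate_vindep, rate_vdep, breakpoint_day
    if decline == "linear":
        at_break = S - r1 * T
        out = np.where(t <= T, S - r1 * t, at_break - r2 * (t - T))
    elif decline == "exponential":
        at_break = S * np.exp(-r1 * T)
        out = np.where(t <= T, S * np.exp(-r1 * t), at_break * np.exp(-r2 * (t - T)))
    else:
        raise ValueError(f"unknown decline mode {decline!r}")
    return np.maximum(out, floor)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_expression(
    config: SimulationConfig, two_phase: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the normalized-expression table and its truth table.

    Returns a tidy frame with one row per genotype x timepoint x replicate
    x gene (genes ``FLC`` and ``VIN3``) and columns
    (genotype, site, year, day, block, replicate, gene, value_au).
    Replicate values are mean trajectory x exp(N(0, noise_sd_log^2)) x a
    log-normal block effect shared by all genotypes in a block.
    """
    config.validate(two_phase=two_phase)
    rng = _rng(config.seed)
    days = np.asarray(config.timepoints, dtype=float)
    n_rep = config.n_replicates

    # one multiplicative effect per block x day, shared across genotypes
    block_eff = np.exp(
        rng.normal(0.0, config.block_sd_log, size=(config.n_blocks, len(days)))
    )
    blocks = np.arange(n_rep) % config.n_blocks

    vin3_mean = np.where(
        days <= config.breakpoint_day, config.vin3_baseline, config.vin3_induced
    )

    rows = []
    for g in config.genotypes:
        flc_mean = mean_trajectory(
            days, g.starting_level, g.rate_vindep, g.rate_vdep,
            config.breakpoint_day, config.decline, config.floor,
        )
        for gene, mean in (("FLC", flc_mean), ("VIN3", vin3_mean)):
            noise = np.exp(
                rng.normal(0.0, config.noise_sd_log, size=(n_rep, len(days)))
            )
            vals = mean[None, :] * noise * block_eff[blocks, :]
            for r in range(n_rep):
                for j, d in enumerate(days):
                    rows.append(
                        (g.genotype_id, config.site, config.year, int(d),
                         int(blocks[r]) + 1, r + 1, gene, vals[r, j])
                    )
    expr = pd.DataFrame(
        rows,
        columns=["genotype", "site", "year", "day", "block", "replicate",
                 "gene", "value_au"],
    )
    return expr, truth_table(config)


def truth_table(config: SimulationConfig) -> pd.DataFrame:
    """One row per genotype with the true parameters, plus the breakpoint."""
    rows = [asdict(g) for g in config.genotypes]
    truth = pd.DataFrame(rows).rename(columns={"genotype_id": "genotype"})
    truth["breakpoint_day"] = config.breakpoint_day
    truth["site"] = config.site
    truth["year"] = config.year
    return truth


def simulate_transfers(
    config: SimulationConfig, expression: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Simulate the warm-transfer bolting experiment.

    Each plant bolts at m_g * E_g(t_transfer) + c_g + N(0, sd), floored at
    1 day; plants exceeding ``max_followup_days`` are emitted as censored
    did-not-flower (DNF) records with missing ``days_to_bolting``.
    ``expression`` is accepted for interface symmetry; the bolting response
    is driven by the noiseless genotype trajectory at the transfer day.
    """
    config.validate(two_phase=False)
    tp = np.asarray(config.timepoints, dtype=float)
    for d in config.transfer_days:
        if not (tp.min() <= d <= tp.max()):
            raise ValueError(
                f"transfer day {d} outside the sampled range "
                f"[{tp.min():g}, {tp.max():g}]"
            )
    rng = _rng(config.seed + 1)
    rows = []
    for g in config.genotypes:
        for d in config.transfer_days:
            e_at = float(
                mean_trajectory(
                    [d], g.starting_level, g.rate_vindep, g.rate_vdep,
                    config.breakpoint_day, config.decline, config.floor,
                )[0]
            )
            mean_bolt = g.postvern_m * e_at + g.postvern_c
            noise = rng.normal(0.0, config.bolting_noise_sd, config.n_transfer_plants)
            bolt = np.maximum(mean_bolt + noise, 1.0)
            for i, b in enumerate(bolt):
                dnf = b > config.max_followup_days
                rows.append(
                    (g.genotype_id, config.site, config.year, int(d), i + 1,
                     np.nan if dnf else float(b), bool(dnf), e_at)
                )
    return pd.DataFrame(
        rows,
        columns=["genotype", "site", "year", "transfer_day", "plant",
                 "days_to_bolting", "dnf", "flc_at_transfer"],
    )


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def simulate_fitness(
    config: SimulationConfig, expression: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Simulate the overwinter fitness census.

    P(bolted before winter) = invlogit(a - b * E_autumn); survivors carry a
    logit penalty when they bolted precociously; rosette branching declines
    with the genotype post-vern slope; siliques are Poisson in branches for
    survivors and 0 otherwise.
    """
    config.validate(two_phase=False)
    tp = np.asarray(config.timepoints, dtype=float)
    if not (tp.min() <= config.autumn_census_day <= tp.max()):
        raise ValueError(
            f"autumn_census_day={config.autumn_census_day} outside the "
            f"sampled range [{tp.min():g}, {tp.max():g}]"
        )
    rng = _rng(config.seed + 2)
    n = config.n_fitness_plants
    rows = []
    for g in config.genotypes:
        e_autumn = float(
            mean_trajectory(
                [config.autumn_census_day], g.starting_level, g.rate_vindep,
                g.rate_vdep, config.breakpoint_day, config.decline, config.floor,
            )[0]
        )
        p_bolt = _invlogit(config.precocity_intercept
                           - g.precocity_logit_slope * e_autumn)
        bolted = rng.random(n) < p_bolt
        p_surv = _invlogit(config.survival_base_logit
                           - g.survival_penalty_logit * bolted.astype(float))
        survived = rng.random(n) < p_surv
        branches = np.maximum(
            np.rint(
                g.branch_base - g.branch_postvern_slope * g.postvern_m
                + rng.normal(0.0, config.branch_noise_sd, n)
            ),
            0.0,
        )
        lam = np.exp(config.silique_alpha + config.silique_beta * branches)
        siliques = np.where(survived, rng.poisson(lam), 0)
        for i in range(n):
            rows.append(
                (g.genotype_id, config.site, config.year, i + 1,
                 bool(bolted[i]), bool(survived[i]), int(branches[i]),
                 int(siliques[i]), e_autumn, g.postvern_m)
            )
    return pd.DataFrame(
        rows,
        columns=["genotype", "site", "year", "plant", "bolted_before_winter",
                 "survived", "rosette_branches", "siliques", "autumn_flc",
                 "postvern_m"],
    )
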