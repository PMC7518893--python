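"""qPCR quality filters and reference-gene normalization.

The pipeline starts at the quantification-cycle (Cq/Cp) or back-calculated
starting-concentration level.  Quality control applies two rules used for
field samples: (i) a sample whose reference-gene Cq is high (possible
degradation) is excluded only when its target amplicon is also anomalous
(missing, or an order of magnitude away from its peers); (ii) technical
duplicates whose Cq spread exceeds a threshold are excluded unless a
retest is available.  Abundances are normalized to the geometric mean of
the reference genes (PP2A, UBC) and optionally calibrated to a designated
control sample so plates and sites become directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean

__all__ = [
    "QCThresholds",
    "cq_to_concentration",
    "quality_filter",
    "normalize_to_references",
    "calibrate_to_control",
    "normalize_table",
]

DEFAULT_REFERENCE_GENES = ("UBC", "PP2A")


@dataclass(frozen=True)
class QCThresholds:
    reference_cq_max: float = 28.0
    duplicate_cq_spread_max: float = 0.6
    anomaly_fold: float = 10.0

    def __post_init__(self) -> None:
        for name in ("reference_cq_max", "duplicate_cq_spread_max", "anomaly_fold"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


def cq_to_concentration(cq, efficiency: float = 2.0):
    """Convert quantification cycles to relative concentration, eff**(-cq)."""
    if not efficiency > 1.0:
        raise ValueError(f"amplification efficiency must exceed 1, got {efficiency}")
    return np.power(float(efficiency), -np.asarray(cq, dtype=float))


def _sample_conc(df: pd.DataFrame, efficiency: float) -> pd.Series:
    """Per-row abundance: starting_conc when present, else eff**(-cq)."""
    conc = pd.Series(np.nan, index=df.index, dtype=float)
    if "starting_conc" in df:
        conc = df["starting_conc"].astype(float)
    if "cq" in df:
        missing = conc.isna()
        conc[missing] = cq_to_concentration(df.loc[missing, "cq"], efficiency)
    return conc


def quality_filter(
    records: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    reference_amplicons=DEFAULT_REFERENCE_GENES,
    efficiency: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the QC exclusion rules to a long table of qPCR measurements.

    ``records`` has one row per (sample_id, amplicon, technical_rep) with at
    least one of ``cq``/``starting_conc`` and grouping columns
    (genotype, day).  Returns (kept records, exclusion log); the log has
    one row per excluded or flagged record with the rule that fired.
    Filtering is idempotent.
    """
    thresholds = thresholds or QCThresholds()
    if len(records) == 0:
        return records.copy(), pd.DataFrame(
            columns=["sample_id", "amplicon", "rule", "detail"]
        )
    df = records.copy()
    if "qc_flags" not in df:
        df["qc_flags"] = ""
    log_rows: list[tuple] = []
    drop = pd.Series(False, index=df.index)

    # Rule 1: technical-duplicate Cq spread, unless a retest record exists.
    if "cq" in df:
        for (sid, amp), grp in df.groupby(["sample_id", "amplicon"], sort=False):
            cqs = grp["cq"].dropna()
            if len(cqs) < 2:
                continue
            spread = float(cqs.max() - cqs.min())
            if spread > thresholds.duplicate_cq_spread_max:
                has_retest = bool(grp.get("retest", pd.Series(False, index=grp.index))
                                  .fillna(False).astype(bool).any())
                if not has_retest:
                    drop[grp.index] = True
                    log_rows.append(
                        (sid, amp, "duplicate-spread",
                         f"cq spread {spread:.2f} > "
                         f"{thresholds.duplicate_cq_spread_max}")
                    )

    # Rule 2: high reference Cq excludes only if the target is anomalous.
    is_ref = df["amplicon"].isin(reference_amplicons)
    conc = _sample_conc(df, efficiency)
    if "cq" in df:
        bad_ref = df.loc[is_ref & ~drop].groupby("sample_id")["cq"].max()
        flagged_samples = set(bad_ref[bad_ref > thresholds.reference_cq_max].index)
    else:
        flagged_samples = set()

    group_cols = [c for c in ("genotype", "day") if c in df.columns]
    targets = df.loc[~is_ref & ~drop]
    all_target_amps = set(targets["amplicon"])
    for sid in sorted(flagged_samples):
        srows = targets[targets["sample_id"] == sid]
        anomalous_amps: list[str] = []
        measured = set(srows.loc[conc[srows.index].notna(), "amplicon"])
        anomalous_amps += sorted(all_target_amps - measured)  # absent target
        for amp in sorted(measured):
            rows = srows[srows["amplicon"] == amp]
            # peers: same genotype x day, same amplicon, not flagged
            peers = targets[
                (targets["amplicon"] == amp)
                & (~targets["sample_id"].isin(flagged_samples))
            ]
            for c in group_cols:
                peers = peers[peers[c].isin(rows[c].unique())]
            med = float(conc[peers.index].median()) if len(peers) else np.nan
            val = float(conc[rows.index].median())
            if np.isfinite(med) and med > 0:
                if not (med / thresholds.anomaly_fold
                        <= val
                        <= med * thresholds.anomaly_fold):
                    anomalous_amps.append(amp)
        sidx = df.index[df["sample_id"] == sid]
        if anomalous_amps:
            drop[sidx] = True
            log_rows.append(
                (sid, ",".join(anomalous_amps), "high-reference-cq+anomalous",
                 f"reference cq > {thresholds.reference_cq_max} and target "
                 f"anomalous ({','.join(anomalous_amps)})")
            )
        else:
            keep_idx = sidx[~drop[sidx]]
            df.loc[keep_idx, "qc_flags"] = df.loc[keep_idx, "qc_flags"].where(
                df.loc[keep_idx, "qc_flags"].str.contains("high-reference-cq"),
                (df.loc[keep_idx, "qc_flags"] + ";high-reference-cq").str.strip(";"),
            )
            log_rows.append(
                (sid, "", "high-reference-cq",
                 "flag only: target amplicons within range")
            )

    kept = df.loc[~drop].copy()
    log = pd.DataFrame(log_rows, columns=["sample_id", "amplicon", "rule", "detail"])
    return kept, log


def normalize_to_references(target_conc: float, reference_concs) -> float:
    """target / geometric mean of the reference-gene concentrations."""
    refs = np.asarray(list(reference_concs), dtype=float)
    if refs.size == 0:
        raise ValueError("at least one reference concentration is required")
    if not np.isfinite(target_conc) or target_conc <= 0:
        raise ValueError(f"target concentration must be > 0, got {target_conc}")
    bad = np.flatnonzero(~np.isfinite(refs) | (refs <= 0))
    if bad.size:
        raise ValueError(
            f"non-positive reference concentration at position(s) "
            f"{bad.tolist()}: {refs[bad].tolist()}"
        )
    return float(target_conc / gmean(refs))


def calibrate_to_control(values: pd.Series, control_key) -> pd.Series:
    """Divide every value by the control sample's value (control -> 1)."""
    if control_key not in values.index:
        raise ValueError(f"control sample {control_key!r} not found")
    control = float(values.loc[control_key])
    if not np.isfinite(control) or control <= 0:
        raise ValueError(
            f"control sample {control_key!r} has non-positive value {control}"
        )
    return values.astype(float) / control


def normalize_table(
    records: pd.DataFrame,
    target_genes=("FLC", "VIN3"),
    reference_genes=DEFAULT_REFERENCE_GENES,
    efficiency: float = 2.0,
    control_sample=None,
) -> pd.DataFrame:
    """Build the normalized-expression table from filtered qPCR records.

    Averages technical replicates per (sample, amplicon) on the
    concentration scale, divides each target by the geometric mean of the
    reference genes within the sample, and optionally calibrates the whole
    series to ``control_sample``.
    """
    df = records.copy()
    df["_conc"] = _sample_conc(df, efficiency)
    meta_cols = [c for c in ("genotype", "site", "year", "day", "block")
                 if c in df.columns]
    per = (df.groupby(["sample_id", "amplicon"], sort=False)
             .agg(conc=("_conc", "mean"),
                  **{c: (c, "first") for c in meta_cols})
             .reset_index())
    wide = per.pivot_table(index="sample_id", columns="amplicon",
                           values="conc", aggfunc="first")
    meta = per.groupby("sample_id")[meta_cols].first() if meta_cols else None

    out_rows = []
    for sid, row in wide.iterrows():
        refs = [row.get(r) for r in reference_genes]
        refs = [r for r in refs if pd.notna(r)]
        if not refs:
            continue
        for gene in target_genes:
            t = row.get(gene)
            if pd.isna(t):
                continue
            out_rows.append((sid, gene, normalize_to_references(float(t), refs)))
    out = pd.DataFrame(out_rows, columns=["sample_id", "gene", "value_au"])
    if meta is not None:
        out = out.join(meta, on="sample_id")
    if control_sample is not None:
        for gene, grp in out.groupby("gene"):
            series = grp.set_index("sample_id")["value_au"]
            if control_sample in series.index:
                out.loc[grp.index, "value_au"] = calibrate_to_control(
                    series, control_sample
                ).to_numpy()
    return out
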