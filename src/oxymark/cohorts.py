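"""Cohort calling: methylation, hydroxymethylation and CC-motif cohorts.

Thresholds are encoded literally as stated: the methylation cohort takes
contigs with *over* 100 excess 46 h methylcytosine reads (strict >); the
hydroxymethylation cohort requires at least 40 excess reads *and* an
hmC-to-IgG signal ratio of at least 1.5; the CC-motif cohort takes contigs
with 3 or more significant motif hits. A contig whose IgG signal is
non-positive passes the ratio test by definition (IgG depletion cannot mask
hmC enrichment).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "build_methylation_cohort",
    "build_hmc_cohort",
    "build_cc_cohort",
    "cohort_overlap",
    "natural_break_threshold",
    "cohort_table",
]

VENN_REGIONS = (
    "mc_only",
    "hmc_only",
    "cc_only",
    "mc_hmc",
    "mc_cc",
    "hmc_cc",
    "mc_hmc_cc",
)


def _require(table: pd.DataFrame, columns: list[str]) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise InputError(f"signal table missing columns: {missing}")


def build_methylation_cohort(signal_table: pd.DataFrame, min_excess: float = 100) -> set[str]:
    """Contigs with strictly more than ``min_excess`` excess mC reads."""
    _require(signal_table, ["excess_mc"])
    mask = signal_table["excess_mc"] > min_excess
    return set(signal_table.index[mask])


def hmc_to_igg_ratio(signal_table: pd.DataFrame) -> pd.Series:
    """hmC-to-IgG signal ratio; +inf where the IgG signal is non-positive."""
    _require(signal_table, ["signal_hmc", "signal_igg"])
    igg = signal_table["signal_igg"].to_numpy(float)
    hmc = signal_table["signal_hmc"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(igg > 0, hmc / np.where(igg > 0, igg, 1.0), np.inf)
    return pd.Series(ratio, index=signal_table.index, name="hmc_to_igg_ratio")


def build_hmc_cohort(
    signal_table: pd.DataFrame, min_excess: float = 40, min_ratio: float = 1.5
) -> set[str]:
    """Contigs with >= ``min_excess`` excess hmC reads and ratio >= ``min_ratio``."""
    _require(signal_table, ["excess_hmc", "signal_hmc", "signal_igg"])
    ratio = hmc_to_igg_ratio(signal_table)
    mask = (signal_table["excess_hmc"] >= min_excess) & (ratio >= min_ratio)
    return set(signal_table.index[mask])


def build_cc_cohort(motif_hits: pd.Series | dict, min_motifs: int = 3) -> set[str]:
    """Contigs with ``min_motifs`` or more significant motif occurrences."""
    counts = pd.Series(motif_hits, dtype=float)
    return set(counts.index[counts >= min_motifs])


def cohort_overlap(
    mc: set[str], hmc: set[str], cc: set[str]
) -> dict[str, int]:
    """The seven disjoint Venn region counts for the three cohorts."""
    triple = mc & hmc & cc
    return {
        "mc_only": len(mc - hmc - cc),
        "hmc_only": len(hmc - mc - cc),
        "cc_only": len(cc - mc - hmc),
        "mc_hmc": len((mc & hmc) - cc),
        "mc_cc": len((mc & cc) - hmc),
        "hmc_cc": len((hmc & cc) - mc),
        "mc_hmc_cc": len(triple),
    }


def natural_break_threshold(
    excess: pd.Series, min_threshold: float = 10, tail: int = 50
) -> float:
    """Automatic threshold at the largest gap in the sorted upper tail.

    An optional replacement for the fixed excess-read cutoff: the top ``tail``
    values are sorted descending and the threshold is placed inside the
    largest gap between consecutive values above ``min_threshold``. Falls
    back to ``min_threshold`` when no gap exists.
    """
    vals = np.sort(excess.to_numpy(float))[::-1][:tail]
    vals = vals[vals > min_threshold]
    if len(vals) < 2:
        return float(min_threshold)
    gaps = vals[:-1] - vals[1:]
    i = int(np.argmax(gaps))
    if gaps[i] <= 0:
        return float(min_threshold)
    return float((vals[i] + vals[i + 1]) / 2.0)


def cohort_table(
    signal_table: pd.DataFrame,
    motif_counts: pd.Series | dict,
    min_excess_mc: float = 100,
    min_excess_hmc: float = 40,
    min_ratio: float = 1.5,
    min_motifs: int = 3,
) -> pd.DataFrame:
    """Supporting-values table from which every membership is recomputable."""
    motif_counts = pd.Series(motif_counts, dtype=float).reindex(signal_table.index).fillna(0)
    mc = build_methylation_cohort(signal_table, min_excess_mc)
    hmc = build_hmc_cohort(signal_table, min_excess_hmc, min_ratio)
    cc = build_cc_cohort(motif_counts, min_motifs)
    out = signal_table[["excess_mc", "excess_hmc", "signal_mc", "signal_hmc", "signal_igg"]].copy()
    out["hmc_to_igg_ratio"] = hmc_to_igg_ratio(signal_table)
    out["n_motifs"] = motif_counts.astype(int)
    out["in_mc_cohort"] = out.index.isin(sorted(mc))
    out["in_hmc_cohort"] = out.index.isin(sorted(hmc))
    out["in_cc_cohort"] = out.index.isin(sorted(cc))
    return out
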