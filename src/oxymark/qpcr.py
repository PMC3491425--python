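"""ddCt qPCR quantification and Welch one-tailed significance testing.

The 2^-ddCt method quantifies a target relative to a loading-control gene
(mitochondrial rDNA by default) and a reference sample; bisulfite-qPCR
methylation signal normalizes each bisulfite-treated Ct to the same template
in native form, so the retained fraction L = 2^-(Ct_bis - Ct_native)
measures bisulfite resistance (methylation). Significance uses Student's
one-tailed t-test for unequal variance (Welch) on replicate-level delta-Ct
values; stars mark p < 0.05 / 0.01 / 0.005. Undetermined Cts (no
amplification by cycle 45) are imputed at 45.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, InsufficientReplicationError, PairingError

__all__ = [
    "DdctResult",
    "ddct_fold",
    "bisulfite_methylation_signal",
    "welch_t_one_tailed",
    "fold_change_table",
    "stars",
    "read_qpcr_tsv",
    "MAX_CYCLES",
]

MAX_CYCLES = 45.0
STAR_THRESHOLDS = ((0.005, "***"), (0.01, "**"), (0.05, "*"))


def stars(p_value: float | None) -> str:
    if p_value is None or not np.isfinite(p_value):
        return ""
    for cut, mark in STAR_THRESHOLDS:
        if p_value < cut:
            return mark
    return ""


@dataclass
class DdctResult:
    ddct: float  # cycles
    fold_change: float  # 2^-ddct
    se: float  # cycles, propagated across the four arms
    p_value: float | None = None
    stars: str = ""


def _check_arm(name: str, cts) -> np.ndarray:
    arr = np.asarray(cts, dtype=float)
    if arr.size < 2:
        raise InsufficientReplicationError(
            f"{name}: need >= 2 replicates, got {arr.size}"
        )
    return arr


def welch_t_one_tailed(
    group_a, group_b, direction: str = "greater"
) -> tuple[float, float, float]:
    """Welch's unequal-variance t statistic with a one-tailed p-value.

    ``direction='greater'`` tests group_a > group_b (``'less'`` the
    opposite). With zero variance in both groups and equal means the test is
    undefined; p = 0.5 is returned with a warning.
    """
    a = _check_arm("group_a", group_a)
    b = _check_arm("group_b", group_b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            warnings.warn("zero variance in both groups with equal means; p = 0.5")
            return 0.0, float(na + nb - 2), 0.5
        t = math.inf if a.mean() > b.mean() else -math.inf
        df = float(na + nb - 2)
    else:
        se2 = va / na + vb / nb
        t = (a.mean() - b.mean()) / math.sqrt(se2)
        df = se2**2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    if direction == "greater":
        p = float(stats.t.sf(t, df))
    elif direction == "less":
        p = float(stats.t.cdf(t, df))
    else:
        raise InputError(f"unknown direction {direction!r}")
    return float(t), float(df), p


def ddct_fold(
    ct_target_sample,
    ct_norm_sample,
    ct_target_ref,
    ct_norm_ref,
    direction: str = "greater",
) -> DdctResult:
    """2^-ddCt relative quantification of a target across two samples.

    ddCt = (mean Ct_target,sample - mean Ct_norm,sample)
         - (mean Ct_target,ref - mean Ct_norm,ref); fold = 2^-ddCt.
    The standard error propagates the four per-arm SEMs in quadrature. The
    p-value is a Welch one-tailed test on replicate-level delta-Ct values
    (reference vs sample for ``direction='greater'``, i.e. testing fold > 1).
    """
    ts = _check_arm("ct_target_sample", ct_target_sample)
    ns = _check_arm("ct_norm_sample", ct_norm_sample)
    tr = _check_arm("ct_target_ref", ct_target_ref)
    nr = _check_arm("ct_norm_ref", ct_norm_ref)
    ddct = (ts.mean() - ns.mean()) - (tr.mean() - nr.mean())
    se = math.sqrt(
        sum(arr.var(ddof=1) / len(arr) for arr in (ts, ns, tr, nr))
    )
    dct_sample = _paired_dct(ts, ns)
    dct_ref = _paired_dct(tr, nr)
    if direction == "greater":
        _, _, p = welch_t_one_tailed(dct_ref, dct_sample, "greater")
    else:
        _, _, p = welch_t_one_tailed(dct_sample, dct_ref, "greater")
    return DdctResult(
        ddct=float(ddct),
        fold_change=float(2.0**-ddct),
        se=float(se),
        p_value=p,
        stars=stars(p),
    )


def _paired_dct(target: np.ndarray, norm: np.ndarray) -> np.ndarray:
    """Replicate-level delta-Ct; pairs by replicate index when sizes match."""
    if len(target) == len(norm):
        return target - norm
    return target - norm.mean()


def bisulfite_methylation_signal(
    ct_bisulfite_by_sample: dict[str, list[float]],
    ct_native_by_sample: dict[str, list[float]],
    control_sample: str,
) -> pd.DataFrame:
    """Per-sample bisulfite-retained signal and fold over the control.

    For each sample L = 2^-(mean Ct_bisulfite - mean Ct_native): the fraction
    of qPCR signal surviving bisulfite treatment (1 for a fully methylated
    template). The methylation fold is L_sample / L_control, with a Welch
    one-tailed p-value on replicate-level (Ct_bisulfite - Ct_native) values.
    """
    missing = set(ct_bisulfite_by_sample) ^ set(ct_native_by_sample)
    if missing:
        raise PairingError(f"samples without a bisulfite/native pair: {sorted(missing)}")
    if control_sample not in ct_bisulfite_by_sample:
        raise PairingError(f"control sample {control_sample!r} not measured")
    rows = {}
    dct = {}
    for sample in ct_bisulfite_by_sample:
        b = _check_arm(f"{sample} bisulfite", ct_bisulfite_by_sample[sample])
        n = _check_arm(f"{sample} native", ct_native_by_sample[sample])
        dct[sample] = _paired_dct(b, n)
        rows[sample] = 2.0 ** -(b.mean() - n.mean())
    out = []
    for sample, L in rows.items():
        if sample == control_sample:
            p = None
        else:
            _, _, p = welch_t_one_tailed(dct[control_sample], dct[sample], "greater")
        out.append(
            {
                "sample": sample,
                "retained_signal": L,
                "fold_vs_control": L / rows[control_sample],
                "p_value": p,
                "stars": stars(p) if p is not None else "",
            }
        )
    return pd.DataFrame(out).set_index("sample")


def read_qpcr_tsv(path: str) -> pd.DataFrame:
    """Read a long- or wide-format Ct table.

    Wide format: ``target, sample, treatment, template, ct1, ct2, ct3``;
    long format additionally allowed with ``replicate`` and ``ct`` columns.
    Undetermined/NA Cts are imputed at the cycle ceiling (45) and flagged.
    """
    df = pd.read_csv(path, sep="\t")
    ct_cols = [c for c in df.columns if c.startswith("ct") and c != "ct"]
    if ct_cols:
        df = df.melt(
            id_vars=[c for c in df.columns if c not in ct_cols],
            value_vars=ct_cols,
            var_name="replicate",
            value_name="ct",
        )
        df["replicate"] = df["replicate"].str.removeprefix("ct").astype(int)
    if "ct" not in df.columns:
        raise InputError("qPCR table needs ct1..ctN columns or a 'ct' column")
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    df["imputed"] = df["ct"].isna()
    df["ct"] = df["ct"].fillna(MAX_CYCLES)
    return df


def fold_change_table(
    records: pd.DataFrame,
    norm_target: str = "mito_rDNA",
    reference_treatment: str = "untreated",
    direction: str = "greater",
    holm: bool = False,
) -> pd.DataFrame:
    """Per-(target, treatment) ddCt fold changes against the loading control.

    ``records`` is a long-format Ct table (columns target, sample, treatment,
    template, replicate, ct). Each target/template is normalized to the
    *native* loading-control measurement of the same sample and treatment,
    then referenced to ``reference_treatment`` (whose fold is fixed at 1).
    Stars come from a Welch one-tailed test on replicate-level delta-Ct; the
    Holm step-down correction is optional and off by default.
    """
    needed = {"target", "sample", "treatment", "template", "replicate", "ct"}
    missing = needed - set(records.columns)
    if missing:
        raise InputError(f"records missing columns: {sorted(missing)}")

    def norm_cts(treatment: str, sample: str) -> np.ndarray:
        sel = records[
            (records["target"] == norm_target)
            & (records["treatment"] == treatment)
            & (records["sample"] == sample)
            & (records["template"] == "native")
        ].sort_values("replicate")["ct"]
        if sel.empty:
            raise InputError(
                f"normalization target {norm_target!r} not measured in "
                f"sample {sample!r} / treatment {treatment!r}"
            )
        return sel.to_numpy(float)

    rows = []
    groups = records[records["target"] != norm_target]
    for (target, template, treatment), grp in groups.groupby(
        ["target", "template", "treatment"], sort=True
    ):
        for sample, sgrp in grp.groupby("sample"):
            cts = sgrp.sort_values("replicate")["ct"].to_numpy(float)
            dct = _paired_dct(cts, norm_cts(treatment, sample))
            rows.append(
                {
                    "target": target,
                    "template": template,
                    "treatment": treatment,
                    "sample": sample,
                    "dct": dct,
                }
            )
    frame = pd.DataFrame(rows)
    out = []
    for (target, template), grp in frame.groupby(["target", "template"], sort=True):
        ref = grp[grp["treatment"] == reference_treatment]
        if ref.empty:
            raise InputError(
                f"reference treatment {reference_treatment!r} missing for {target!r}"
            )
        dct_ref = np.concatenate(ref["dct"].tolist())
        for _, row in grp.iterrows():
            if row["treatment"] == reference_treatment:
                out.append(
                    {
                        "target": target,
                        "template": template,
                        "treatment": row["treatment"],
                        "ddct": 0.0,
                        "fold_change": 1.0,
                        "se": float(
                            math.sqrt(dct_ref.var(ddof=1) / len(dct_ref))
                        ),
                        "p_value": np.nan,
                        "stars": "",
                    }
                )
                continue
            dct_s = row["dct"]
            ddct = float(dct_s.mean() - dct_ref.mean())
            se = math.sqrt(
                dct_s.var(ddof=1) / len(dct_s) + dct_ref.var(ddof=1) / len(dct_ref)
            )
            if direction == "greater":
                _, _, p = welch_t_one_tailed(dct_ref, dct_s, "greater")
            else:
                _, _, p = welch_t_one_tailed(dct_s, dct_ref, "greater")
            out.append(
                {
                    "target": target,
                    "template": template,
                    "treatment": row["treatment"],
                    "ddct": ddct,
                    "fold_change": float(2.0**-ddct),
                    "se": float(se),
                    "p_value": p,
                    "stars": stars(p),
                }
            )
    result = pd.DataFrame(out)
    if holm and not result.empty:
        tested = result["p_value"].notna()
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(result.loc[tested, "p_value"], method="holm")[1]
        result.loc[tested, "p_value"] = adj
        result.loc[tested, "stars"] = [stars(p) for p in adj]
    return result
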