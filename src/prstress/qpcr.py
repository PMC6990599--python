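"""Comparative-Ct (2^-ddCt) fold changes and qPCR/sequencing concordance."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .cross import CorrelationResult, evans_label, pearson

__all__ = ["read_ct_table", "delta_delta_ct", "platform_concordance"]

CT_COLUMNS = ("gene", "sample", "condition", "ct")


def read_ct_table(path) -> pd.DataFrame:
    """Read a tab-separated Ct table with columns gene, sample, condition, ct."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns {missing}")
    df = df[list(CT_COLUMNS)].copy()
    df["ct"] = pd.to_numeric(df["ct"], errors="raise")
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return df


def delta_delta_ct(
    ct: pd.DataFrame,
    treated_condition: str,
    control_condition: str,
    reference_gene: str | list[str],
) -> pd.DataFrame:
    """Per-gene fold change and log2FC by the comparative Ct method.

    dCt = Ct_gene - Ct_reference per sample (multiple reference genes are
    averaged); ddCt = mean dCt(treated) - mean dCt(control);
    fold = 2^(-ddCt) and log2FC = -ddCt.  The standard error column
    propagates replicate variation of dCt across the two conditions.
    """
    refs = [reference_gene] if isinstance(reference_gene, str) else list(reference_gene)
    ref_rows = ct[ct["gene"].isin(refs)]
    ref_ct = ref_rows.groupby("sample")["ct"].mean()  # geometric-mean equivalent on Ct scale
    missing_ref = set(ct["sample"]) - set(ref_ct.index)
    if missing_ref:
        raise ValueError(f"samples without a reference measurement: {sorted(missing_ref)}")
    for cond in (treated_condition, control_condition):
        if not (ct["condition"] == cond).any():
            raise ValueError(f"condition {cond!r} absent from Ct table")

    work = ct[~ct["gene"].isin(refs)].copy()
    work["dct"] = work["ct"] - work["sample"].map(ref_ct)
    rows = []
    for gene, sub in work.groupby("gene", sort=True):
        trt = sub.loc[sub["condition"] == treated_condition, "dct"]
        ctl = sub.loc[sub["condition"] == control_condition, "dct"]
        if trt.empty or ctl.empty:
            raise ValueError(f"gene {gene!r} lacks replicates in one condition")
        ddct = trt.mean() - ctl.mean()
        se = math.sqrt(
            (trt.var(ddof=1) / len(trt) if len(trt) > 1 else 0.0)
            + (ctl.var(ddof=1) / len(ctl) if len(ctl) > 1 else 0.0)
        )
        rows.append(
            {
                "gene": gene,
                "ddct": ddct,
                "fold_change": 2.0 ** (-ddct),
                "log2fc": -ddct,
                "se_log2fc": se,
                "n_treated": len(trt),
                "n_control": len(ctl),
            }
        )
    return pd.DataFrame(rows)


def platform_concordance(qpcr_log2fc, seq_log2fc) -> CorrelationResult:
    """Pearson correlation of paired qPCR vs sequencing log2FCs (no outlier removal)."""
    x = np.asarray(qpcr_log2fc, dtype=float)
    y = np.asarray(seq_log2fc, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors differ in length")
    if x.size < 3:
        raise ValueError("need >= 3 paired measurements")
    r, p = pearson(x, y)
    return CorrelationResult(
        r=r, p=p, n_used=int(x.size), outliers=[], strength=evans_label(r),
        n_shared=int(x.size),
    )
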