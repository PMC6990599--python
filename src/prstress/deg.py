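"""Minimal negative-binomial differential-expression caller for time courses.

Per-gene counts at each post-reference time point are contrasted against
time 0 with a Wald test on the log2 fold change.  Dispersion is estimated
by method of moments and shrunk toward a fitted mean-dispersion trend.
This is a documented stand-in: downstream stages consume only the
(log2FC, FDR) table, which may equally be supplied externally.

Status thresholds: up <=> log2FC > 1 and FDR <= 0.05; down <=> log2FC < -1
and FDR <= 0.05; otherwise ns.  |log2FC| is compared strictly, FDR
inclusively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix

__all__ = [
    "LOG2FC_THRESHOLD",
    "FDR_THRESHOLD",
    "LOW_COUNT_MEAN",
    "filter_low_counts",
    "normalize",
    "test_contrast",
    "bh_adjust",
    "call_deg_status",
    "fpkm_log2fc",
    "call_degs",
    "ContrastResult",
]

LOG2FC_THRESHOLD = 1.0
FDR_THRESHOLD = 0.05
LOW_COUNT_MEAN = 20.0

_DISPERSION_FLOOR = 1e-8
_TREND_SHRINKAGE = 0.5  # weight on the fitted mean-dispersion trend


@dataclass(frozen=True)
class ContrastResult:
    gene_id: str
    timepoint: float
    log2fc: float
    p: float
    fdr: float


def filter_low_counts(
    cm: CountMatrix, min_mean: float = LOW_COUNT_MEAN
) -> tuple[CountMatrix, list[str]]:
    """Drop genes whose mean raw count over the whole time course is <= ``min_mean``.

    The threshold is inclusive: a gene averaging exactly 20 reads is removed.
    Returns the filtered matrix and the list of removed gene ids.
    """
    if cm.n_genes == 0:
        raise ValueError("empty count matrix")
    means = cm.counts.mean(axis=1)
    keep = means > min_mean
    removed = list(cm.counts.index[~keep])
    return CountMatrix(cm.counts.loc[keep], cm.sample_meta), removed


def normalize(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (one per sample/column).

    The reference is the per-gene geometric mean over genes positive in
    every sample; each sample's factor is the median ratio to it.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[1] == 1:
        return np.ones(1)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with nonzero counts in every sample")
    logs = np.log(arr[positive])
    ref = logs.mean(axis=1)
    return np.exp(np.median(logs - ref[:, None], axis=0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    np.clip(adjusted, 0.0, 1.0, out=adjusted)
    out = np.empty(n)
    out[order] = adjusted
    return out


def call_deg_status(log2fc: float, fdr: float) -> str:
    """Classify one (log2FC, FDR) pair as ``up``, ``down`` or ``ns``."""
    if not (math.isfinite(log2fc) and math.isfinite(fdr)):
        raise ValueError("log2fc and fdr must be finite")
    if fdr <= FDR_THRESHOLD:
        if log2fc > LOG2FC_THRESHOLD:
            return "up"
        if log2fc < -LOG2FC_THRESHOLD:
            return "down"
    return "ns"


def fpkm_log2fc(fpkm_treated: float, fpkm_mock: float, pseudocount: float = 0.0) -> float:
    """log2((treated + pseudocount) / (mock + pseudocount)) for FPKM pairs."""
    if fpkm_treated < 0 or fpkm_mock < 0:
        raise ValueError("FPKM values must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    t = fpkm_treated + pseudocount
    m = fpkm_mock + pseudocount
    if m == 0:
        raise ValueError("mock FPKM is zero and pseudocount is zero")
    if t == 0:
        return float("-inf")
    return math.log2(t / m)


# ---------------------------------------------------------------------------
# NB Wald contrast
# ---------------------------------------------------------------------------


def _trend_dispersion(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Fit alpha ~ a0 + a1/mu by least squares and evaluate at mu.

    Degenerate fits (too few genes, non-positive trend) fall back to the
    mean dispersion.
    """
    valid = (mu > 0) & np.isfinite(alpha)
    fallback = float(np.mean(alpha[valid])) if valid.any() else 0.0
    fallback = max(fallback, _DISPERSION_FLOOR)
    if valid.sum() < 10:
        return np.full_like(alpha, fallback)
    x = np.column_stack([np.ones(valid.sum()), 1.0 / mu[valid]])
    coef, *_ = np.linalg.lstsq(x, alpha[valid], rcond=None)
    trend = coef[0] + coef[1] / np.maximum(mu, 1e-12)
    trend = np.where(np.isfinite(trend) & (trend > 0), trend, fallback)
    return trend


def test_contrast(
    cm: CountMatrix,
    timepoint,
    reference_timepoint=0,
    size_factors: np.ndarray | None = None,
) -> list[ContrastResult]:
    """NB Wald contrast of ``timepoint`` vs the reference time point.

    Counts are normalized by median-of-ratios size factors computed over
    the full matrix (unless provided).  Per-gene dispersion is a moments
    estimate pooled over the two groups, shrunk halfway toward a fitted
    1/mu trend, floored at 1e-8.  BH adjustment is applied across all
    genes of the contrast.
    """
    ref_samples = cm.samples_at(reference_timepoint)
    trt_samples = cm.samples_at(timepoint)
    if len(ref_samples) < 2 or len(trt_samples) < 2:
        raise ValueError(
            f"need >= 2 replicates at both time {reference_timepoint} and "
            f"time {timepoint}"
        )
    if size_factors is None:
        size_factors = normalize(cm.counts)
    sf = pd.Series(np.asarray(size_factors, dtype=float), index=cm.counts.columns)
    norm = cm.counts / sf

    a = norm[ref_samples].to_numpy(dtype=float)
    b = norm[trt_samples].to_numpy(dtype=float)
    n0, n1 = a.shape[1], b.shape[1]

    mu0 = a.mean(axis=1)
    mu1 = b.mean(axis=1)
    # moments dispersion pooled over the two groups: alpha = (s2 - mu) / mu^2
    var0 = a.var(axis=1, ddof=1)
    var1 = b.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a0 = (var0 - mu0) / np.square(mu0)
        a1 = (var1 - mu1) / np.square(mu1)
    alpha_raw = np.nanmean(np.column_stack([a0, a1]), axis=1)
    alpha_raw = np.where(np.isfinite(alpha_raw), alpha_raw, 0.0)
    alpha_raw = np.maximum(alpha_raw, _DISPERSION_FLOOR)
    mu_pool = (n0 * mu0 + n1 * mu1) / (n0 + n1)
    trend = _trend_dispersion(mu_pool, alpha_raw)
    alpha = np.maximum(
        (1 - _TREND_SHRINKAGE) * alpha_raw + _TREND_SHRINKAGE * trend,
        _DISPERSION_FLOOR,
    )

    pseud = 0.5
    log2fc = np.log2((mu1 + pseud) / (mu0 + pseud))
    # delta method on log means: Var(log mu_hat) ~ (1/mu + alpha) / n
    with np.errstate(divide="ignore"):
        v0 = (1.0 / np.maximum(mu0, 1e-12) + alpha) / n0
        v1 = (1.0 / np.maximum(mu1, 1e-12) + alpha) / n1
    se = np.sqrt(v0 + v1) / math.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    # small-sample calibration: the shrunk moments variance behaves like a
    # t statistic with the raw df inflated by the squared shrinkage factor
    df_eff = (n0 + n1 - 2) / (1 - _TREND_SHRINKAGE) ** 2
    p = 2.0 * stats.t.sf(np.abs(z), df_eff)
    p = np.clip(p, 0.0, 1.0)
    fdr = bh_adjust(p)

    genes = list(cm.counts.index)
    return [
        ContrastResult(g, timepoint, float(l), float(pp), float(q))
        for g, l, pp, q in zip(genes, log2fc, p, fdr)
    ]


def call_degs(
    cm: CountMatrix,
    condition: str | None = None,
    min_mean: float = LOW_COUNT_MEAN,
    pooled_fdr: bool = False,
) -> pd.DataFrame:
    """Full caller for one condition's time course: filter, contrast, threshold.

    Returns a DEG table (gene, condition, timepoint, log2fc, fdr, status)
    with one row per retained gene and post-reference time point.  BH is
    applied per time point by default; ``pooled_fdr=True`` adjusts across
    the whole time course instead.
    """
    if condition is not None:
        cm = cm.subset_condition(condition)
    else:
        conds = cm.sample_meta["condition"].unique()
        if len(conds) != 1:
            raise ValueError(
                "count matrix spans several conditions; pass `condition`"
            )
        condition = conds[0]
    filtered, _removed = filter_low_counts(cm, min_mean=min_mean)
    sf = normalize(filtered.counts)
    timepoints = [t for t in filtered.timepoints if t != 0]
    rows: list[dict] = []
    for t in timepoints:
        for res in test_contrast(filtered, t, size_factors=sf):
            rows.append(
                {
                    "gene": res.gene_id,
                    "condition": condition,
                    "timepoint": t,
                    "log2fc": res.log2fc,
                    "p": res.p,
                    "fdr": res.fdr,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["gene", "condition", "timepoint", "log2fc", "fdr", "status"]
        )
    if pooled_fdr:
        df["fdr"] = bh_adjust(df["p"].to_numpy())
    df["status"] = [call_deg_status(l, f) for l, f in zip(df["log2fc"], df["fdr"])]
    return df[["gene", "condition", "timepoint", "log2fc", "p", "fdr", "status"]]
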