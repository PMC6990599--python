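"""Cross-stress consolidation, robust correlation, and family attribution.

A stress profile maps each gene to its mean log2FC over the time points at
which it qualified as a DEG.  Pairs of profiles are correlated over shared
genes after a single pass of boxplot-rule outlier removal (k = 2.0,
flagged per axis, removed as the union); pairs sharing fewer than ten
genes are skipped, never correlated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneCatalog

__all__ = [
    "StressProfile",
    "CorrelationResult",
    "consolidate_profile",
    "boxplot_outliers",
    "correlate_stresses",
    "evans_label",
    "family_attribution",
    "pearson",
    "round_half_away",
    "MIN_SHARED_DEGS",
    "OUTLIER_K",
]

MIN_SHARED_DEGS = 10
OUTLIER_K = 2.0

#: Evans strength bands over |R|: label applies to closed-open intervals
#: except the last, which is closed.
_EVANS_BANDS = (
    (0.20, "very weak"),
    (0.40, "weak"),
    (0.60, "moderate"),
    (0.80, "strong"),
    (1.0 + 1e-12, "very strong"),
)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (printed-table style)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass
class StressProfile:
    """Per-stress consolidated profile: gene -> mean log2FC over DEG time points."""

    stress: str
    values: pd.Series  # index gene, float mean log2FC

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if not self.values.index.is_unique:
            raise ValueError("duplicate genes in stress profile")

    @property
    def genes(self) -> set[str]:
        return set(self.values.index)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CorrelationResult:
    r: float | None
    p: float | None
    n_used: int
    outliers: list[str] = field(default_factory=list)
    strength: str | None = None
    n_shared: int | None = None
    skipped: bool = False
    skip_reason: str | None = None


def consolidate_profile(degs: pd.DataFrame, stress: str | None = None) -> StressProfile:
    """Mean log2FC per gene over its DEG-qualifying time points only.

    Genes never reaching DEG status at any time point are absent from the
    profile.
    """
    if stress is None:
        conds = degs["condition"].unique() if "condition" in degs.columns else ["?"]
        stress = str(conds[0]) if len(conds) == 1 else "combined"
    hits = degs[degs["status"].isin(("up", "down"))]
    values = hits.groupby("gene")["log2fc"].mean()
    return StressProfile(stress=stress, values=values)


def boxplot_outliers(values, k: float = OUTLIER_K) -> list[int]:
    """Indices of values outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation (numpy default, type 7).  Requires
    at least four values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if arr.size < 4:
        raise ValueError("boxplot rule needs at least 4 values")
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return [int(i) for i in np.nonzero((arr < lo) | (arr > hi))[0]]


def pearson(x, y) -> tuple[float, float]:
    """Pearson R and two-sided p via the t transform; errors on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def evans_label(r: float) -> str:
    """Qualitative strength of a correlation coefficient by |R| band."""
    if not math.isfinite(r) or abs(r) > 1:
        raise ValueError("R must lie in [-1, 1]")
    a = abs(r)
    for upper, label in _EVANS_BANDS:
        if a < upper:
            return label
    return "very strong"  # pragma: no cover


def correlate_stresses(
    a: StressProfile,
    b: StressProfile,
    min_shared: int = MIN_SHARED_DEGS,
    k: float = OUTLIER_K,
) -> CorrelationResult:
    """Correlate two consolidated profiles over their shared genes.

    Outliers are flagged on each axis separately with the boxplot rule and
    the union is removed exactly once (no iteration).  A pair sharing
    fewer than ``min_shared`` genes is reported as skipped, not an error.
    """
    shared = sorted(a.genes & b.genes)
    n_shared = len(shared)
    if n_shared < min_shared:
        return CorrelationResult(
            r=None,
            p=None,
            n_used=0,
            n_shared=n_shared,
            skipped=True,
            skip_reason=f"fewer than {min_shared} shared DEGs (found {n_shared})",
        )
    xa = a.values.loc[shared].to_numpy()
    xb = b.values.loc[shared].to_numpy()
    flagged = set(boxplot_outliers(xa, k=k)) | set(boxplot_outliers(xb, k=k))
    keep = [i for i in range(n_shared) if i not in flagged]
    outlier_genes = [shared[i] for i in sorted(flagged)]
    r, p = pearson(xa[keep], xb[keep])
    return CorrelationResult(
        r=r,
        p=p,
        n_used=len(keep),
        outliers=outlier_genes,
        strength=evans_label(r),
        n_shared=n_shared,
        skipped=False,
    )


def family_attribution(
    profiles: dict[str, StressProfile] | list[StressProfile],
    catalog: GeneCatalog,
) -> pd.DataFrame:
    """Per-stress family percentages plus per-family any-stress responsiveness.

    Returns a families x stresses table of integer percentages (each stress
    column sums to ~100 up to rounding), an ``any_stress_pct`` column
    (percent of the family's genes responding to >= 1 stress), and a
    ``n_degs`` bottom row with the per-stress DEG totals.
    """
    if isinstance(profiles, list):
        profiles = {p.stress: p for p in profiles}
    families = catalog.families()
    fam_size = {f: 0 for f in families}
    for rec in catalog:
        if rec.family is not None:
            fam_size[rec.family] += 1

    def fam_of(gene: str) -> str:
        rec = catalog.get(gene)
        if rec is None:
            raise KeyError(f"gene {gene!r} absent from catalog")
        return rec.family or "unassigned"

    table = pd.DataFrame(0.0, index=families, columns=list(profiles))
    totals = {}
    responsive: dict[str, set[str]] = {f: set() for f in families}
    for stress, prof in profiles.items():
        counts: dict[str, int] = {f: 0 for f in families}
        for gene in prof.values.index:
            f = fam_of(gene)
            counts[f] = counts.get(f, 0) + 1
            if f in responsive:
                responsive[f].add(gene)
        total = len(prof)
        totals[stress] = total
        for f in families:
            pct = 100.0 * counts[f] / total if total else 0.0
            table.loc[f, stress] = round_half_away(pct)
    table = table.astype(int)
    any_pct = [
        round_half_away(100.0 * len(responsive[f]) / fam_size[f]) if fam_size[f] else 0
        for f in families
    ]
    table["any_stress_pct"] = any_pct
    bottom = {s: totals[s] for s in profiles}
    bottom["any_stress_pct"] = 0
    table.loc["n_degs"] = pd.Series(bottom)
    return table
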