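"""Temporal, trend-cluster and hormone expression-program classification.

Temporal programs over a four-point post-infestation grid: early = DEG at
1 and/or 7 dpi only, late = 14 and/or 22 dpi only, sustained = both
windows, none = never a DEG.

Trend clusters encode the per-genotype trend signs of a gene across four
genotypes into ids 1-16: id 1 is all-positive, id 9 all-negative, and
cluster k+8 is the sign-flip of cluster k.  Within the first-genotype-up
half (ids 1-8) patterns are ordered by the binary code of the remaining
genotypes' *down* flags; the other half mirrors with *up* flags.

Hormone programs partition genes into sa_only / ja_only / co_regulated /
reciprocal / none from their DEG statuses under the two hormone time
courses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cross import CorrelationResult, evans_label, pearson, round_half_away
from .io import GeneCatalog

__all__ = [
    "EARLY_TIMEPOINTS",
    "LATE_TIMEPOINTS",
    "temporal_program",
    "assign_temporal_programs",
    "genotype_trend",
    "trend_cluster",
    "assign_trend_clusters",
    "hormone_program",
    "assign_hormone_programs",
    "coreg_correlation",
    "program_summary",
    "percent",
]

EARLY_TIMEPOINTS = (1, 7)
LATE_TIMEPOINTS = (14, 22)

HORMONE_PROGRAMS = ("sa_only", "ja_only", "co_regulated", "reciprocal", "none")


def percent(count: int, total: int) -> int:
    """Integer percentage, rounded half away from zero; 0 when total is 0."""
    if total == 0:
        return 0
    return round_half_away(100.0 * count / total)


# ---------------------------------------------------------------------------
# temporal programs
# ---------------------------------------------------------------------------


def temporal_program(
    statuses: Mapping[float, str],
    early: Sequence[float] = EARLY_TIMEPOINTS,
    late: Sequence[float] = LATE_TIMEPOINTS,
) -> str:
    """Classify one gene's per-time-point statuses as early/late/sustained/none."""
    for t in (*early, *late):
        if t not in statuses:
            raise ValueError(f"missing status for time point {t}")
    hit_early = any(statuses[t] in ("up", "down") for t in early)
    hit_late = any(statuses[t] in ("up", "down") for t in late)
    if hit_early and hit_late:
        return "sustained"
    if hit_early:
        return "early"
    if hit_late:
        return "late"
    return "none"


def assign_temporal_programs(
    degs: pd.DataFrame,
    early: Sequence[float] = EARLY_TIMEPOINTS,
    late: Sequence[float] = LATE_TIMEPOINTS,
) -> pd.DataFrame:
    """Per-gene temporal program and direction for one condition's DEG table.

    Direction is the sign of the mean log2FC over the gene's DEG time
    points (0 for genes never a DEG).
    """
    rows = []
    for gene, sub in degs.groupby("gene", sort=True):
        statuses = dict(zip(sub["timepoint"], sub["status"]))
        for t in (*early, *late):
            statuses.setdefault(t, "ns")
        prog = temporal_program(statuses, early=early, late=late)
        hits = sub[sub["status"].isin(("up", "down"))]
        direction = int(np.sign(hits["log2fc"].mean())) if len(hits) else 0
        rows.append({"gene": gene, "temporal_program": prog, "direction": direction})
    return pd.DataFrame(rows, columns=["gene", "temporal_program", "direction"])


# ---------------------------------------------------------------------------
# cross-genotype trend clusters
# ---------------------------------------------------------------------------


def genotype_trend(log2fcs: Sequence[float]) -> int:
    """Trend sign (+1/-1) of one genotype: sign of the mean log2FC.

    A zero mean falls back to the sign at the last time point; an exact
    zero there resolves to -1 by convention.
    """
    arr = np.asarray(list(log2fcs), dtype=float)
    if arr.size == 0:
        raise ValueError("no log2FC values")
    m = arr.mean()
    if m > 0:
        return 1
    if m < 0:
        return -1
    last = arr[-1]
    return 1 if last > 0 else -1


def trend_cluster(signs: Sequence[int]) -> int:
    """Map a 4-genotype sign pattern to its cluster id in 1..16.

    (+,+,+,+) -> 1 and (-,-,-,-) -> 9; cluster k+8 is the global sign
    flip of cluster k.
    """
    signs = tuple(signs)
    if len(signs) != 4 or any(s not in (-1, 1) for s in signs):
        raise ValueError("signs must be four values in {-1, +1}")
    first, rest = signs[0], signs[1:]
    if first > 0:
        offset = sum((1 << (2 - i)) for i, s in enumerate(rest) if s < 0)
        return 1 + offset
    offset = sum((1 << (2 - i)) for i, s in enumerate(rest) if s > 0)
    return 9 + offset


def assign_trend_clusters(
    degs_by_genotype: Mapping[str, pd.DataFrame],
    genotype_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cluster ids for every gene that is a DEG in at least one genotype.

    The trend of each genotype is the sign of the gene's mean log2FC over
    that genotype's whole post-reference time course.
    """
    order = list(genotype_order) if genotype_order else list(degs_by_genotype)
    if len(order) != 4:
        raise ValueError("trend clustering expects exactly four genotypes")
    deg_genes: set[str] = set()
    for g in order:
        df = degs_by_genotype[g]
        deg_genes |= set(df.loc[df["status"].isin(("up", "down")), "gene"])
    rows = []
    for gene in sorted(deg_genes):
        signs = []
        for g in order:
            df = degs_by_genotype[g]
            vals = df.loc[df["gene"] == gene, "log2fc"]
            signs.append(genotype_trend(vals) if len(vals) else -1)
        rows.append(
            {
                "gene": gene,
                "cluster": trend_cluster(signs),
                **{f"trend_{g}": s for g, s in zip(order, signs)},
            }
        )
    cols = ["gene", "cluster"] + [f"trend_{g}" for g in order]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# hormone programs
# ---------------------------------------------------------------------------


def _hormone_direction(statuses: Mapping[float, str], log2fcs: Mapping[float, float]) -> int:
    """Direction under one hormone: sign of the largest-|log2FC| DEG time point."""
    hits = [(abs(log2fcs[t]), log2fcs[t]) for t, s in statuses.items() if s in ("up", "down")]
    if not hits:
        return 0
    return 1 if max(hits)[1] > 0 else -1


def hormone_program(
    sa_statuses: Mapping[float, str],
    ja_statuses: Mapping[float, str],
    sa_log2fcs: Mapping[float, float],
    ja_log2fcs: Mapping[float, float],
) -> tuple[str, int, int]:
    """Classify one gene from its SA and JA time-course statuses.

    Returns (program, sa_direction, ja_direction) where program is one of
    sa_only / ja_only / co_regulated / reciprocal / none.
    """
    sa_dir = _hormone_direction(sa_statuses, sa_log2fcs)
    ja_dir = _hormone_direction(ja_statuses, ja_log2fcs)
    if sa_dir and ja_dir:
        program = "co_regulated" if sa_dir == ja_dir else "reciprocal"
    elif sa_dir:
        program = "sa_only"
    elif ja_dir:
        program = "ja_only"
    else:
        program = "none"
    return program, sa_dir, ja_dir


def assign_hormone_programs(
    sa_degs: pd.DataFrame, ja_degs: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene hormone program over the union of genes in the two tables."""
    genes = sorted(set(sa_degs["gene"]) | set(ja_degs["gene"]))
    rows = []
    for gene in genes:
        sa = sa_degs[sa_degs["gene"] == gene]
        ja = ja_degs[ja_degs["gene"] == gene]
        program, sa_dir, ja_dir = hormone_program(
            dict(zip(sa["timepoint"], sa["status"])),
            dict(zip(ja["timepoint"], ja["status"])),
            dict(zip(sa["timepoint"], sa["log2fc"])),
            dict(zip(ja["timepoint"], ja["log2fc"])),
        )
        rows.append(
            {
                "gene": gene,
                "hormone_program": program,
                "sa_direction": sa_dir,
                "ja_direction": ja_dir,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "hormone_program", "sa_direction", "ja_direction"]
    )


def coreg_correlation(sa_means: pd.Series, ja_means: pd.Series) -> CorrelationResult:
    """Pearson correlation of SA vs JA mean log2FC over co-regulated genes.

    No outlier removal is applied.  Requires >= 3 shared genes.
    """
    shared = sorted(set(sa_means.index) & set(ja_means.index))
    if len(shared) < 3:
        raise ValueError("need >= 3 co-regulated genes")
    r, p = pearson(sa_means.loc[shared], ja_means.loc[shared])
    return CorrelationResult(
        r=r,
        p=p,
        n_used=len(shared),
        outliers=[],
        strength=evans_label(r),
        n_shared=len(shared),
    )


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------


def _direction_sets(degs: pd.DataFrame) -> tuple[set[str], set[str]]:
    up = set(degs.loc[degs["status"] == "up", "gene"])
    down = set(degs.loc[degs["status"] == "down", "gene"])
    return up, down


@dataclass
class ProgramSummary:
    """Aggregated per-family counts plus headline percentages."""

    family_table: pd.DataFrame | None
    hormone_table: pd.DataFrame | None
    cluster_counts: pd.Series | None
    n_classified: int
    conserved_pct: int | None  # clusters 1 + 9 as a fraction of classified genes
    all_up_genes: set | None = None
    all_down_genes: set | None = None

    def hormone_total(self) -> int | None:
        if self.hormone_table is None:
            return None
        return int(self.hormone_table.loc["total", "n_genes"])

    def hormone_pct(self, program: str) -> int | None:
        if self.hormone_table is None:
            return None
        n = int(self.hormone_table.loc[program, "n_genes"])
        return percent(n, self.n_classified)


def program_summary(
    catalog: GeneCatalog | None = None,
    degs_by_genotype: Mapping[str, pd.DataFrame] | None = None,
    trend_clusters: pd.DataFrame | None = None,
    hormone_assignments: pd.DataFrame | None = None,
) -> ProgramSummary:
    """Aggregate classification results into printed-table layouts.

    ``family_table``: per family, up/down DEG counts per genotype plus an
    ALL column (genes DEG in the given direction at >= 1 time point in
    *every* genotype, any time point).  ``hormone_table``: counts per
    hormone program with a total row.  ``cluster_counts``: genes per trend
    cluster; ``conserved_pct`` is the share of classified genes in the two
    fully conserved clusters (1 and 9).
    """
    family_table = None
    all_up = all_down = None
    classified: set[str] = set()

    if degs_by_genotype:
        genotypes = list(degs_by_genotype)
        per_dir = {g: _direction_sets(df) for g, df in degs_by_genotype.items()}
        all_up = set.intersection(*(per_dir[g][0] for g in genotypes))
        all_down = set.intersection(*(per_dir[g][1] for g in genotypes))
        for g in genotypes:
            classified |= per_dir[g][0] | per_dir[g][1]
        if catalog is not None:
            for gene in classified:
                if gene not in catalog:
                    raise KeyError(f"gene {gene!r} absent from catalog")
            families = catalog.families()
            cols: dict[str, list[int]] = {}
            for g in genotypes:
                up, down = per_dir[g]
                cols[f"{g}_up"] = [
                    sum(1 for x in up if catalog.family_of(x) == f) for f in families
                ]
                cols[f"{g}_down"] = [
                    sum(1 for x in down if catalog.family_of(x) == f) for f in families
                ]
            cols["ALL_up"] = [
                sum(1 for x in all_up if catalog.family_of(x) == f) for f in families
            ]
            cols["ALL_down"] = [
                sum(1 for x in all_down if catalog.family_of(x) == f) for f in families
            ]
            family_table = pd.DataFrame(cols, index=families)
            family_table.loc["total"] = family_table.sum()

    cluster_counts = None
    conserved_pct = None
    if trend_clusters is not None and len(trend_clusters):
        cluster_counts = trend_clusters["cluster"].value_counts().sort_index()
        classified |= set(trend_clusters["gene"])
        n = len(trend_clusters)
        conserved = int(cluster_counts.get(1, 0)) + int(cluster_counts.get(9, 0))
        conserved_pct = percent(conserved, n)

    hormone_table = None
    if hormone_assignments is not None:
        counts = hormone_assignments["hormone_program"].value_counts()
        rows = {p: int(counts.get(p, 0)) for p in HORMONE_PROGRAMS if p != "none"}
        hormone_table = pd.DataFrame(
            {"n_genes": rows}
        )
        hormone_table.loc["total"] = hormone_table["n_genes"].sum()
        classified |= set(
            hormone_assignments.loc[
                hormone_assignments["hormone_program"] != "none", "gene"
            ]
        )

    n_classified = (
        len(trend_clusters)
        if trend_clusters is not None and len(trend_clusters)
        else len(classified)
    )
    return ProgramSummary(
        family_table=family_table,
        hormone_table=hormone_table,
        cluster_counts=cluster_counts,
        n_classified=n_classified,
        conserved_pct=conserved_pct,
        all_up_genes=all_up,
        all_down_genes=all_down,
    )
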