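"""Clade nomenclature, species-specific expansion detection and tandem clusters.

Expansions are maximal monophyletic clades whose tips all belong to the
focal species, with at least ``min_size`` tips (default 3).  Physical
clusters are maximal chains of same-family genes on one chromosome where
adjacent members lie within a gap threshold with at most a bounded number
of intervening genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import GeneCatalog, GeneRecord

__all__ = [
    "Expansion",
    "PhysicalCluster",
    "GeneName",
    "detect_expansions",
    "assign_nomenclature",
    "detect_physical_clusters",
    "cluster_summary",
    "MIN_EXPANSION_SIZE",
    "MAX_GAP_BASES",
    "MAX_INTERVENING",
]

MIN_EXPANSION_SIZE = 3
MAX_GAP_BASES = 100_000
MAX_INTERVENING = 5


@dataclass(frozen=True)
class Expansion:
    species: str
    members: tuple[str, ...]
    family: str | None = None
    node_id: int | None = None

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PhysicalCluster:
    family: str
    chromosome: str
    members: tuple[str, ...]  # ordered by start coordinate
    span: int  # bases from first start to last end

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GeneName:
    gene_id: str
    family: str
    clade_letter: str
    like_flag: bool
    index: int

    @property
    def name(self) -> str:
        infix = "L" if self.like_flag else ""
        return f"{self.family}{self.clade_letter}{infix}{self.index}"


# ---------------------------------------------------------------------------
# expansions
# ---------------------------------------------------------------------------


def _leaf_info(node) -> list[tuple[str, str]]:
    """(label, species) for every leaf under ``node``."""
    out = []
    for leaf in node.leaf_iter():
        out.append((leaf.gene_label, leaf.species))
    return out


def detect_expansions(tree, focal_species: str, min_size: int = MIN_EXPANSION_SIZE):
    """Maximal monophyletic clades of >= ``min_size`` focal-species tips.

    A qualifying clade contained in a larger qualifying clade is not
    reported, so each tip belongs to at most one expansion.
    """
    species_present = {leaf.species for leaf in tree.leaf_node_iter()}
    if focal_species not in species_present:
        raise ValueError(f"species {focal_species!r} absent from tree")

    expansions: list[Expansion] = []
    counter = {"id": 0}

    def visit(node) -> bool:
        """Return True when every tip under node is the focal species."""
        if node.is_leaf():
            return node.species == focal_species
        child_pure = [visit(ch) for ch in node.child_nodes()]
        pure = all(child_pure)
        if not pure:
            # children that are pure become maximal candidates here
            for ch, ok in zip(node.child_nodes(), child_pure):
                if ok:
                    leaves = _leaf_info(ch)
                    if len(leaves) >= min_size:
                        counter["id"] += 1
                        expansions.append(
                            Expansion(
                                species=focal_species,
                                members=tuple(lbl for lbl, _ in leaves),
                                node_id=counter["id"],
                            )
                        )
        return pure

    root = tree.seed_node
    if visit(root):
        leaves = _leaf_info(root)
        if len(leaves) >= min_size:
            expansions.append(
                Expansion(
                    species=focal_species,
                    members=tuple(lbl for lbl, _ in leaves),
                    node_id=1,
                )
            )
    return expansions


# ---------------------------------------------------------------------------
# nomenclature
# ---------------------------------------------------------------------------


def _clade_letter(i: int) -> str:
    """0 -> a, 25 -> z, 26 -> aa, 27 -> ab, ..."""
    letters = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        letters = chr(ord("a") + rem) + letters
    return letters


def assign_nomenclature(tree, family: str, deg_history) -> list[GeneName]:
    """Deterministic clade-letter + sequential-index names for a family tree.

    Clades are the root's child subtrees (a leaf child forms a singleton
    clade), lettered a, b, c, ... in order of their smallest descendant
    gene label; genes within a clade are numbered sequentially in the same
    order.  Genes never differentially expressed in any supplied treatment
    (``deg_history[gene]`` falsy or absent) carry the "L" infix.

    The result is a gene <-> name bijection, stable under input-row
    permutation, and idempotent: naming depends only on tree topology,
    labels and the DEG history.
    """
    if callable(deg_history):
        ever_deg = deg_history
    else:
        history = dict(deg_history)
        ever_deg = lambda g: bool(history.get(g, False))

    root = tree.seed_node
    clades = []  # (sort key, ordered member labels)
    for child in root.child_nodes():
        labels = sorted(leaf.gene_label for leaf in child.leaf_iter())
        clades.append((labels[0], labels))
    if not clades:  # single-leaf tree
        labels = sorted(leaf.gene_label for leaf in tree.leaf_node_iter())
        clades = [(labels[0], labels)]
    clades.sort(key=lambda c: c[0])

    names: list[GeneName] = []
    for clade_idx, (_, labels) in enumerate(clades):
        letter = _clade_letter(clade_idx)
        for idx, gene in enumerate(labels, start=1):
            names.append(
                GeneName(
                    gene_id=gene,
                    family=family,
                    clade_letter=letter,
                    like_flag=not ever_deg(gene),
                    index=idx,
                )
            )
    return names


# ---------------------------------------------------------------------------
# physical clusters
# ---------------------------------------------------------------------------


def detect_physical_clusters(
    catalog: GeneCatalog,
    max_gap_bases: int = MAX_GAP_BASES,
    max_intervening: int = MAX_INTERVENING,
    min_members: int = 2,
) -> list[PhysicalCluster]:
    """Maximal same-family chains along each chromosome.

    Genes are sorted by (chromosome, start).  Two consecutive same-family
    genes chain when the gap between them (next start minus previous end,
    floored at 0) is <= ``max_gap_bases`` and at most ``max_intervening``
    catalog genes of any family start between them.  Chains shorter than
    ``min_members`` are dropped; unplaced genes are skipped.
    """
    placed = sorted(
        catalog.placed(), key=lambda r: (r.chromosome, r.start, r.gene_id)
    )
    by_chrom: dict[str, list[GeneRecord]] = {}
    for rec in placed:
        by_chrom.setdefault(rec.chromosome, []).append(rec)

    clusters: list[PhysicalCluster] = []
    for chrom, recs in by_chrom.items():
        families = {r.family for r in recs if r.family is not None}
        for fam in sorted(families, key=str):
            fam_recs = [r for r in recs if r.family == fam]
            chain: list[GeneRecord] = []
            pos_index = {r.gene_id: i for i, r in enumerate(recs)}
            for rec in fam_recs:
                if not chain:
                    chain = [rec]
                    continue
                prev = chain[-1]
                gap = max(0, rec.start - prev.end)
                intervening = pos_index[rec.gene_id] - pos_index[prev.gene_id] - 1
                if gap <= max_gap_bases and intervening <= max_intervening:
                    chain.append(rec)
                else:
                    if len(chain) >= min_members:
                        clusters.append(_make_cluster(fam, chrom, chain))
                    chain = [rec]
            if len(chain) >= min_members:
                clusters.append(_make_cluster(fam, chrom, chain))
    return clusters


def _make_cluster(family, chrom, chain) -> PhysicalCluster:
    return PhysicalCluster(
        family=family,
        chromosome=chrom,
        members=tuple(r.gene_id for r in chain),
        span=chain[-1].end - chain[0].start + 1,
    )


def cluster_summary(
    clusters: list[PhysicalCluster], catalog: GeneCatalog
) -> pd.DataFrame:
    """Per-family clustered counts and percentages, plus an overall row."""
    clustered: dict[str, set[str]] = {}
    for cl in clusters:
        clustered.setdefault(cl.family, set()).update(cl.members)
    families = catalog.families()
    rows = []
    total_genes = 0
    total_clustered = 0
    for fam in families:
        size = sum(1 for r in catalog if r.family == fam)
        n_cl = len(clustered.get(fam, set()))
        total_genes += size
        total_clustered += n_cl
        rows.append(
            {
                "family": fam,
                "n_genes": size,
                "n_clustered": n_cl,
                "pct_clustered": _pct(n_cl, size),
            }
        )
    rows.append(
        {
            "family": "overall",
            "n_genes": total_genes,
            "n_clustered": total_clustered,
            "pct_clustered": _pct(total_clustered, total_genes),
        }
    )
    return pd.DataFrame(rows, columns=["family", "n_genes", "n_clustered", "pct_clustered"])


def _pct(count: int, total: int) -> int:
    from .cross import round_half_away

    return round_half_away(100.0 * count / total) if total else 0
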