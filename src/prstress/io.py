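"""Readers and writers for the tabular, tree and interval formats used by the pipeline.

All genomic coordinates are stored 1-based inclusive (GFF3 convention);
BED input is converted on read.  Count, DEG and metadata tables are
tab-separated.  Trees are Newick with species-prefixed tip labels
(e.g. ``Mes_gene1``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "GeneRecord",
    "GeneCatalog",
    "CountMatrix",
    "read_counts",
    "write_counts",
    "read_deg_table",
    "write_deg_table",
    "read_gene_coords",
    "write_gene_coords",
    "read_tree",
    "write_tree",
    "DEG_COLUMNS",
]

#: canonical DEG-table header; a column mapping may be supplied on read
DEG_COLUMNS = ("gene", "condition", "timepoint", "log2fc", "fdr")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# gene catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRecord:
    """One gene locus: family/clade membership plus optional placement.

    ``chromosome`` is ``None`` for unplaced genes, which then carry no
    coordinates and are skipped by physical clustering.
    """

    gene_id: str
    family: str | None = None
    clade: str | None = None
    chromosome: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str = "?"

    def __post_init__(self) -> None:
        if self.chromosome is None:
            if self.start is not None or self.end is not None:
                raise ValueError(
                    f"unplaced gene {self.gene_id!r} must not carry coordinates"
                )
        else:
            if self.start is None or self.end is None:
                raise ValueError(f"placed gene {self.gene_id!r} lacks coordinates")
            if self.start > self.end:
                raise ValueError(
                    f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
                )
            if self.start < 1:
                raise ValueError(f"gene {self.gene_id!r}: 1-based start must be >= 1")
        if self.strand not in ("+", "-", "?"):
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def placed(self) -> bool:
        return self.chromosome is not None

    @property
    def length(self) -> int | None:
        if not self.placed:
            return None
        return self.end - self.start + 1  # type: ignore[operator]


class GeneCatalog:
    """Ordered collection of :class:`GeneRecord` keyed by unique gene id."""

    def __init__(self, records: Iterable[GeneRecord]):
        self._records: dict[str, GeneRecord] = {}
        for rec in records:
            if rec.gene_id in self._records:
                raise ValueError(f"duplicate gene id {rec.gene_id!r}")
            self._records[rec.gene_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._records

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._records[gene_id]

    def get(self, gene_id: str) -> GeneRecord | None:
        return self._records.get(gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return list(self._records)

    def placed(self) -> list[GeneRecord]:
        return [r for r in self if r.placed]

    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self:
            if rec.family is not None:
                seen.setdefault(rec.family, None)
        return list(seen)

    def family_of(self, gene_id: str) -> str | None:
        return self._records[gene_id].family

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": r.gene_id,
                "family": r.family,
                "clade": r.clade,
                "chromosome": r.chromosome,
                "start": r.start,
                "end": r.end,
                "strand": r.strand,
            }
            for r in self
        ]
        return pd.DataFrame(
            rows,
            columns=["gene", "family", "clade", "chromosome", "start", "end", "strand"],
        )


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix joined to per-sample metadata.

    ``sample_meta`` is indexed by sample id with columns ``condition``,
    ``timepoint`` and ``replicate``; its order matches the count columns.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [s for s in self.counts.columns if s not in self.sample_meta.index]
        if missing:
            raise FormatError(f"samples absent from metadata: {missing}")
        self.counts = self.counts.rename_axis(index="gene", columns=None)
        self.sample_meta = self.sample_meta.rename_axis(index="sample")
        self.sample_meta = self.sample_meta.loc[list(self.counts.columns)]
        if self.sample_meta["timepoint"].isna().any():
            bad = self.sample_meta.index[self.sample_meta["timepoint"].isna()]
            raise FormatError(f"samples without a time point: {list(bad)}")
        if not self.counts.index.is_unique:
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise FormatError(f"duplicate gene ids: {list(dups)}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                i, j = np.argwhere(np.mod(arr, 1) != 0)[0]
                raise FormatError(
                    f"non-integer count at gene {self.counts.index[i]!r}, "
                    f"sample {self.counts.columns[j]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def timepoints(self) -> list:
        return sorted(self.sample_meta["timepoint"].unique().tolist())

    def subset_condition(self, condition: str) -> "CountMatrix":
        keep = self.sample_meta.index[self.sample_meta["condition"] == condition]
        if len(keep) == 0:
            raise KeyError(f"no samples for condition {condition!r}")
        return CountMatrix(self.counts[list(keep)], self.sample_meta.loc[list(keep)])

    def samples_at(self, timepoint) -> list[str]:
        mask = self.sample_meta["timepoint"] == timepoint
        return list(self.sample_meta.index[mask])


def read_counts(path, meta_path) -> CountMatrix:
    """Read a tab-separated counts table plus its sample-metadata table."""
    counts = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    counts.index = counts.index.astype(str)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, comment="#")
    meta.index = meta.index.astype(str)
    for col in ("condition", "timepoint", "replicate"):
        if col not in meta.columns:
            raise FormatError(f"sample metadata lacks column {col!r}")
    for col in counts.columns:
        series = pd.to_numeric(counts[col], errors="coerce")
        if series.isna().any():
            gene = counts.index[series.isna()][0]
            raise FormatError(f"non-numeric count at gene {gene!r}, sample {col!r}")
        counts[col] = series
    return CountMatrix(counts, meta)


def write_counts(cm: CountMatrix, path, meta_path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene")
    cm.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------


def read_deg_table(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a per-gene, per-time-point log2FC/FDR table.

    The ``status`` column is always recomputed from the threshold rule,
    never trusted from the file.  ``column_map`` maps canonical names
    (``gene``, ``condition``, ``timepoint``, ``log2fc``, ``fdr``) to the
    file's actual headers.
    """
    from .deg import call_deg_status

    df = pd.read_csv(path, sep="\t", comment="#")
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in DEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"DEG table lacks columns {missing}")
    df = df[list(DEG_COLUMNS)].copy()
    df["log2fc"] = pd.to_numeric(df["log2fc"], errors="coerce")
    if df["log2fc"].isna().any():
        raise FormatError("non-numeric log2fc value in DEG table")
    df["fdr"] = pd.to_numeric(df["fdr"], errors="coerce")
    if df["fdr"].isna().any() or ((df["fdr"] < 0) | (df["fdr"] > 1)).any():
        raise FormatError("FDR values must be numeric and within [0, 1]")
    dup = df.duplicated(subset=["gene", "condition", "timepoint"])
    if dup.any():
        raise FormatError("duplicate (gene, condition, timepoint) rows in DEG table")
    df["status"] = [
        call_deg_status(l, f) for l, f in zip(df["log2fc"], df["fdr"])
    ]
    return df


def write_deg_table(degs: pd.DataFrame, path) -> None:
    cols = [c for c in (*DEG_COLUMNS, "status") if c in degs.columns]
    degs[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene coordinates (BED / GFF3)
# ---------------------------------------------------------------------------

_GFF_ATTR = re.compile(r"(\w+)=([^;]+)")


def _parse_gff_attrs(text: str) -> dict[str, str]:
    return {m.group(1): m.group(2) for m in _GFF_ATTR.finditer(text)}


def read_gene_coords(
    path,
    dialect: str,
    family_map: Mapping[str, str] | None = None,
    clade_map: Mapping[str, str] | None = None,
) -> GeneCatalog:
    """Read gene loci from BED (0-based half-open) or GFF3 (1-based inclusive).

    BED starts are incremented by one so that all internal coordinates are
    1-based inclusive.  For GFF3, ``family`` and ``clade`` attributes are
    honoured when present; ``family_map``/``clade_map`` override per gene id.
    """
    if dialect not in ("bed", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "bed":
                    if len(fields) < 4:
                        raise ValueError("BED line needs >= 4 fields")
                    chrom, start0, end0, name = fields[:4]
                    strand = fields[5] if len(fields) >= 6 else "?"
                    start = int(start0) + 1
                    end = int(end0)
                    family = clade = None
                else:
                    if len(fields) < 9:
                        raise ValueError("GFF3 line needs 9 fields")
                    chrom = fields[0]
                    if fields[2] != "gene":
                        continue
                    start = int(fields[3])
                    end = int(fields[4])
                    strand = fields[6] if fields[6] in "+-" else "?"
                    attrs = _parse_gff_attrs(fields[8])
                    name = attrs.get("ID") or attrs.get("Name")
                    if not name:
                        raise ValueError("GFF3 gene lacks ID attribute")
                    family = attrs.get("family")
                    clade = attrs.get("clade")
                if start > end:
                    raise ValueError(f"start {start} > end {end} after conversion")
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if family_map is not None:
                family = family_map.get(name, family)
            if clade_map is not None:
                clade = clade_map.get(name, clade)
            records.append(
                GeneRecord(
                    gene_id=name,
                    family=family,
                    clade=clade,
                    chromosome=chrom,
                    start=start,
                    end=end,
                    strand=strand if strand in "+-" else "?",
                )
            )
    return GeneCatalog(records)


def write_gene_coords(catalog: GeneCatalog, path, dialect: str = "gff3") -> None:
    """Write placed genes; unplaced genes have no coordinates to serialize."""
    if dialect not in ("bed", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
        for rec in catalog.placed():
            strand = rec.strand if rec.strand in "+-" else "."
            if dialect == "bed":
                fh.write(
                    f"{rec.chromosome}\t{rec.start - 1}\t{rec.end}\t{rec.gene_id}"
                    f"\t0\t{strand if strand != '.' else '.'}\n"
                )
            else:
                attrs = f"ID={rec.gene_id}"
                if rec.family:
                    attrs += f";family={rec.family}"
                if rec.clade:
                    attrs += f";clade={rec.clade}"
                fh.write(
                    f"{rec.chromosome}\tprstress\tgene\t{rec.start}\t{rec.end}"
                    f"\t.\t{strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

_SPECIES_PREFIX = re.compile(r"^([A-Za-z]+)_(.+)$")


def read_tree(path_or_string, species_map: Mapping[str, str] | None = None):
    """Read a Newick tree and tag every tip with its species.

    The species is the underscore-delimited label prefix (``Mes_x`` ->
    species ``Mes``), optionally translated through ``species_map``.
    Trees whose root has more than two children are treated as unrooted
    and midpoint-rooted deterministically.
    """
    src = str(path_or_string)
    kwargs = {"data": src} if src.lstrip().startswith("(") else {"path": src}
    try:
        tree = dendropy.Tree.get(
            schema="newick", suppress_internal_node_taxa=True, **kwargs
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"unparseable Newick: {exc}") from exc
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label.replace(" ", "_")
        m = _SPECIES_PREFIX.match(label)
        if not m:
            raise FormatError(
                f"tip {label!r} lacks a species prefix of the form 'Xxx_'"
            )
        prefix = m.group(1)
        species = species_map.get(prefix, prefix) if species_map else prefix
        leaf.species = species
        leaf.gene_label = label
    if tree.seed_node and len(tree.seed_node.child_nodes()) > 2:
        tree.reroot_at_midpoint(update_bipartitions=False)
    return tree


def write_tree(tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def tip_labels(tree) -> list[str]:
    return [leaf.taxon.label.replace(" ", "_") for leaf in tree.leaf_node_iter()]


def tip_species(tree) -> dict[str, str]:
    return {
        leaf.taxon.label.replace(" ", "_"): leaf.species
        for leaf in tree.leaf_node_iter()
    }
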