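"""Synthetic data generators with planted ground truth.

Three generators cover the pipeline's inputs: negative-binomial
time-course counts with planted temporal DEG programs, paired
hormone-response counts with a tunable co-regulation fraction and
correlation, and family structure (species-labeled Newick trees with
planted same-species expansions plus chromosome layouts with planted
tandem arrays).

All randomness flows from ``SimulationConfig.seed``; identical configs
produce byte-identical outputs.  Counts are NB with variance
mu + alpha * mu^2; per-sample size factors are drawn log-uniform in
[0.7, 1.4] to exercise normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneCatalog, GeneRecord

__all__ = [
    "SimulationConfig",
    "simulate_timecourse_counts",
    "simulate_hormone_pair",
    "simulate_family_structure",
]

_TEMPORAL_PROGRAMS = (
    "early_up",
    "early_down",
    "late_up",
    "late_down",
    "sustained_up",
    "sustained_down",
)
_HORMONE_PROGRAMS = ("co_regulated", "sa_only", "ja_only", "reciprocal")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for all three generators; unused fields are ignored by each."""

    seed: int = 0
    n_genes: int = 1000
    timepoints: tuple = (0, 1, 7, 14, 22)
    hormone_timepoints: tuple = (0, 0.5, 1, 2, 4, 8, 12, 24)
    n_replicates: int = 3
    dispersion: float = 0.05
    baseline_log_mean: float = math.log(500.0)
    baseline_log_sd: float = 1.0
    effect_size: float = 2.0
    effect_sd: float = 0.0  # jitter on planted |log2FC|
    #: fraction of genes planted per temporal program (rest are null)
    program_fractions: dict = field(
        default_factory=lambda: {
            "early_up": 0.03,
            "early_down": 0.03,
            "late_up": 0.05,
            "late_down": 0.05,
            "sustained_up": 0.02,
            "sustained_down": 0.02,
        }
    )
    early_timepoints: tuple = (1, 7)
    late_timepoints: tuple = (14, 22)
    condition: str = "SIM"
    #: hormone-pair structure
    coreg_fraction: float = 0.2
    coreg_correlation: float = 0.9
    sa_only_fraction: float = 0.05
    ja_only_fraction: float = 0.1
    reciprocal_fraction: float = 0.01
    hormone_effect_sd: float = 0.5
    #: family structure: (family label, size)
    families: tuple = (("PR-A", 30), ("PR-B", 25))
    focal_species: str = "Mes"
    #: planted expansions: tuples of (family label, clade size)
    expansion_spec: tuple = (("PR-A", 3),)
    #: planted tandem arrays: tuples of (family label, chromosome, size)
    cluster_spec: tuple = (("PR-A", "chr1", 4),)
    gene_length: int = 1_000
    intra_cluster_gap: int = 5_000
    inter_cluster_gap: int = 500_000

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if len(self.timepoints) == 0:
            raise ValueError("empty time grid")
        if not -1.0 <= self.coreg_correlation <= 1.0:
            raise ValueError("coreg_correlation must lie in [-1, 1]")
        for name in _TEMPORAL_PROGRAMS:
            if self.program_fractions.get(name, 0.0) < 0:
                raise ValueError(f"negative fraction for {name}")
        if sum(self.program_fractions.get(n, 0.0) for n in _TEMPORAL_PROGRAMS) > 1:
            raise ValueError("temporal program fractions must sum to <= 1")
        hf = (
            self.coreg_fraction
            + self.sa_only_fraction
            + self.ja_only_fraction
            + self.reciprocal_fraction
        )
        if hf > 1:
            raise ValueError("hormone program fractions must sum to <= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, alpha) with variance mu + alpha*mu^2; Poisson when alpha == 0."""
    mean = np.maximum(mean, 1e-12)
    if alpha <= 0:
        return rng.poisson(mean)
    shape = 1.0 / alpha
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p)


def _planted_counts(n_genes: int, fractions: dict, programs) -> list[int]:
    counts = [int(round(fractions.get(p, 0.0) * n_genes)) for p in programs]
    while sum(counts) > n_genes:  # guard against rounding overshoot
        counts[int(np.argmax(counts))] -= 1
    return counts


# ---------------------------------------------------------------------------
# time-course counts
# ---------------------------------------------------------------------------


def simulate_timecourse_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB time-course counts with planted early/late/sustained up/down genes.

    Planted genes shift their mean by 2^(true log2FC) at their program's
    time points; null genes are flat.  Returns the count matrix (with
    sample metadata) and a truth table carrying the planted program,
    direction and per-time-point true log2FC of every gene.
    """
    rng = _rng(config, 1)
    n = config.n_genes
    genes = [f"g{i:05d}" for i in range(1, n + 1)]
    timepoints = tuple(config.timepoints)
    post = [t for t in timepoints if t != 0]

    program_counts = _planted_counts(n, config.program_fractions, _TEMPORAL_PROGRAMS)
    labels = np.array(["none"] * n, dtype=object)
    perm = rng.permutation(n)
    cursor = 0
    for prog, cnt in zip(_TEMPORAL_PROGRAMS, program_counts):
        labels[perm[cursor : cursor + cnt]] = prog
        cursor += cnt

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    magnitudes = np.abs(
        config.effect_size + config.effect_sd * rng.standard_normal(n)
    )

    window = {
        "early": set(config.early_timepoints),
        "late": set(config.late_timepoints),
        "sustained": set(config.early_timepoints) | set(config.late_timepoints),
    }
    true_lfc = pd.DataFrame(0.0, index=genes, columns=post)
    direction = np.zeros(n, dtype=int)
    for i, prog in enumerate(labels):
        if prog == "none":
            continue
        phase, sign_word = prog.rsplit("_", 1)
        sign = 1 if sign_word == "up" else -1
        direction[i] = sign
        for t in post:
            if t in window[phase]:
                true_lfc.iloc[i, true_lfc.columns.get_loc(t)] = sign * magnitudes[i]

    samples, meta_rows = [], []
    for t in timepoints:
        for r in range(1, config.n_replicates + 1):
            samples.append(f"{config.condition}_t{t}_r{r}")
            meta_rows.append(
                {
                    "sample": samples[-1],
                    "condition": config.condition,
                    "timepoint": t,
                    "replicate": r,
                }
            )
    size_factors = np.exp(
        rng.uniform(math.log(0.7), math.log(1.4), size=len(samples))
    )

    counts = np.empty((n, len(samples)), dtype=np.int64)
    for j, (s, row) in enumerate(zip(samples, meta_rows)):
        t = row["timepoint"]
        lfc = true_lfc[t].to_numpy() if t in true_lfc.columns else np.zeros(n)
        mu = baseline * np.exp2(lfc) * size_factors[j]
        counts[:, j] = _nb_draw(rng, mu, config.dispersion)

    cm = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=samples),
        pd.DataFrame(meta_rows).set_index("sample"),
    )
    truth = pd.DataFrame(
        {
            "gene": genes,
            "program": [p.rsplit("_", 1)[0] if p != "none" else "none" for p in labels],
            "direction": direction,
            "baseline_mean": baseline,
        }
    )
    for t in post:
        truth[f"true_log2fc_{t}"] = true_lfc[t].to_numpy()
    return cm, truth


# ---------------------------------------------------------------------------
# paired hormone responses
# ---------------------------------------------------------------------------


def simulate_hormone_pair(
    config: SimulationConfig,
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame]:
    """Paired SA/JA count matrices with a planted co-regulation structure.

    Co-regulated genes draw their (SA, JA) true log2FCs from a bivariate
    normal with the configured correlation around a same-sign effect;
    reciprocal genes carry opposite signs; single-hormone genes respond in
    one condition only.  Effects are sustained over all post-0 points.
    """
    rng = _rng(config, 2)
    n = config.n_genes
    genes = [f"g{i:05d}" for i in range(1, n + 1)]
    fractions = {
        "co_regulated": config.coreg_fraction,
        "sa_only": config.sa_only_fraction,
        "ja_only": config.ja_only_fraction,
        "reciprocal": config.reciprocal_fraction,
    }
    program_counts = _planted_counts(n, fractions, _HORMONE_PROGRAMS)
    labels = np.array(["none"] * n, dtype=object)
    perm = rng.permutation(n)
    cursor = 0
    for prog, cnt in zip(_HORMONE_PROGRAMS, program_counts):
        labels[perm[cursor : cursor + cnt]] = prog
        cursor += cnt

    rho = config.coreg_correlation
    sd = config.hormone_effect_sd
    e = config.effect_size
    sa_lfc = np.zeros(n)
    ja_lfc = np.zeros(n)
    for i, prog in enumerate(labels):
        if prog == "none":
            continue
        sign = 1 if rng.random() < 0.5 else -1
        if prog == "co_regulated":
            z1 = rng.standard_normal()
            z2 = rho * z1 + math.sqrt(max(0.0, 1 - rho * rho)) * rng.standard_normal()
            sa_lfc[i] = sign * abs(e + sd * z1)
            ja_lfc[i] = sign * abs(e + sd * z2)
        elif prog == "sa_only":
            sa_lfc[i] = sign * abs(e + sd * rng.standard_normal())
        elif prog == "ja_only":
            ja_lfc[i] = sign * abs(e + sd * rng.standard_normal())
        else:  # reciprocal
            sa_lfc[i] = sign * abs(e + sd * rng.standard_normal())
            ja_lfc[i] = -sign * abs(e + sd * rng.standard_normal())

    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)

    def build(cond: str, lfc: np.ndarray) -> CountMatrix:
        samples, meta_rows = [], []
        for t in config.hormone_timepoints:
            for r in range(1, config.n_replicates + 1):
                samples.append(f"{cond}_t{t}_r{r}")
                meta_rows.append(
                    {
                        "sample": samples[-1],
                        "condition": cond,
                        "timepoint": t,
                        "replicate": r,
                    }
                )
        sfs = np.exp(rng.uniform(math.log(0.7), math.log(1.4), size=len(samples)))
        counts = np.empty((n, len(samples)), dtype=np.int64)
        for j, row in enumerate(meta_rows):
            active = row["timepoint"] != 0
            mu = baseline * (np.exp2(lfc) if active else 1.0) * sfs[j]
            counts[:, j] = _nb_draw(rng, mu, config.dispersion)
        return CountMatrix(
            pd.DataFrame(counts, index=genes, columns=samples),
            pd.DataFrame(meta_rows).set_index("sample"),
        )

    cm_sa = build("SA", sa_lfc)
    cm_ja = build("JA", ja_lfc)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "hormone_program": labels,
            "sa_true_log2fc": sa_lfc,
            "ja_true_log2fc": ja_lfc,
            "baseline_mean": baseline,
        }
    )
    return cm_sa, cm_ja, truth


# ---------------------------------------------------------------------------
# family structure: tree + chromosome layout
# ---------------------------------------------------------------------------


def _ladder(units: list[str]) -> str:
    """Fold subtree strings into a rooted binary ladder."""
    tree = units[0]
    for unit in units[1:]:
        tree = f"({tree},{unit})"
    return tree


def simulate_family_structure(
    config: SimulationConfig,
) -> tuple[GeneCatalog, str, pd.DataFrame]:
    """Plant expansions in a species-labeled tree and tandem arrays on chromosomes.

    The tree contains exactly the planted monophyletic focal-species
    clades: every non-expansion focal gene is paired with an outgroup tip
    so no unplanned pure clade can form.  The chromosome layout places the
    planted arrays with intra-array gaps below and inter-array gaps above
    the clustering threshold; remaining genes are scattered as singletons.
    """
    rng = _rng(config, 3)
    families = list(config.families)
    for fam, size in config.expansion_spec:
        fam_size = dict(families).get(fam)
        if fam_size is None:
            raise ValueError(f"expansion family {fam!r} not among families")
        if size < 2:
            raise ValueError("expansion clade size must be >= 2")
    sizes = dict(families)
    demand: dict[str, int] = {}
    for fam, size in config.expansion_spec:
        demand[fam] = demand.get(fam, 0) + size
    for fam, _chrom, size in config.cluster_spec:
        if fam not in sizes:
            raise ValueError(f"cluster family {fam!r} not among families")
    for fam, total in demand.items():
        if total > sizes[fam]:
            raise ValueError(f"expansion sizes exceed family {fam!r} size")

    prefix = config.focal_species
    gene_ids: dict[str, list[str]] = {}
    for fi, (fam, size) in enumerate(families, start=1):
        gene_ids[fam] = [f"{prefix}_F{fi}G{g:03d}" for g in range(1, size + 1)]

    # --- tree with planted expansions ---
    truth_expansion: dict[str, int] = {}
    units: list[str] = []
    fill = iter(range(1, 10_000))
    exp_id = 0
    used: dict[str, int] = {fam: 0 for fam in sizes}
    for fam, size in config.expansion_spec:
        exp_id += 1
        members = gene_ids[fam][used[fam] : used[fam] + size]
        used[fam] += size
        for m in members:
            truth_expansion[m] = exp_id
        units.append(_ladder(members))
    for fam, size in families:
        for gene in gene_ids[fam][used[fam] :]:
            units.append(f"({gene},Ptr_fill{next(fill)})")
    order = rng.permutation(len(units))
    units = [units[i] for i in order]
    # anchor the ladder with an outgroup tip so that no ladder prefix of
    # pure focal units can merge planted expansions into a larger clade
    units.insert(0, f"Ptr_anchor{next(fill)}")
    units.append(f"Osa_out{next(fill)}")
    newick = _ladder(units) + ";"

    # --- chromosome layout with planted arrays ---
    truth_cluster: dict[str, int] = {}
    records: list[GeneRecord] = []
    placed: set[str] = set()
    cursor_by_chrom: dict[str, int] = {}
    array_id = 0
    avail: dict[str, list[str]] = {fam: list(gene_ids[fam]) for fam in sizes}
    for fam, chrom, size in config.cluster_spec:
        if size > len(avail[fam]):
            raise ValueError(f"cluster size exceeds remaining {fam!r} genes")
        array_id += 1
        members = [avail[fam].pop(0) for _ in range(size)]
        pos = cursor_by_chrom.get(chrom, 1) + config.inter_cluster_gap
        for gene in members:
            records.append(
                GeneRecord(
                    gene_id=gene,
                    family=fam,
                    chromosome=chrom,
                    start=pos,
                    end=pos + config.gene_length - 1,
                    strand="+",
                )
            )
            truth_cluster[gene] = array_id
            placed.add(gene)
            pos += config.gene_length + config.intra_cluster_gap
        cursor_by_chrom[chrom] = pos + config.inter_cluster_gap
    # scatter the rest far apart, round-robin over a few chromosomes
    scatter_chroms = [f"chr{k}" for k in range(1, 6)]
    for fam in sizes:
        for gene in avail[fam]:
            chrom = scatter_chroms[rng.integers(len(scatter_chroms))]
            pos = cursor_by_chrom.get(chrom, 1) + config.inter_cluster_gap
            records.append(
                GeneRecord(
                    gene_id=gene,
                    family=fam,
                    chromosome=chrom,
                    start=pos,
                    end=pos + config.gene_length - 1,
                    strand="+",
                )
            )
            cursor_by_chrom[chrom] = pos + config.gene_length
            placed.add(gene)
    catalog = GeneCatalog(records)

    rows = []
    for fam, size in families:
        for gene in gene_ids[fam]:
            rows.append(
                {
                    "gene": gene,
                    "family": fam,
                    "expansion_id": truth_expansion.get(gene, 0),
                    "cluster_id": truth_cluster.get(gene, 0),
                }
            )
    truth = pd.DataFrame(rows, columns=["gene", "family", "expansion_id", "cluster_id"])
    return catalog, newick, truth
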