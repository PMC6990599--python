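"""End-to-end orchestration: simulate -> call DEGs -> classify -> structure
-> cross-stress -> qPCR, with a reproducible run manifest.

All randomness flows from the single config seed.  Every output table
carries the manifest hash in a leading ``#`` comment so runs can be tied
back to their configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cross, deg, family, programs, qpcr
from .io import write_gene_coords
from .simulate import SimulationConfig, simulate_family_structure, simulate_hormone_pair, simulate_timecourse_counts

__all__ = ["default_config", "run_pipeline", "PipelineError"]

DEFAULT_GENOTYPES = ("GT1", "GT2", "GT3", "GT4")


class PipelineError(RuntimeError):
    """A stage failed; the message names the failing stage."""


def default_config(seed: int = 0) -> dict:
    """Structured config with every analysis threshold surfaced as a key."""
    return {
        "seed": seed,
        "genotypes": list(DEFAULT_GENOTYPES),
        "thresholds": {
            "log2fc": deg.LOG2FC_THRESHOLD,
            "fdr": deg.FDR_THRESHOLD,
            "low_count_mean": deg.LOW_COUNT_MEAN,
            "min_expansion_size": family.MIN_EXPANSION_SIZE,
            "min_shared_degs": cross.MIN_SHARED_DEGS,
            "outlier_k": cross.OUTLIER_K,
            "max_gap_bases": family.MAX_GAP_BASES,
            "max_intervening": family.MAX_INTERVENING,
        },
        "simulate": {
            "n_genes": 400,
            "dispersion": 0.02,
            "effect_size": 2.5,
            "baseline_log_mean": 6.5,
            "baseline_log_sd": 0.5,
        },
    }


def _manifest_hash(payload: dict) -> str:
    canon = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, manifest_hash: str, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# manifest: {manifest_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the full synthetic end-to-end analysis and write a report bundle.

    Returns the run manifest (also written to ``manifest.json``).  Stage
    failures raise :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    genotypes = list(config.get("genotypes", DEFAULT_GENOTYPES))
    sim_kwargs = dict(config.get("simulate", {}))
    mhash = _manifest_hash({"config": config, "version": __version__})
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "manifest_hash": mhash,
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            try:
                result = fn()
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return result

        return wrap

    # --- simulate + call DEGs per genotype -------------------------------
    @stage("call-degs")
    def degs_by_genotype():
        tables = {}
        truths = {}
        for i, g in enumerate(genotypes):
            cfg = SimulationConfig(seed=seed + i, condition=g, **sim_kwargs)
            cm, truth = simulate_timecourse_counts(cfg)
            tables[g] = deg.call_degs(cm)
            truths[g] = truth
        return tables, truths

    deg_tables, truths = degs_by_genotype
    for g, table in deg_tables.items():
        _write_table(table, out / f"degs_{g}.tsv", mhash)
    manifest["stages"]["call-degs"] = {
        g: {"n_rows": int(len(t)), "n_degs": int((t["status"] != "ns").sum())}
        for g, t in deg_tables.items()
    }

    # --- classification --------------------------------------------------
    @stage("classify")
    def classify():
        temporal = programs.assign_temporal_programs(deg_tables[genotypes[0]])
        trends = programs.assign_trend_clusters(deg_tables, genotypes)
        cfg = SimulationConfig(seed=seed, **sim_kwargs)
        cm_sa, cm_ja, htruth = simulate_hormone_pair(cfg)
        sa_degs = deg.call_degs(cm_sa)
        ja_degs = deg.call_degs(cm_ja)
        hormones = programs.assign_hormone_programs(sa_degs, ja_degs)
        coreg = hormones.loc[hormones["hormone_program"] == "co_regulated", "gene"]
        sa_prof = cross.consolidate_profile(sa_degs, "SA")
        ja_prof = cross.consolidate_profile(ja_degs, "JA")
        shared = [g for g in coreg if g in sa_prof.genes and g in ja_prof.genes]
        corr = (
            programs.coreg_correlation(
                sa_prof.values.loc[shared], ja_prof.values.loc[shared]
            )
            if len(shared) >= 3
            else None
        )
        return temporal, trends, hormones, corr, sa_degs, ja_degs, htruth

    temporal, trends, hormones, coreg_corr, sa_degs, ja_degs, _h = classify
    merged = temporal.merge(trends, on="gene", how="outer").merge(
        hormones, on="gene", how="outer"
    )
    _write_table(merged, out / "programs.tsv", mhash)
    summary = programs.program_summary(
        degs_by_genotype=deg_tables, trend_clusters=trends, hormone_assignments=hormones
    )
    manifest["stages"]["classify"] = {
        "n_classified": summary.n_classified,
        "conserved_pct": summary.conserved_pct,
        "coreg_r": None if coreg_corr is None else round(coreg_corr.r, 4),
    }

    # --- family structure -------------------------------------------------
    @stage("structure")
    def structure():
        cfg = SimulationConfig(seed=seed, **sim_kwargs)
        catalog, newick, truth = simulate_family_structure(cfg)
        from .io import read_tree

        tree = read_tree(newick)
        expansions = family.detect_expansions(tree, cfg.focal_species)
        clusters = family.detect_physical_clusters(catalog)
        ever = set()
        for t in deg_tables.values():
            ever |= set(t.loc[t["status"] != "ns", "gene"])
        names = family.assign_nomenclature(
            tree, cfg.families[0][0], {g: g in ever for g in catalog.gene_ids}
        )
        return catalog, tree, expansions, clusters, names

    catalog, tree, expansions, clusters, names = structure
    write_gene_coords(catalog, out / "catalog.gff3", dialect="gff3")
    _write_table(
        pd.DataFrame(
            [
                {"expansion": e.node_id, "species": e.species, "size": e.size,
                 "members": ",".join(e.members)}
                for e in expansions
            ]
        ),
        out / "expansions.tsv",
        mhash,
    )
    _write_table(
        pd.DataFrame(
            [
                {"family": c.family, "chromosome": c.chromosome, "size": c.size,
                 "span": c.span, "members": ",".join(c.members)}
                for c in clusters
            ]
        ),
        out / "clusters.tsv",
        mhash,
    )
    _write_table(
        pd.DataFrame(
            [{"gene": n.gene_id, "name": n.name} for n in names]
        ),
        out / "names.tsv",
        mhash,
    )
    manifest["stages"]["structure"] = {
        "n_expansions": len(expansions),
        "n_clusters": len(clusters),
        "n_named": len(names),
    }

    # --- cross-stress ------------------------------------------------------
    @stage("cross-stress")
    def cross_stage():
        profiles = {
            g: cross.consolidate_profile(t, g) for g, t in deg_tables.items()
        }
        rows = []
        keys = list(profiles)
        thr = config.get("thresholds", {})
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                res = cross.correlate_stresses(
                    profiles[keys[i]],
                    profiles[keys[j]],
                    min_shared=int(thr.get("min_shared_degs", cross.MIN_SHARED_DEGS)),
                    k=float(thr.get("outlier_k", cross.OUTLIER_K)),
                )
                rows.append(
                    {
                        "a": keys[i],
                        "b": keys[j],
                        "r": res.r,
                        "p": res.p,
                        "n_used": res.n_used,
                        "n_shared": res.n_shared,
                        "strength": res.strength,
                        "skipped": res.skipped,
                        "reason": res.skip_reason,
                    }
                )
        return pd.DataFrame(rows)

    corr_table = cross_stage
    _write_table(corr_table, out / "correlations.tsv", mhash)
    manifest["stages"]["cross-stress"] = {"n_pairs": int(len(corr_table))}

    # --- qPCR concordance on a noiseless synthetic Ct table ----------------
    @stage("qpcr")
    def qpcr_stage():
        rng = np.random.default_rng([seed, 99])
        profile = cross.consolidate_profile(deg_tables[genotypes[0]])
        picks = list(profile.values.index[:8])
        if len(picks) < 3:
            return None
        rows = []
        for cond, shift in (("treated", True), ("control", False)):
            for rep in range(1, 4):
                sample = f"{cond}_r{rep}"
                rows.append({"gene": "REF", "sample": sample, "condition": cond, "ct": 20.0})
                for gene in picks:
                    lfc = profile.values[gene] if shift else 0.0
                    rows.append(
                        {
                            "gene": gene,
                            "sample": sample,
                            "condition": cond,
                            "ct": 25.0 - lfc + 0.05 * rng.standard_normal(),
                        }
                    )
        ct = pd.DataFrame(rows)
        dd = qpcr.delta_delta_ct(ct, "treated", "control", "REF")
        seq = profile.values.loc[dd["gene"]].to_numpy()
        conc = qpcr.platform_concordance(dd["log2fc"].to_numpy(), seq)
        return dd, conc

    qres = qpcr_stage
    if qres is not None:
        dd, conc = qres
        _write_table(dd, out / "qpcr.tsv", mhash)
        manifest["stages"]["qpcr"] = {"n_genes": int(len(dd)), "r": round(conc.r, 4)}

    # heatmap-ready matrix: gene x (genotype, timepoint) log2FC
    wide = pd.concat(
        [
            t.assign(col=lambda d, g=g: g + "_" + d["timepoint"].astype(str))[
                ["gene", "col", "log2fc"]
            ]
            for g, t in deg_tables.items()
        ]
    ).pivot(index="gene", columns="col", values="log2fc")
    _write_table(wide, out / "log2fc_matrix.tsv", mhash, index=True)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
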