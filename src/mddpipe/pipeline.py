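"""End-to-end orchestration: simulate -> dge -> coexpr -> ora -> mkl.

Writes every stage artifact to an output directory plus a JSON manifest
(parameters, seeds, package version, SHA-256 file hashes), so a rerun
with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from mddpipe import __version__, coexpr, dge, enrichment, io, mkl, simulate

logger = logging.getLogger("mddpipe")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and stage settings for a full pipeline run.

    When ``counts``/``metadata``/``gmt`` are None the synthetic cohort with
    the default study structure is generated first.
    """

    outdir: Path = Path("mddpipe_out")
    counts: Path | None = None
    metadata: Path | None = None
    gmt: Path | None = None
    covariates: tuple[str, ...] = ("dataset", "sex", "age", "pmi")
    dge_regions: tuple[str, ...] | None = None  # None: every region + pooled
    padj_threshold: float = 0.05
    module_padj: float = 0.1
    filter_p: float = 0.1
    min_module_size: int = 30
    nes_permutations: int = 1000
    mkl_replications: int = 100
    mkl_train_frac: float = 0.8
    mkl_inner_folds: int = 4
    selection_threshold: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        for name in ("padj_threshold", "module_padj", "filter_p", "selection_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not (0 < self.mkl_train_frac < 1):
            raise ValueError("mkl_train_frac must be in (0, 1)")
        given = [self.counts, self.metadata, self.gmt]
        if any(p is not None for p in given) and not all(p is not None for p in given):
            raise ValueError("provide counts, metadata and gmt together, or none")
        for p in given:
            if p is not None and not Path(p).exists():
                raise ValueError(f"input file not found: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written as JSON).

    Stage failures are recorded in the manifest and re-raised after the
    manifest is written, so partial completion is always observable.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in vars(config).items()
        },
        "stages": {},
        "outputs": {},
    }
    error: Exception | None = None
    try:
        _run_stages(config, outdir, manifest)
    except Exception as exc:  # record partial completion, then re-raise
        error = exc
        manifest["error"] = f"{type(exc).__name__}: {exc}"
    manifest["outputs"] = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.glob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    io.write_json(manifest, outdir / "manifest.json")
    if error is not None:
        raise error
    return manifest


def _stage(manifest: dict, name: str, t0: float, **info) -> None:
    manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **info}
    logger.info("stage %s done (%.1fs) %s", name, time.time() - t0, info)


def _run_stages(config: PipelineConfig, outdir: Path, manifest: dict) -> None:
    # --- inputs / simulation -------------------------------------------
    t0 = time.time()
    if config.counts is None:
        sim = simulate.SimConfig(seed=config.seed)
        pathways = simulate.generate_pathways(sim)
        metadata = simulate.generate_metadata(sim)
        counts, truth = simulate.generate_counts(sim, metadata, pathways)
        io.write_counts_tsv(counts, outdir / "counts.tsv")
        io.write_metadata_tsv(metadata, outdir / "metadata.tsv")
        io.write_gmt(pathways, outdir / "pathways.gmt")
        truth.to_json(outdir / "ground_truth.json")
        _stage(manifest, "simulate", t0, n_genes=counts.shape[0],
               n_samples=counts.shape[1])
    else:
        counts = io.read_counts_tsv(config.counts)
        metadata = io.read_metadata_tsv(config.metadata)
        pathways = io.read_gmt(config.gmt)
        _stage(manifest, "load", t0, n_genes=counts.shape[0],
               n_samples=counts.shape[1])

    design = dge.DesignSpec(covariates=config.covariates)

    # --- per-region + pooled DGE ---------------------------------------
    t0 = time.time()
    regions = (
        list(config.dge_regions)
        if config.dge_regions is not None
        else sorted(metadata["region"].unique())
    )
    results: dict[str, dge.DGEResult] = {}
    for region in regions:
        sub = metadata.loc[metadata["region"] == region, "condition"]
        if sub.nunique() < 2:
            logger.warning("region %s has one condition; skipped", region)
            continue
        res = dge.run_region_dge(counts, metadata, design, region=region)
        res.table.to_csv(outdir / f"dge_{region}.tsv", sep="\t", index_label="gene_id")
        results[region] = res
    # the intersection analysis targets the regions that show any DE signal
    de_counts = {
        r: len(res.de_genes(config.padj_threshold)) for r, res in results.items()
    }
    affected_map = {r: results[r] for r, n in de_counts.items() if n > 0} or results
    venn = dge.intersect_de_sets(affected_map, threshold=config.padj_threshold)
    io.write_json(
        {
            "per_region": {r: sorted(s) for r, s in venn.de_sets.items()},
            "intersection_counts": {
                "+".join(k): v for k, v in venn.intersection_counts.items()
            },
            "common_genes": sorted(venn.common_genes),
            "common_signs": venn.common_signs,
        },
        outdir / "venn.json",
    )
    spearman = dge.cross_region_spearman(results)
    spearman.to_csv(outdir / "spearman.tsv", sep="\t")
    affected = sorted(affected_map)
    pooled_meta = metadata.loc[metadata["region"].isin(affected)]
    pooled = dge.run_region_dge(counts, pooled_meta, design, region="pooled")
    pooled.table.to_csv(outdir / "dge_pooled.tsv", sep="\t", index_label="gene_id")
    _stage(manifest, "dge", t0, regions=regions, affected_regions=affected,
           common_genes=sorted(venn.common_genes))

    # --- co-expression on the affected regions -------------------------
    t0 = time.time()
    expr = coexpr.normalized_log_expression(
        counts.loc[:, pooled_meta.index], pooled.size_factors
    )
    kept = coexpr.filter_genes_by_variance(expr, p_threshold=config.filter_p)
    beta = coexpr.select_soft_threshold(expr.loc[kept])
    modules = coexpr.detect_modules(
        expr.loc[kept], beta, min_module_size=config.min_module_size,
        filter_pvalue=config.filter_p,
    )
    mod_coll = io.GeneSetCollection()
    for i, mod in enumerate(modules.modules, start=1):
        mod_coll.add(f"M{i}", sorted(mod), "co-expression module")
    io.write_gmt(mod_coll, outdir / "modules.gmt")
    if modules.modules:
        nes = coexpr.module_nes(
            expr.loc[kept], pooled_meta["condition"], modules,
            n_perm=config.nes_permutations, seed=config.seed,
        )
        nes.to_csv(outdir / "module_nes.tsv", sep="\t", index=False)
    _stage(manifest, "coexpr", t0, beta=beta, n_filtered=len(kept),
           n_modules=len(modules.modules))

    # --- overrepresentation of pooled DE genes -------------------------
    t0 = time.time()
    query = pooled.de_genes(config.padj_threshold)
    background = set(pooled.table.index)
    if query:
        ora = enrichment.run_ora(
            query, pathways, background, seed=config.seed
        )
        ora.table.to_csv(outdir / "ora.tsv", sep="\t", index=False)
        ora.edges.to_csv(outdir / "ora_edges.tsv", sep="\t", index=False)
        _stage(manifest, "ora", t0, n_query=len(query),
               n_uncovered=len(ora.uncovered_genes))
    else:
        _stage(manifest, "ora", t0, n_query=0, skipped=True)

    # --- MKL over all regions and samples ------------------------------
    t0 = time.time()
    sf_all = dge.estimate_size_factors(counts, pseudocount=0.5)
    norm_all = counts / sf_all
    report = mkl.replicate_experiment(
        norm_all, metadata["condition"], pathways,
        n_replications=config.mkl_replications,
        seed=config.seed,
        train_frac=config.mkl_train_frac,
        inner_folds=config.mkl_inner_folds,
        selection_threshold=config.selection_threshold,
    )
    io.write_json(report.to_dict(), outdir / "mkl_report.json")
    report.selection_table().to_csv(outdir / "mkl_selection.tsv", sep="\t", index=False)
    _stage(manifest, "mkl", t0, mean_auc=report.mean_auc, sd_auc=report.sd_auc,
           n_informative=len(report.informative_pathways()))
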