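"""End-to-end orchestration: simulate -> qc -> filter -> dmr -> annotate ->
enrich -> explore, with one YAML config, per-stage seeding, and a manifest.

Re-running the pipeline with an identical config reproduces byte-identical
text outputs: all randomness flows through per-stage generators derived
from the single config seed, and every table is written with a fixed float
format.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (
    AnnotationDB,
    CPG_FEATURES,
    GENE_FEATURES,
    REPEAT_CLASSES,
    classify_cpg,
    classify_gene_feature,
    classify_repeat,
    build_repeat_index,
    derive_cpg_context,
    feature_distribution,
    gene_feature_tracks,
    write_gene_models,
)
from .diffmeth import (
    attach_coordinates,
    call_dmrs,
    map_dmrs_to_genes,
    robustness_excluding,
    size_factors,
    subgroup_dmr,
    write_dmr_table,
)
from .enrich import hypergeom_ora, permutation_z, write_gmt
from .explore import heatmap_matrix, kmeans_cluster, svd_batch_check, top_variance_bins, vst
from .filters import run_filter_cascade
from .genome import GInterval, build_bin_grid, cpg_per_bin, write_bed, write_chrom_sizes, write_fasta
from .qc import evaluate_wells, write_report
from .simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_ddpcr_wells,
    simulate_gene_sets,
    simulate_genome,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("cfmeth.pipeline")

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Every knob of one reproducible run."""

    outdir: str = "cfmeth_run"
    seed: int = 0
    simulate: SimulationConfig = field(default_factory=SimulationConfig)

    # thresholds (analysis-wide printed constants)
    pbl_threshold: int = 20
    min_total: int = 10
    padj_alpha: float = 0.1
    n_permutations: int = 1000
    top_variance_k: int = 10_000
    kmeans_k: int = 2
    ora_alpha: float = 0.1

    contrast: str = "oc-vs-all"  # oc-vs-all | oc-vs-benign | oc-vs-healthy
    exclude: str | None = "auto"  # sample id, "auto" (the simulated outlier), or None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in (raw.pop("simulate", {}) or {}).items()
        })
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulate=sim, **raw)

    def to_canonical_yaml(self) -> str:
        payload = dataclasses.asdict(self)
        return yaml.safe_dump(payload, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the analysis conditions (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        text = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    def stage_seed(self, stage: int) -> int:
        return (self.seed * 1009 + 7919 * stage + 1) % (2**31 - 1)


def _contrast_subset(contrast: str) -> str:
    mapping = {"oc-vs-all": "both", "oc-vs-benign": "benign", "oc-vs-healthy": "healthy"}
    if contrast not in mapping:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {list(mapping)}")
    return mapping[contrast]


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every stage in order; returns the manifest (also written to disk)."""
    _contrast_subset(config.contrast)  # validate before any compute
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    # ---- stage 1: simulate -------------------------------------------------
    log.info("stage simulate")
    sim = config.simulate
    rng_genome = np.random.default_rng(config.stage_seed(1))
    layout, sequences, db = simulate_genome(sim, rng_genome)
    grid = build_bin_grid(layout, sim.bin_width)
    rng_counts = np.random.default_rng(config.stage_seed(2))
    counts, sheet, truth = simulate_counts(sim, grid, sequences, db, rng_counts)
    wells, well_truth = simulate_ddpcr_wells(
        n_samples=12, rng=np.random.default_rng(config.stage_seed(3))
    )

    write_fasta(sequences, out / "genome.fa")
    write_chrom_sizes(layout, out / "genome.chrom.sizes")
    write_bed(db.blacklist, out / "blacklist.bed")
    write_bed(db.cpg_islands, out / "cpg_islands.bed")
    write_bed(db.repeats, out / "repeats.bed")
    write_gene_models(db.genes, out / "genes.tsv")
    counts.to_tsv(out / "counts.tsv")
    sheet.to_csv(out / "samples.csv")
    truth.to_tsv(out / "truth.tsv")
    wells.to_csv(out / "ddpcr_wells.csv", index=False)
    well_truth.to_csv(out / "ddpcr_regimes.csv", index=False)
    manifest["stages"]["simulate"] = {
        "n_bins": grid.n_bins,
        "n_samples": len(counts.samples),
        "n_genes": len(db.genes),
        "n_spikes": len(truth.spiked_bins),
        "outlier": truth.outlier_sample,
    }

    # ---- stage 2: qc -------------------------------------------------------
    log.info("stage qc")
    qc_report = evaluate_wells(wells)
    write_report(qc_report, out / "qc_report.tsv", out / "qc_flags.json")
    manifest["stages"]["qc"] = {
        "n_samples": int(len(qc_report)),
        "n_invalid": int((qc_report["contamination_flag"] == "invalid").sum()),
    }

    # ---- stage 3: filter ---------------------------------------------------
    log.info("stage filter")
    cpg = cpg_per_bin(grid, sequences)
    filtered, report = run_filter_cascade(
        counts, sheet, db.blacklist, cpg,
        pbl_threshold=config.pbl_threshold, min_total=config.min_total,
    )
    filtered.to_tsv(out / "counts.filtered.tsv")
    report.to_tsv(out / "filter_report.tsv")
    manifest["stages"]["filter"] = {
        name: {"removed": rem, "remaining": left} for name, rem, left in report.stages
    }

    # ---- stage 4: dmr ------------------------------------------------------
    log.info("stage dmr")
    exclude: list[str] = []
    exclude_id = truth.outlier_sample if config.exclude == "auto" else config.exclude
    table = subgroup_dmr(filtered, sheet, control_subset=_contrast_subset(config.contrast))
    write_dmr_table(table, grid, out / "dmr_table.tsv")
    called, tally = call_dmrs(table, config.padj_alpha)
    genes_table = map_dmrs_to_genes(called, db.gene_bodies(), grid)
    attach = attach_coordinates(called, grid)
    attach.to_csv(out / "dmr_called.tsv", sep="\t", index_label="bin_id", float_format=_FLOAT_FMT)
    genes_table.to_csv(out / "dmr_genes.tsv", sep="\t", float_format=_FLOAT_FMT)

    robust = None
    if exclude_id is not None:
        robust = robustness_excluding(
            filtered, sheet, exclude_id, db.gene_bodies(), alpha=config.padj_alpha,
            full_table=table,
        )
        pd.DataFrame(
            {
                "gene": sorted(robust.genes_full | robust.genes_reduced),
            }
        ).assign(
            in_full=lambda d: d["gene"].isin(robust.genes_full),
            in_reduced=lambda d: d["gene"].isin(robust.genes_reduced),
            robust=lambda d: d["gene"].isin(robust.robust_genes),
        ).to_csv(out / "robust_genes.tsv", sep="\t", index=False)
    manifest["stages"]["dmr"] = {
        "tested": int(table["tested"].sum()),
        "called": int(len(called)),
        "hyper": tally["hyper"],
        "hypo": tally["hypo"],
        "genes": int(len(genes_table)),
        "robust_genes": (len(robust.robust_genes) if robust is not None else None),
        "excluded": exclude_id,
    }

    # ---- stage 5: annotate -------------------------------------------------
    log.info("stage annotate")
    hyper = called[called["log2FoldChange"] > 0]
    hyper_regions = [grid.bin_interval(int(b)) for b in hyper.index]
    context = derive_cpg_context(db.cpg_islands, layout)
    rep_index = build_repeat_index(db.repeats)
    ann_counts = {}
    if hyper_regions:
        dist_cpg = feature_distribution(
            hyper_regions, lambda r: classify_cpg(r, context), CPG_FEATURES
        )
        dist_gene = feature_distribution(
            hyper_regions, lambda r: classify_gene_feature(r, db.genes, layout), GENE_FEATURES
        )
        dist_rep = feature_distribution(
            hyper_regions, lambda r: classify_repeat(r, rep_index),
            REPEAT_CLASSES + ("none",),
        )
        dist_cpg.to_csv(out / "distribution_cpg.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        dist_gene.to_csv(out / "distribution_gene.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        dist_rep.to_csv(out / "distribution_repeat.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        ann_counts = {
            "cpg_assignments": int(dist_cpg["count"].sum()),
            "gene_assignments": int(dist_gene["count"].sum()),
            "repeat_assignments": int(dist_rep["count"].sum()),
        }
    manifest["stages"]["annotate"] = {"n_hyper_regions": len(hyper_regions), **ann_counts}

    # ---- stage 6: enrich ---------------------------------------------------
    log.info("stage enrich")
    perm_rows = []
    if hyper_regions:
        feature_sets: dict[str, list[GInterval]] = {
            f"cpg:{cat}": context.intervals(cat) for cat in CPG_FEATURES
        }
        for cat, track in gene_feature_tracks(db.genes, layout).items():
            feature_sets[f"gene:{cat}"] = track
        for cls in REPEAT_CLASSES:
            feature_sets[f"repeat:{cls}"] = [r for r in db.repeats if r.name == cls]
        for i, (name, feats) in enumerate(sorted(feature_sets.items())):
            if not feats:
                continue
            res = permutation_z(
                hyper_regions, feats, layout, n=config.n_permutations,
                seed=config.stage_seed(40 + i), feature_name=name,
            )
            perm_rows.append(res.to_dict())
        pd.DataFrame(perm_rows).to_csv(
            out / "permutation_z.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )

    universe = [g.name for g in db.genes]
    gene_sets = simulate_gene_sets(
        universe, sorted(truth.spiked_gene_set),
        rng=np.random.default_rng(config.stage_seed(5)),
    )
    write_gmt(gene_sets, out / "gene_sets.gmt")
    ora = hypergeom_ora(sorted(genes_table.index), gene_sets, universe, alpha=config.ora_alpha)
    ora.to_csv(out / "ora.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    manifest["stages"]["enrich"] = {
        "n_features_tested": len(perm_rows),
        "n_terms": int(len(ora)),
        "n_terms_significant": int(ora["significant"].sum()) if len(ora) else 0,
    }

    # ---- stage 7: explore --------------------------------------------------
    log.info("stage explore")
    factors = size_factors(filtered.counts, allow_pseudo_reference=True)
    transformed = vst(filtered.counts, factors)
    batches = sheet.table.set_index("sample_id")["batch"]
    batch_check = svd_batch_check(transformed, batches)
    with open(out / "batch_check.json", "w") as fh:
        json.dump(batch_check, fh, indent=2, sort_keys=True)

    k_top = min(config.top_variance_k, filtered.counts.shape[0])
    top_bins = top_variance_bins(filtered.counts, k_top)
    assign, coords, inertia = kmeans_cluster(
        filtered.counts.loc[top_bins], k=config.kmeans_k, seed=config.stage_seed(6)
    )
    cluster_out = pd.concat([assign, coords], axis=1)
    cluster_out.to_csv(out / "clusters.tsv", sep="\t", index_label="sample_id", float_format=_FLOAT_FMT)

    heat = None
    if robust is not None and len(robust.representatives):
        heat = heatmap_matrix(filtered.counts, robust.representatives, sheet)
        heat.to_csv(out / "heatmap_matrix.tsv", sep="\t", index_label="gene", float_format=_FLOAT_FMT)
        (out / "heatmap_column_order.txt").write_text("\n".join(heat.columns) + "\n")
    manifest["stages"]["explore"] = {
        "batch_p_sv1": batch_check["p_sv1"],
        "batch_p_sv2": batch_check["p_sv2"],
        "kmeans_inertia": inertia,
        "top_variance_k": int(k_top),
        "heatmap_genes": int(len(heat)) if heat is not None else 0,
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
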