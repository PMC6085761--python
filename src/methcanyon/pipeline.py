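"""End-to-end pipeline orchestration.

Stages: UMR detection per sample -> per-group reference atlas (UOF +
Poisson) -> combined atlas -> entropy heterogeneity filter -> beta-LRT
differential methylation (pan-cancer + per tumor type) -> gene association,
DE filter and gene-set enrichment -> metagene bin correlation. All
inter-stage state is plain text (TSV/BED); every run writes a manifest with
the parameters and seed used.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import diffmeth, entropy_filter, gene_association, metagene, reference_atlas
from .core import ReferenceUMR
from .io_formats import write_gene_models, write_regions_bed
from .simulate import SimCohort, SimConfig, simulate_cohort, truth_report
from .umr_detection import detect_umrs

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters, at the analysis defaults."""

    seed: int = 0
    min_coverage: int = 4
    min_cpgs: int = 4
    max_mean: float = 0.10
    # Per-CpG cap: runs stop only at confidently methylated CpGs; the binding
    # rule is the run mean < max_mean. See the methods note.
    cpg_threshold: float = 0.5
    max_gap: int = 1000
    min_obs_exp: float = 0.1
    poisson_p_cutoff: float = 1.0e-8
    entropy_threshold: Optional[float] = None  # None -> log2(N) - 1
    dm_fdr: float = 0.001
    dm_value: float = 0.1
    de_fdr: float = 0.01
    de_fc: float = 2.0
    min_bin_genes: int = 10
    sim: SimConfig = field(default_factory=SimConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class PipelineState:
    config: PipelineConfig
    cohort: SimCohort
    umrs_by_sample: Dict[str, list] = field(default_factory=dict)
    ref_normal: List[ReferenceUMR] = field(default_factory=list)
    ref_tumor: List[ReferenceUMR] = field(default_factory=list)
    ref_combined: List[ReferenceUMR] = field(default_factory=list)
    ref_filtered: List[ReferenceUMR] = field(default_factory=list)
    dm_results: list = field(default_factory=list)
    per_type: Optional[pd.DataFrame] = None
    de_up: List[str] = field(default_factory=list)
    de_down: List[str] = field(default_factory=list)
    de_table: Optional[pd.DataFrame] = None
    enrichment: Optional[pd.DataFrame] = None
    bin_change: Optional[metagene.BinCorrelation] = None
    recovery: Optional[pd.DataFrame] = None


def simulate_stage(config: PipelineConfig) -> PipelineState:
    cfg = dataclasses.replace(config.sim, seed=config.seed)
    config.sim = cfg
    cohort = simulate_cohort(cfg)
    log.info(
        "simulated cohort: %d normals, %d tumors, %d genes",
        len(cohort.normals),
        len(cohort.tumors),
        len(cohort.gene_models),
    )
    return PipelineState(config=config, cohort=cohort)


def detect_stage(state: PipelineState) -> PipelineState:
    c = state.config
    for m in state.cohort.methylomes:
        state.umrs_by_sample[m.sample_id] = detect_umrs(
            m,
            min_cpgs=c.min_cpgs,
            max_mean=c.max_mean,
            cpg_threshold=c.cpg_threshold,
            max_gap=c.max_gap,
        )
    n = sum(len(v) for v in state.umrs_by_sample.values())
    log.info("detected %d UMRs across %d samples", n, len(state.umrs_by_sample))
    return state


def atlas_stage(state: PipelineState) -> PipelineState:
    c = state.config
    normal_sets = [state.umrs_by_sample[m.sample_id] for m in state.cohort.normals]
    tumor_sets = [state.umrs_by_sample[m.sample_id] for m in state.cohort.tumors]
    seg_n = reference_atlas.atomic_segments(normal_sets)
    seg_t = reference_atlas.atomic_segments(tumor_sets)
    state.ref_normal = reference_atlas.call_reference_umrs(seg_n, c.poisson_p_cutoff)
    state.ref_tumor = reference_atlas.call_reference_umrs(seg_t, c.poisson_p_cutoff)
    state.ref_combined = reference_atlas.combine_normal_tumor_atlases(
        state.ref_normal, state.ref_tumor
    )
    log.info(
        "reference atlas: %d normal, %d tumor, %d combined (%d canyons)",
        len(state.ref_normal),
        len(state.ref_tumor),
        len(state.ref_combined),
        sum(1 for r in state.ref_combined if r.umr_class == "canyon"),
    )
    return state


def entropy_stage(state: PipelineState) -> PipelineState:
    c = state.config
    state.ref_filtered = entropy_filter.filter_heterogeneous(
        state.ref_combined,
        state.cohort.normals,
        threshold_bits=c.entropy_threshold,
    )
    return state


def diffmeth_stage(state: PipelineState) -> PipelineState:
    c = state.config
    state.dm_results, state.per_type = diffmeth.call_pan_cancer(
        state.ref_filtered,
        state.cohort.normals,
        state.cohort.tumors,
        fdr_cut=c.dm_fdr,
        dm_cut=c.dm_value,
    )
    counts = pd.Series([r.category for r in state.dm_results]).value_counts()
    log.info("differential methylation categories: %s", counts.to_dict())
    return state


def association_stage(state: PipelineState) -> PipelineState:
    c = state.config
    cohort = state.cohort
    normal_ids = [m.sample_id for m in cohort.normals]
    tumor_ids = [m.sample_id for m in cohort.tumors]
    state.de_up, state.de_down, state.de_table = gene_association.de_filter(
        cohort.expression, normal_ids, tumor_ids, fdr_cut=c.de_fdr, fc_cut=c.de_fc
    )
    hyper_canyons = [
        r for r in state.dm_results if r.category == "hyper-canyon"
    ]
    annos = gene_association.associate_umrs_to_genes(hyper_canyons, cohort.gene_models)
    category_genes = [a.gene_id for a in annos]
    background = [g.gene_id for g in cohort.gene_models]
    rows = []
    for name, genes in cohort.gene_sets.items():
        res = gene_association.fisher_enrichment(
            category_genes, genes, background, set_name=name
        )
        rows.append(
            {
                "gene_set": name,
                "n_overlap": res.table[0][0],
                "odds_ratio": res.odds_ratio,
                "p_value": res.p_value,
            }
        )
    state.enrichment = pd.DataFrame(rows)
    return state


def bincorr_stage(state: PipelineState) -> PipelineState:
    """Paired tumor/normal per-bin correlation over the planted gene classes
    plus background genes (first tumor vs first normal sample)."""
    c = state.config
    cohort = state.cohort
    tumor = cohort.tumors[0]
    normal = cohort.normals[0]
    genes = cohort.gene_models
    state.bin_change = metagene.bin_correlation_change(
        tumor,
        normal,
        cohort.expression[tumor.sample_id].to_dict(),
        cohort.expression[normal.sample_id].to_dict(),
        genes,
        min_n=c.min_bin_genes,
    )
    return state


def recovery_stage(state: PipelineState) -> PipelineState:
    by_cat: Dict[str, list] = {}
    for r in state.dm_results:
        if r.category != "none":
            by_cat.setdefault(r.category, []).append(r.region)
    state.recovery = truth_report(state.cohort.truth, by_cat)
    return state


STAGES = [
    detect_stage,
    atlas_stage,
    entropy_stage,
    diffmeth_stage,
    association_stage,
    bincorr_stage,
    recovery_stage,
]


def run_upto(config: PipelineConfig, stage_name: str) -> PipelineState:
    """Run the pipeline from simulation up to and including ``stage_name``."""
    state = simulate_stage(config)
    for stage in STAGES:
        state = stage(state)
        if stage.__name__ == stage_name:
            break
    return state


def write_outputs(state: PipelineState, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "umr").mkdir(exist_ok=True)
    for sid, umrs in state.umrs_by_sample.items():
        write_regions_bed(umrs, out / "umr" / f"{sid}.umr.bed")
    write_regions_bed(state.ref_normal, out / "reference_normal.bed")
    write_regions_bed(state.ref_tumor, out / "reference_tumor.bed")
    write_regions_bed(state.ref_combined, out / "reference_combined.bed")
    write_regions_bed(state.ref_filtered, out / "reference_filtered.bed")
    diffmeth.results_table(state.dm_results).to_csv(
        out / "dm.tsv", sep="\t", index=False, float_format="%.6g"
    )
    if state.per_type is not None:
        state.per_type.to_csv(out / "dm_per_type.tsv", sep="\t")
    if state.de_table is not None:
        state.de_table.to_csv(
            out / "de_genes.tsv", sep="\t", float_format="%.6g"
        )
    if state.enrichment is not None:
        state.enrichment.to_csv(
            out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
        )
    if state.bin_change is not None:
        state.bin_change.as_frame().to_csv(
            out / "bins_change.tsv", sep="\t", index=False, float_format="%.6g"
        )
    if state.recovery is not None:
        state.recovery.to_csv(
            out / "recovery.tsv", sep="\t", index=False, float_format="%.6g"
        )
    write_gene_models(state.cohort.gene_models, out / "genes.tsv")
    state.cohort.truth.save(out / "truth")
    manifest = {
        "parameters": state.config.to_dict(),
        "n_samples": len(state.cohort.methylomes),
        "n_reference_umrs": len(state.ref_combined),
        "n_reference_filtered": len(state.ref_filtered),
        "n_dm_results": len(state.dm_results),
        "stages": [s.__name__ for s in STAGES],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_all(config: PipelineConfig, outdir=None) -> PipelineState:
    """Execute every stage on a simulated cohort; optionally write all
    tables plus a manifest to ``outdir``."""
    state = simulate_stage(config)
    for stage in STAGES:
        try:
            state = stage(state)
        except Exception as exc:  # noqa: BLE001 - name the failing stage
            raise RuntimeError(f"stage {stage.__name__} failed: {exc}") from exc
    if outdir is not None:
        write_outputs(state, outdir)
    return state
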