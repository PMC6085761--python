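"""Synthetic methylome cohort generator with known ground truth.

One synthetic chromosome carries planted methylation canyons (> 3.5 kb) and
shorter control UMRs against a highly methylated background. CpG positions
are drawn with geometric gaps and are five-fold densified inside planted
regions (CpG-island-like density). Per sample and CpG, a latent methylation
level is drawn from the region's Beta law; the observed ratio is a binomial
draw at the CpG's read coverage (negative-binomial across CpGs) divided by
that coverage, so low coverage adds realistic noise.

The default cohort mirrors a pan-cancer design: 30 normal and 35 tumor
methylomes across 7 tumor-type labels. Tumor effects re-parameterize the
Beta mean at fixed concentration: 18% of canyons (and a configurable share
of cUMRs) are hypermethylated in tumors, 5% hypomethylated (hypo regions
are under-methylated in tumors but moderately methylated in normals, so they
enter the atlas through the tumor arm). Additional planted structure:

* sample-specific decoy UMRs (each sample privately hypomethylates a small
  random subset of decoy sites), giving the occupancy profile the realistic
  background of non-recurrent UMRs;
* "unstable" regions, unmethylated in most normals but methylated in a few,
  which the entropy filter is expected to remove;
* promoter-hypermethylation blocks over the promoters of a planted gene
  class, silencing them in tumors.

Expression is RSEM-like: 2**(baseline + slope * gene-body methylation) for
canyon-body genes (positive coupling), 2**(baseline - slope * promoter
methylation) for promoter-silenced genes, log-normal noise throughout. The
seed fully determines the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import GeneModel, Methylome, Region


@dataclass
class SimConfig:
    seed: int = 0
    n_normals: int = 30
    n_tumors: int = 35
    n_tumor_types: int = 7
    # genome layout
    bg_cpg_gap: float = 120.0  # geometric mean gap between background CpGs, bp
    densify_factor: int = 5  # CpG densification inside planted regions
    n_canyons: int = 60
    canyon_len: Tuple[int, int] = (4200, 8000)
    n_cumrs: int = 150
    cumr_len: Tuple[int, int] = (700, 2200)
    n_unstable: int = 12  # heterogeneous-in-normals regions
    unstable_len: Tuple[int, int] = (700, 1500)
    unstable_high_frac: float = 0.1  # normals in which an unstable region is methylated
    n_promoter_genes: int = 15
    n_background_genes: int = 45
    gap_len: Tuple[int, int] = (8000, 18000)
    # decoy (sample-specific) UMR sites
    n_decoy_sites: int = 30000
    decoy_len: int = 800
    decoy_rate: float = 0.010  # per-sample activation probability per site
    # methylation laws
    alpha_bg: float = 8.5
    beta_bg: float = 1.5  # background mean 0.85
    alpha_lo: float = 1.0
    beta_lo: float = 19.0  # UMR mean 0.05
    hypo_normal_mean: float = 0.30  # hypo regions in normals
    concentration: float = 20.0  # kept fixed when shifting the beta mean
    body_hyper_mean: float = 0.50  # tumor mean inside hypermethylated regions
    promoter_hyper_mean: float = 0.60
    unstable_high_mean: float = 0.80
    frac_hyper_canyon: float = 0.18
    frac_hypo_canyon: float = 0.05
    frac_hyper_cumr: float = 0.10
    frac_hypo_cumr: float = 0.10
    # coverage
    coverage_mean: float = 30.0
    coverage_dispersion: float = 8.0  # gamma shape of the gamma-Poisson mixture
    min_coverage: int = 4
    # expression
    expr_baseline_mean: float = 5.0  # log2 scale
    expr_baseline_sd: float = 1.0
    body_coupling_slope: float = 4.0  # log2 expression per unit body methylation
    promoter_coupling_slope: float = 4.0
    expr_noise_sd: float = 0.3
    chrom: str = "chrS"

    def validate(self) -> None:
        problems = []
        for name in (
            "frac_hyper_canyon",
            "frac_hypo_canyon",
            "frac_hyper_cumr",
            "frac_hypo_cumr",
            "decoy_rate",
            "unstable_high_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name}={v} not in [0, 1]")
        if self.frac_hyper_canyon + self.frac_hypo_canyon > 1:
            problems.append("canyon hyper+hypo fractions exceed 1")
        if self.frac_hyper_cumr + self.frac_hypo_cumr > 1:
            problems.append("cUMR hyper+hypo fractions exceed 1")
        if self.n_normals < 3 or self.n_tumors < 3:
            problems.append("need at least 3 samples per group")
        if self.coverage_mean <= 0 or self.bg_cpg_gap <= 1:
            problems.append("coverage_mean and bg_cpg_gap must be positive")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))


@dataclass
class PlantedRegion:
    region: Region
    kind: str  # canyon | cumr | unstable | promoter_block
    effect: str  # hyper | hypo | none
    normal_mean: float
    tumor_mean: float
    gene_id: Optional[str] = None
    high_normals: Tuple[int, ...] = ()  # sample indices where an unstable region is methylated


@dataclass
class SyntheticTruth:
    config: SimConfig
    chrom_len: int
    regions: List[PlantedRegion]
    decoy_sites: List[Region]
    decoy_active: Dict[str, List[int]]  # sample_id -> active site indices
    gene_labels: pd.DataFrame  # gene_id, role, effect
    gene_sets: Dict[str, List[str]]

    def planted_regions(self, kinds=None, effects=None) -> List[PlantedRegion]:
        out = self.regions
        if kinds is not None:
            out = [r for r in out if r.kind in kinds]
        if effects is not None:
            out = [r for r in out if r.effect in effects]
        return list(out)

    def sample_umr_truth(self, sample_id: str, group: str, sample_index: int) -> List[Region]:
        """Intervals genuinely under-methylated in one sample."""
        out: List[Region] = []
        for pr in self.regions:
            if pr.kind == "unstable":
                low = group == "normal" and sample_index not in pr.high_normals
            elif group == "normal":
                low = pr.normal_mean < 0.10
            else:
                low = pr.tumor_mean < 0.10
            if low:
                out.append(pr.region)
        for i in self.decoy_active.get(sample_id, []):
            out.append(self.decoy_sites[i])
        out.sort(key=lambda r: (r.chrom, r.start))
        return out

    def regions_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.region.chrom for r in self.regions],
                "start": [r.region.start for r in self.regions],
                "end": [r.region.end for r in self.regions],
                "kind": [r.kind for r in self.regions],
                "effect": [r.effect for r in self.regions],
                "normal_mean": [r.normal_mean for r in self.regions],
                "tumor_mean": [r.tumor_mean for r in self.regions],
                "gene_id": [r.gene_id or "" for r in self.regions],
            }
        )

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.regions_table().to_csv(outdir / "regions.tsv", sep="\t", index=False)
        self.gene_labels.to_csv(outdir / "gene_labels.tsv", sep="\t", index=False)


@dataclass
class SimCohort:
    methylomes: List[Methylome]
    expression: pd.DataFrame  # genes x samples
    gene_models: List[GeneModel]
    gene_sets: Dict[str, List[str]]
    truth: SyntheticTruth

    @property
    def normals(self) -> List[Methylome]:
        return [m for m in self.methylomes if m.group == "normal"]

    @property
    def tumors(self) -> List[Methylome]:
        return [m for m in self.methylomes if m.group == "tumor"]


def _geometric_positions(rng, start: int, end: int, mean_gap: float) -> np.ndarray:
    if end <= start:
        return np.empty(0, dtype=np.int64)
    n_expect = int((end - start) / mean_gap * 1.6) + 8
    gaps = rng.geometric(1.0 / mean_gap, size=n_expect)
    pos = start + np.cumsum(gaps)
    pos = pos[pos < end]
    while len(pos) and pos[-1] < end - 4 * mean_gap:
        extra = pos[-1] + np.cumsum(rng.geometric(1.0 / mean_gap, size=n_expect))
        pos = np.concatenate([pos, extra[extra < end]])
    return pos.astype(np.int64)


def _layout(cfg: SimConfig, rng) -> Tuple[List[PlantedRegion], List[GeneModel], pd.DataFrame, int]:
    """Place planted elements left to right with random gaps and build the
    gene models anchored on them."""
    n_hyper_c = int(round(cfg.frac_hyper_canyon * cfg.n_canyons))
    n_hypo_c = int(round(cfg.frac_hypo_canyon * cfg.n_canyons))
    n_hyper_u = int(round(cfg.frac_hyper_cumr * cfg.n_cumrs))
    n_hypo_u = int(round(cfg.frac_hypo_cumr * cfg.n_cumrs))
    lo_mean = cfg.alpha_lo / (cfg.alpha_lo + cfg.beta_lo)

    elements: List[Tuple[str, str]] = []
    elements += [("canyon", "hyper")] * n_hyper_c
    elements += [("canyon", "hypo")] * n_hypo_c
    elements += [("canyon", "none")] * (cfg.n_canyons - n_hyper_c - n_hypo_c)
    elements += [("cumr", "hyper")] * n_hyper_u
    elements += [("cumr", "hypo")] * n_hypo_u
    elements += [("cumr", "none")] * (cfg.n_cumrs - n_hyper_u - n_hypo_u)
    elements += [("unstable", "none")] * cfg.n_unstable
    elements += [("promoter_block", "hyper")] * cfg.n_promoter_genes
    elements += [("background_gene", "none")] * cfg.n_background_genes
    order = rng.permutation(len(elements))
    elements = [elements[i] for i in order]

    regions: List[PlantedRegion] = []
    genes: List[GeneModel] = []
    labels = []
    cursor = 3000
    gene_counter = 0
    n_high = max(1, int(round(cfg.unstable_high_frac * cfg.n_normals)))
    for kind, effect in elements:
        cursor += int(rng.integers(cfg.gap_len[0], cfg.gap_len[1]))
        if kind in ("canyon", "cumr"):
            lo, hi = cfg.canyon_len if kind == "canyon" else cfg.cumr_len
            length = int(rng.integers(lo, hi))
            reg = Region(cfg.chrom, cursor, cursor + length)
            if effect == "hyper":
                nm, tm = lo_mean, cfg.body_hyper_mean
            elif effect == "hypo":
                nm, tm = cfg.hypo_normal_mean, lo_mean
            else:
                nm, tm = lo_mean, lo_mean
            gene_id = None
            if kind == "canyon":
                gene_id = f"CG{gene_counter:04d}"
                gene_counter += 1
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "+":
                    g = GeneModel.from_interval(
                        gene_id, cfg.chrom, reg.start - 600, reg.end + 100, strand
                    )
                else:
                    g = GeneModel.from_interval(
                        gene_id, cfg.chrom, reg.start - 100, reg.end + 600, strand
                    )
                genes.append(g)
                labels.append((gene_id, "canyon_body", effect))
            regions.append(PlantedRegion(reg, kind, effect, nm, tm, gene_id))
            cursor = reg.end + (1700 if kind == "canyon" else 0)
        elif kind == "unstable":
            length = int(rng.integers(cfg.unstable_len[0], cfg.unstable_len[1]))
            reg = Region(cfg.chrom, cursor, cursor + length)
            high = tuple(
                sorted(rng.choice(cfg.n_normals, size=n_high, replace=False))
            )
            regions.append(
                PlantedRegion(
                    reg,
                    "unstable",
                    "none",
                    lo_mean,
                    cfg.unstable_high_mean,
                    high_normals=high,
                )
            )
            cursor = reg.end
        elif kind == "promoter_block":
            gene_id = f"PG{gene_counter:04d}"
            gene_counter += 1
            strand = "+" if rng.random() < 0.5 else "-"
            body_len = int(rng.integers(2500, 4000))
            if strand == "+":
                tss = cursor + 1000
                g = GeneModel.from_interval(
                    gene_id, cfg.chrom, tss, tss + 500 + body_len, strand
                )
            else:
                tss = cursor + 500 + body_len
                g = GeneModel.from_interval(
                    gene_id, cfg.chrom, tss - 500 - body_len, tss, strand
                )
            genes.append(g)
            labels.append((gene_id, "promoter_silenced", "hyper"))
            reg = g.promoter
            regions.append(
                PlantedRegion(
                    reg, "promoter_block", "hyper", lo_mean, cfg.promoter_hyper_mean, gene_id
                )
            )
            cursor = max(g.tss, g.tts)
        else:  # background_gene
            gene_id = f"BG{gene_counter:04d}"
            gene_counter += 1
            strand = "+" if rng.random() < 0.5 else "-"
            body_len = int(rng.integers(2500, 4000))
            g = GeneModel.from_interval(
                gene_id, cfg.chrom, cursor, cursor + 500 + body_len, strand
            )
            genes.append(g)
            labels.append((gene_id, "background", "none"))
            cursor += 500 + body_len
    chrom_len = cursor + 5000
    gene_labels = pd.DataFrame(labels, columns=["gene_id", "role", "effect"])
    return regions, genes, gene_labels, chrom_len


def _cpg_positions(cfg: SimConfig, rng, regions: Sequence[PlantedRegion], chrom_len: int) -> np.ndarray:
    dense = sorted((r.region.start, r.region.end) for r in regions)
    parts = []
    prev = 0
    dense_gap = cfg.bg_cpg_gap / cfg.densify_factor
    for s, e in dense:
        parts.append(_geometric_positions(rng, prev, s, cfg.bg_cpg_gap))
        parts.append(_geometric_positions(rng, s, e, dense_gap))
        prev = e
    parts.append(_geometric_positions(rng, prev, chrom_len, cfg.bg_cpg_gap))
    pos = np.unique(np.concatenate(parts))
    return pos


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Generate a full cohort (methylomes, expression, genes, sets, truth).

    The same seed always yields byte-identical output.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    regions, genes, gene_labels, chrom_len = _layout(cfg, rng)
    pos = _cpg_positions(cfg, rng, regions, chrom_len)
    n_cpg = len(pos)

    # per-CpG latent mean/concentration per group, as arrays
    mean_n = np.full(n_cpg, cfg.alpha_bg / (cfg.alpha_bg + cfg.beta_bg))
    mean_t = mean_n.copy()
    conc_n = np.full(n_cpg, cfg.alpha_bg + cfg.beta_bg)
    conc_t = conc_n.copy()
    lo_conc = cfg.alpha_lo + cfg.beta_lo
    region_slices: List[Tuple[PlantedRegion, slice]] = []
    for pr in regions:
        i0 = np.searchsorted(pos, pr.region.start, side="left")
        i1 = np.searchsorted(pos, pr.region.end, side="left")
        sl = slice(i0, i1)
        region_slices.append((pr, sl))
        mean_n[sl] = pr.normal_mean
        mean_t[sl] = pr.tumor_mean
        conc_n[sl] = lo_conc if pr.normal_mean < 0.10 else cfg.concentration
        conc_t[sl] = lo_conc if pr.tumor_mean < 0.10 else cfg.concentration

    # decoy sites live in the methylated background (outside planted regions)
    # and must hold enough CpGs to be callable when a sample activates them
    decoy_sites: List[Region] = []
    placeable = chrom_len - cfg.decoy_len - 2000
    cand = np.sort(rng.integers(1000, placeable, size=cfg.n_decoy_sites * 3))
    planted_iv = sorted((r.region.start, r.region.end) for r in regions)
    pl_starts = np.array([s for s, _ in planted_iv], dtype=np.int64)
    pl_ends = np.array([e for _, e in planted_iv], dtype=np.int64)
    for s in cand:
        e = int(s) + cfg.decoy_len
        j = int(np.searchsorted(pl_ends, s, side="right"))
        if j < len(pl_starts) and pl_starts[j] < e:
            continue  # overlaps a planted region
        i0 = np.searchsorted(pos, s, side="left")
        i1 = np.searchsorted(pos, e, side="left")
        if i1 - i0 < 5:
            continue  # too few CpGs to ever be called
        decoy_sites.append(Region(cfg.chrom, int(s), e))
        if len(decoy_sites) == cfg.n_decoy_sites:
            break
    decoy_idx = [
        (
            np.searchsorted(pos, r.start, side="left"),
            np.searchsorted(pos, r.end, side="left"),
        )
        for r in decoy_sites
    ]

    sample_ids = [f"N{i:02d}" for i in range(cfg.n_normals)] + [
        f"T{i:02d}" for i in range(cfg.n_tumors)
    ]
    groups = ["normal"] * cfg.n_normals + ["tumor"] * cfg.n_tumors
    type_labels = [None] * cfg.n_normals + [
        f"TT{i % cfg.n_tumor_types}" for i in range(cfg.n_tumors)
    ]

    methylomes: List[Methylome] = []
    decoy_active: Dict[str, List[int]] = {}
    body_meth = pd.DataFrame(index=[g.gene_id for g in genes], columns=sample_ids, dtype=float)
    prom_meth = body_meth.copy()

    gene_regions = {g.gene_id: (g.genebody, g.promoter) for g in genes}

    for si, sid in enumerate(sample_ids):
        group = groups[si]
        mean = (mean_n if group == "normal" else mean_t).copy()
        conc = (conc_n if group == "normal" else conc_t).copy()
        if group == "normal":
            for pr, sl in region_slices:
                if pr.kind == "unstable" and si in pr.high_normals:
                    mean[sl] = pr.tumor_mean  # methylated in this normal
                    conc[sl] = cfg.concentration
        # sample-specific decoy UMRs
        active = list(np.flatnonzero(rng.random(len(decoy_sites)) < cfg.decoy_rate))
        decoy_active[sid] = [int(i) for i in active]
        for i in active:
            i0, i1 = decoy_idx[i]
            mean[i0:i1] = cfg.alpha_lo / (cfg.alpha_lo + cfg.beta_lo)
            conc[i0:i1] = lo_conc
        latent = rng.beta(mean * conc, (1.0 - mean) * conc)
        coverage = rng.poisson(
            rng.gamma(
                cfg.coverage_dispersion, cfg.coverage_mean / cfg.coverage_dispersion, n_cpg
            )
        )
        coverage = np.maximum(coverage, 1)
        meth_reads = rng.binomial(coverage, latent)
        ratio = meth_reads / coverage
        keep = coverage >= cfg.min_coverage
        df = pd.DataFrame(
            {
                "chrom": cfg.chrom,
                "pos": pos[keep],
                "meth_ratio": ratio[keep],
                "coverage": coverage[keep],
            }
        )
        m = Methylome(sid, df, group=group, tumor_type=type_labels[si])
        methylomes.append(m)
        for gid, (body, prom) in gene_regions.items():
            body_meth.loc[gid, sid] = m.region_mean(body)
            prom_meth.loc[gid, sid] = m.region_mean(prom)

    # expression: log2-scale baseline + methylation coupling + noise
    gene_ids = [g.gene_id for g in genes]
    baseline = rng.normal(cfg.expr_baseline_mean, cfg.expr_baseline_sd, len(gene_ids))
    role = gene_labels.set_index("gene_id")["role"]
    log2e = np.tile(baseline[:, None], (1, len(sample_ids))).astype(float)
    bm = body_meth.fillna(0.0).to_numpy()
    pm = prom_meth.fillna(0.0).to_numpy()
    for gi, gid in enumerate(gene_ids):
        if role.loc[gid] == "canyon_body":
            log2e[gi] += cfg.body_coupling_slope * bm[gi]
        elif role.loc[gid] == "promoter_silenced":
            log2e[gi] -= cfg.promoter_coupling_slope * pm[gi]
    log2e += rng.normal(0.0, cfg.expr_noise_sd, log2e.shape)
    expression = pd.DataFrame(
        np.power(2.0, log2e), index=gene_ids, columns=sample_ids
    )

    # gene sets: a homeobox-like set planted preferentially in hyper canyons
    hyper_canyon_genes = [
        pr.gene_id for pr in regions if pr.kind == "canyon" and pr.effect == "hyper"
    ]
    other_genes = [g for g in gene_ids if g not in hyper_canyon_genes]
    n_core = max(1, int(round(0.7 * len(hyper_canyon_genes))))
    homeobox = list(hyper_canyon_genes[:n_core]) + [
        other_genes[i]
        for i in rng.choice(len(other_genes), size=5, replace=False)
    ]
    oncogene = list(hyper_canyon_genes[: max(1, n_core // 2)]) + [
        other_genes[i]
        for i in rng.choice(len(other_genes), size=8, replace=False)
    ]
    tsg = [
        gene_ids[i] for i in rng.choice(len(gene_ids), size=10, replace=False)
    ]
    gene_sets = {
        "homeobox_like": sorted(set(homeobox)),
        "oncogene_like": sorted(set(oncogene)),
        "tsg_like": sorted(set(tsg)),
    }

    truth = SyntheticTruth(
        config=cfg,
        chrom_len=chrom_len,
        regions=regions,
        decoy_sites=decoy_sites,
        decoy_active=decoy_active,
        gene_labels=gene_labels,
        gene_sets=gene_sets,
    )
    return SimCohort(
        methylomes=methylomes,
        expression=expression,
        gene_models=genes,
        gene_sets=gene_sets,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# recovery scoring


def _mask(regions: Sequence[Region], chrom_len: int) -> np.ndarray:
    mask = np.zeros(chrom_len, dtype=bool)
    for r in regions:
        mask[r.start : min(r.end, chrom_len)] = True
    return mask


def base_level_metrics(
    truth_regions: Sequence[Region], called_regions: Sequence[Region], chrom_len: int
) -> Dict[str, float]:
    """Base-level precision/recall of calls against truth on one chromosome."""
    t = _mask([r.region if hasattr(r, "region") else r for r in truth_regions], chrom_len)
    c = _mask([r.region if hasattr(r, "region") else r for r in called_regions], chrom_len)
    tp = int((t & c).sum())
    fp = int((~t & c).sum())
    fn = int((t & ~c).sum())
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return {"precision": precision, "recall": recall, "tp": tp, "fp": fp, "fn": fn}


def region_level_metrics(
    truth_regions: Sequence[Region],
    called_regions: Sequence[Region],
    min_overlap: float = 0.5,
) -> Dict[str, float]:
    """Region-level precision/recall/F1.

    A truth region is recovered when calls cover >= ``min_overlap`` of its
    bases; a call is a true positive when truth covers >= ``min_overlap`` of
    it."""
    truth = [r.region if hasattr(r, "region") else r for r in truth_regions]
    called = [r.region if hasattr(r, "region") else r for r in called_regions]

    def covered_frac(target: Region, others: Sequence[Region]) -> float:
        cov = 0
        for o in others:
            if o.chrom != target.chrom:
                continue
            cov += max(0, min(o.end, target.end) - max(o.start, target.start))
        return cov / target.length

    recovered = sum(1 for t in truth if covered_frac(t, called) >= min_overlap)
    true_calls = sum(1 for c in called if covered_frac(c, truth) >= min_overlap)
    recall = recovered / len(truth) if truth else float("nan")
    precision = true_calls / len(called) if called else float("nan")
    if precision != precision or recall != recall or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "n_truth": len(truth),
        "n_called": len(called),
    }


def truth_report(
    truth: SyntheticTruth,
    called: Dict[str, Sequence[Region]],
    kinds_by_category: Optional[Dict[str, Tuple[Sequence[str], Sequence[str]]]] = None,
) -> pd.DataFrame:
    """Precision/recall table per called category against the planted truth.

    ``called`` maps category name -> called regions. ``kinds_by_category``
    maps category name -> (kinds, effects) selecting the matching truth;
    default categories cover the DM classes.
    """
    if kinds_by_category is None:
        kinds_by_category = {
            "hyper-canyon": (("canyon",), ("hyper",)),
            "hypo-canyon": (("canyon",), ("hypo",)),
            "hyper-cUMR": (("cumr", "promoter_block"), ("hyper",)),
            "hypo-cUMR": (("cumr",), ("hypo",)),
        }
    rows = []
    for cat, regs in called.items():
        kinds, effects = kinds_by_category.get(cat, (None, None))
        planted = truth.planted_regions(kinds, effects)
        base = base_level_metrics(
            [p.region for p in planted], regs, truth.chrom_len
        )
        reg = region_level_metrics([p.region for p in planted], regs)
        rows.append(
            {
                "category": cat,
                "base_precision": base["precision"],
                "base_recall": base["recall"],
                "region_precision": reg["precision"],
                "region_recall": reg["recall"],
                "region_f1": reg["f1"],
                "n_truth": reg["n_truth"],
                "n_called": reg["n_called"],
            }
        )
    return pd.DataFrame(rows)
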