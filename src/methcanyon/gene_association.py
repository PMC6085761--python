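"""Gene association, differential-expression filter, and gene-set enrichment.

A UMR is associated with every gene whose promoter or gene body it overlaps
by at least one base; hypermethylated canyons often cover entire gene bodies,
so the containment flag is tracked explicitly. Differential expression uses a
rank-sum test with BH adjustment plus a fold-change filter (> 2 on
pseudocounted group means); gene-set enrichment uses the two-sided Fisher
exact test on the category x set contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GeneModel, Region


@dataclass
class GeneAnnotation:
    gene_id: str
    umrs: List = field(default_factory=list)  # associated Region-like items
    promoter_overlap: bool = False
    genebody_overlap: bool = False
    covers_entire_genebody: bool = False


@dataclass
class EnrichmentResult:
    gene_set: str
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    odds_ratio: float
    p_value: float


def _region_of(item) -> Region:
    return item.region if hasattr(item, "region") else item


def associate_umrs_to_genes(
    umrs: Sequence, gene_models: Sequence[GeneModel]
) -> List[GeneAnnotation]:
    """Associate each UMR with every gene whose promoter or gene body it
    overlaps (>= 1 bp). Returns one annotation per gene that has at least
    one associated UMR."""
    annos: Dict[str, GeneAnnotation] = {}
    by_chrom: Dict[str, List] = {}
    for u in umrs:
        by_chrom.setdefault(_region_of(u).chrom, []).append(u)
    for g in gene_models:
        for u in by_chrom.get(g.chrom, []):
            r = _region_of(u)
            prom = r.overlaps(g.promoter)
            body = r.overlaps(g.genebody)
            if not (prom or body):
                continue
            a = annos.setdefault(g.gene_id, GeneAnnotation(gene_id=g.gene_id))
            a.umrs.append(u)
            a.promoter_overlap |= prom
            a.genebody_overlap |= body
            a.covers_entire_genebody |= r.contains(g.genebody)
    return [annos[g.gene_id] for g in gene_models if g.gene_id in annos]


def de_filter(
    expression: pd.DataFrame,
    normal_ids: Sequence[str],
    tumor_ids: Sequence[str],
    fdr_cut: float = 0.01,
    fc_cut: float = 2.0,
    pseudocount: float = 1.0,
) -> Tuple[List[str], List[str], pd.DataFrame]:
    """Differential-expression filter: rank-sum p (BH adjusted) < ``fdr_cut``
    and fold change of pseudocounted group means > ``fc_cut``.

    Returns (up_genes, down_genes, per-gene table). Fold change is
    (mean_tumor + c) / (mean_normal + c); a gene passes on max(FC, 1/FC).
    """
    if len(normal_ids) < 3 or len(tumor_ids) < 3:
        raise ValueError("need at least 3 samples per group")
    nx = expression[list(normal_ids)].to_numpy(dtype=float)
    tx = expression[list(tumor_ids)].to_numpy(dtype=float)
    if np.all(nx == nx[:, :1], axis=None) and np.all(tx == tx[:, :1], axis=None):
        raise ValueError("degenerate expression matrix: all values constant")
    fc = (tx.mean(axis=1) + pseudocount) / (nx.mean(axis=1) + pseudocount)
    stat, p = stats.mannwhitneyu(tx, nx, axis=1, alternative="two-sided")
    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "fold_change": fc,
            "p_value": p,
            "fdr": fdr,
        },
        index=expression.index,
    )
    effect = np.maximum(fc, 1.0 / fc) > fc_cut
    de = (fdr < fdr_cut) & effect
    table["de"] = de
    table["direction"] = np.where(~de, "none", np.where(fc > 1, "up", "down"))
    up = list(table.index[(table["direction"] == "up")])
    down = list(table.index[(table["direction"] == "down")])
    return up, down, table


def fisher_enrichment(
    category_genes: Sequence[str],
    gene_set: Sequence[str],
    background_genes: Sequence[str],
    set_name: str = "gene_set",
) -> EnrichmentResult:
    """Two-sided Fisher exact test of gene-set membership within a category
    against the background universe."""
    bg: Set[str] = set(background_genes)
    if not bg:
        raise ValueError("empty background")
    cat = set(category_genes) & bg
    gs = set(gene_set) & bg
    a = len(cat & gs)
    b = len(cat - gs)
    c = len(gs - cat)
    d = len(bg - cat - gs)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(
        gene_set=set_name,
        table=((a, b), (c, d)),
        odds_ratio=float(odds),
        p_value=float(p),
    )
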