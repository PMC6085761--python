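"""Metagene binning and per-bin methylation-expression correlation.

Every gene is rescaled to a common 70-bin frame in gene orientation: bins
1-10 are the fixed 1-kb upstream flank (100 bp per bin, immediately 5' of
the gene body, so they cover the promoter core around the TSS), bins 11-60
divide the gene body into 50 equal genomic fractions (exactly 100 bp each
when the body is 5 kb), and bins 61-70 are the fixed 1-kb downstream flank.
Minus-strand genes are reversed so bin 1 is always 5'-most.

Per-bin Spearman rank correlation is computed across a gene set, either
between a single sample's expression and methylation, or between
tumor-vs-normal expression fold changes and methylation differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, Methylome

N_BINS = 70
N_BODY_BINS = 50
N_FLANK_BINS = 10
FLANK_BIN_BP = 100
EXACT_PERM_MAX_N = 8
DEFAULT_MIN_GENES = 10


@dataclass
class MetageneProfile:
    gene_id: str
    values: np.ndarray  # length 70, NaN where a bin holds no CpG


@dataclass
class BinCorrelation:
    rho: np.ndarray  # length 70, NaN where < min_n genes
    p_value: np.ndarray
    n_genes: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        role = (
            ["upstream_flank"] * N_FLANK_BINS
            + ["gene_body"] * N_BODY_BINS
            + ["downstream_flank"] * N_FLANK_BINS
        )
        return pd.DataFrame(
            {
                "bin": np.arange(1, N_BINS + 1),
                "role": role,
                "rho": self.rho,
                "p_value": self.p_value,
                "n_genes": self.n_genes,
            }
        )


def bin_edges(gene: GeneModel) -> np.ndarray:
    """Genomic edges of the 70 bins in gene orientation (length 71).

    Edges tile flank + body + flank with no gaps or overlaps; for minus-
    strand genes the edges run right-to-left (descending coordinates).
    """
    body = gene.genebody
    length = body.length
    if length < N_BODY_BINS:
        raise ValueError(
            f"gene {gene.gene_id}: body of {length} bp is shorter than "
            f"{N_BODY_BINS} bp (one bp per body bin)"
        )
    body_edges = body.start + (
        np.arange(N_BODY_BINS + 1) * length
    ) // N_BODY_BINS
    up = body.start - FLANK_BIN_BP * np.arange(N_FLANK_BINS, 0, -1)
    down = body.end + FLANK_BIN_BP * np.arange(1, N_FLANK_BINS + 1)
    edges = np.concatenate([up, body_edges, down]).astype(np.int64)
    if gene.strand == "-":
        edges = edges[::-1]
    return edges


def binned_methylation(methylome: Methylome, gene: GeneModel) -> MetageneProfile:
    """Mean methylation ratio of the CpGs falling in each of the 70 bins."""
    edges = bin_edges(gene)
    lo, hi = int(edges.min()), int(edges.max())
    values = np.full(N_BINS, np.nan)
    arrs = methylome.chrom_arrays(gene.chrom)
    if arrs is not None:
        pos, ratio, _, _ = arrs
        i0 = np.searchsorted(pos, lo, side="left")
        i1 = np.searchsorted(pos, hi, side="left")
        p = pos[i0:i1]
        r = ratio[i0:i1]
        if gene.strand == "+":
            which = np.searchsorted(edges, p, side="right") - 1
        else:
            # descending edges: bin b covers [edges[b+1], edges[b])
            which = N_BINS - np.searchsorted(edges[::-1], p, side="right")
        for b in range(N_BINS):
            m = which == b
            if m.any():
                values[b] = float(np.mean(r[m]))
    return MetageneProfile(gene_id=gene.gene_id, values=values)


def _exact_perm_p(xr: np.ndarray, yr: np.ndarray, rho: float) -> float:
    n = len(xr)
    count = 0
    total = 0
    sx = np.std(xr)
    sy = np.std(yr)
    xc = (xr - xr.mean()) / sx
    yc = (yr - yr.mean()) / sy
    target = abs(rho) - 1e-12
    for perm in permutations(range(n)):
        r = float(np.dot(xc, yc[list(perm)])) / n
        total += 1
        if abs(r) >= target:
            count += 1
    return count / total


def spearman(x: Sequence[float], y: Sequence[float]):
    """Spearman rank correlation with average ranks for ties.

    Missing pairs are dropped pairwise; at least 3 pairs are required. The
    p-value uses exhaustive permutation enumeration for n <= 8 and the
    t-approximation otherwise. Constant input yields (nan, nan).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    m = ~(np.isnan(x) | np.isnan(y))
    x, y = x[m], y[m]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 non-missing pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    rho = float(np.corrcoef(xr, yr)[0, 1])
    if n <= EXACT_PERM_MAX_N:
        p = _exact_perm_p(xr, yr, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p


def _per_bin_correlation(
    profiles: Dict[str, np.ndarray], response: Dict[str, float], min_n: int
) -> BinCorrelation:
    genes = [g for g in profiles if g in response and not np.isnan(response[g])]
    if len(genes) < min_n:
        raise ValueError(f"only {len(genes)} genes shared; need >= {min_n}")
    meth = np.vstack([profiles[g] for g in genes])
    resp = np.array([response[g] for g in genes])
    rho = np.full(N_BINS, np.nan)
    pv = np.full(N_BINS, np.nan)
    ng = np.zeros(N_BINS, dtype=int)
    for b in range(N_BINS):
        col = meth[:, b]
        ok = ~np.isnan(col)
        ng[b] = int(ok.sum())
        if ng[b] < max(min_n, 3):
            continue
        if np.all(col[ok] == col[ok][0]) or np.all(resp[ok] == resp[ok][0]):
            continue
        rho[b], pv[b] = spearman(col[ok], resp[ok])
    return BinCorrelation(rho=rho, p_value=pv, n_genes=ng)


def bin_correlation_single(
    methylome: Methylome,
    expression: Dict[str, float],
    genes: Sequence[GeneModel],
    min_n: int = DEFAULT_MIN_GENES,
) -> BinCorrelation:
    """Per-bin Spearman correlation, across genes, between one sample's
    expression and its binned methylation."""
    profiles = {g.gene_id: binned_methylation(methylome, g).values for g in genes}
    return _per_bin_correlation(profiles, dict(expression), min_n)


def bin_correlation_change(
    tumor_methylome: Methylome,
    normal_methylome: Methylome,
    tumor_expr: Dict[str, float],
    normal_expr: Dict[str, float],
    genes: Sequence[GeneModel],
    min_n: int = DEFAULT_MIN_GENES,
    pseudocount: float = 1.0,
) -> BinCorrelation:
    """Per-bin Spearman correlation between tumor-vs-normal expression fold
    changes and signed methylation differences (tumor - normal)."""
    fc: Dict[str, float] = {}
    for g in genes:
        te = tumor_expr.get(g.gene_id)
        ne = normal_expr.get(g.gene_id)
        if te is None or ne is None:
            continue
        fc[g.gene_id] = (te + pseudocount) / (ne + pseudocount)
    profiles = {}
    for g in genes:
        t = binned_methylation(tumor_methylome, g).values
        n = binned_methylation(normal_methylome, g).values
        profiles[g.gene_id] = t - n
    return _per_bin_correlation(profiles, fc, min_n)
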