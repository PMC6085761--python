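"""Population reference-UMR atlas.

Per-sample UMR calls are merged into a genome-wide union, the union is split
at every sample's UMR boundary into atomic segments of constant occupancy
count k, and the UMR occupancy frequency UOF(s) = k / N is computed per
segment. Segments significantly enriched over a Poisson background (the
ChIP-seq peak-calling analogy: lambda defaults to the mean occupancy count
over all atomic segments) are called reference UMRs after Benjamini-Hochberg
adjustment; adjacent passing segments are merged. Reference UMRs longer than
3.5 kb are methylation canyons, the rest control cUMRs.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ReferenceUMR, Region, UOFSegment

DEFAULT_P_CUTOFF = 1.0e-8


def _regions_of(items) -> List[Region]:
    return [it.region if hasattr(it, "region") else it for it in items]


def merge_umrs(umr_sets: Sequence[Sequence]) -> List[Region]:
    """Union of all samples' UMR intervals; overlapping or book-ended
    intervals are merged. Output sorted and disjoint."""
    regions: List[Region] = []
    for s in umr_sets:
        regions.extend(_regions_of(s))
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    merged: List[Region] = []
    for r in regions:
        if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end:
            last = merged[-1]
            if r.end > last.end:
                merged[-1] = Region(last.chrom, last.start, r.end)
        else:
            merged.append(r)
    return merged


def atomic_segments(umr_sets: Sequence[Sequence]) -> List[UOFSegment]:
    """Split the merged union at every UMR breakpoint from any sample so the
    occupancy count k is constant within each segment; UOF = k / N."""
    n = len(umr_sets)
    if n < 1:
        raise ValueError("need at least one sample")
    by_chrom: dict = {}
    for s in umr_sets:
        for r in _regions_of(s):
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    out: List[UOFSegment] = []
    for chrom in sorted(by_chrom):
        iv = np.array(by_chrom[chrom], dtype=np.int64)
        points = np.unique(iv)  # all breakpoints
        starts = np.sort(iv[:, 0])
        ends = np.sort(iv[:, 1])
        # occupancy on [points[i], points[i+1]) = #starts <= p minus #ends <= p
        k = np.searchsorted(starts, points[:-1], side="right") - np.searchsorted(
            ends, points[:-1], side="right"
        )
        for i in np.flatnonzero(k > 0):
            out.append(
                UOFSegment(
                    region=Region(chrom, int(points[i]), int(points[i + 1])),
                    k=int(k[i]),
                    n_samples=n,
                )
            )
    return out


def call_reference_umrs(
    segments: Sequence[UOFSegment],
    p_cutoff: float = DEFAULT_P_CUTOFF,
    lam: Optional[float] = None,
    merge_gap: int = 0,
) -> List[ReferenceUMR]:
    """Call reference UMRs from the occupancy profile.

    Per segment, the upper-tail Poisson p-value P(X >= k | lambda) is computed
    against the background rate ``lam`` (default: mean k over all atomic
    segments), BH-adjusted over all segments; segments with adjusted p below
    ``p_cutoff`` are kept and passing segments separated by at most
    ``merge_gap`` bp (default 0: book-ended) are merged. A merged region's k
    is the occupancy count with the largest base coverage among its segments
    (ties break to the larger k); its p/fdr are the minima.
    """
    if len(segments) == 0:
        raise ValueError("no segments")
    if len(segments) < 2:
        raise ValueError("need at least two segments to estimate background")
    k = np.array([s.k for s in segments], dtype=float)
    if lam is None:
        lam = float(np.mean(k))
    pvals = stats.poisson.sf(k - 1, lam)  # P(X >= k)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    n = segments[0].n_samples
    passing = [
        (s, float(p), float(q))
        for s, p, q in zip(segments, pvals, fdr)
        if q < p_cutoff
    ]
    passing.sort(key=lambda t: (t[0].region.chrom, t[0].region.start))
    out: List[ReferenceUMR] = []
    cluster: List[tuple] = []

    def _flush():
        if not cluster:
            return
        chrom = cluster[0][0].region.chrom
        start = cluster[0][0].region.start
        end = max(s.region.end for s, _, _ in cluster)
        weights: dict = {}
        for s, _, _ in cluster:
            weights[s.k] = weights.get(s.k, 0) + s.region.length
        best_k = max(weights, key=lambda kk: (weights[kk], kk))
        out.append(
            ReferenceUMR(
                region=Region(chrom, start, end),
                k=best_k,
                n_samples=n,
                poisson_p=min(p for _, p, _ in cluster),
                fdr=min(q for _, _, q in cluster),
            )
        )
        cluster.clear()

    for s, p, q in passing:
        if cluster and (
            s.region.chrom != cluster[-1][0].region.chrom
            or s.region.start - cluster[-1][0].region.end > merge_gap
        ):
            _flush()
        cluster.append((s, p, q))
    _flush()
    return out


def combine_normal_tumor_atlases(
    ref_normal: Sequence[ReferenceUMR], ref_tumor: Sequence[ReferenceUMR]
) -> List[ReferenceUMR]:
    """Interval union of the normal and tumor reference atlases; the
    canyon/cUMR class is re-derived from the merged length. Occupancy
    bookkeeping keeps the maximum k/uof and minimum p/fdr of the merged
    members."""
    items = list(ref_normal) + list(ref_tumor)
    items.sort(key=lambda r: (r.region.chrom, r.region.start, r.region.end))
    out: List[ReferenceUMR] = []
    for it in items:
        if (
            out
            and out[-1].region.chrom == it.region.chrom
            and it.region.start <= out[-1].region.end
        ):
            prev = out[-1]
            out[-1] = ReferenceUMR(
                region=Region(
                    prev.region.chrom,
                    prev.region.start,
                    max(prev.region.end, it.region.end),
                ),
                k=max(prev.k, it.k),
                n_samples=max(prev.n_samples, it.n_samples),
                poisson_p=min(prev.poisson_p, it.poisson_p),
                fdr=min(prev.fdr, it.fdr),
            )
        else:
            out.append(
                ReferenceUMR(
                    region=it.region,
                    k=it.k,
                    n_samples=it.n_samples,
                    poisson_p=it.poisson_p,
                    fdr=it.fdr,
                )
            )
    return out
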