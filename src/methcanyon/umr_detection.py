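"""Single-sample under-methylated region (UMR) segmentation.

A UMR is a run of at least ``min_cpgs`` consecutive CpGs, each with an
observed methylation ratio below a per-CpG cap, whose mean methylation ratio
is below ``max_mean`` (default 10%). Runs are broken where adjacent CpGs are
farther apart than ``max_gap``, so calls never span CpG deserts with no data.
The emitted region runs from the first CpG to the last CpG + 2, covering the
terminal dinucleotide in half-open coordinates.

Candidate runs whose overall mean fails ``max_mean`` (possible only when
``cpg_threshold > max_mean``) are resolved by a deterministic peak trim: the
highest-ratio CpG (leftmost on ties) is removed, the run splits there, and
both halves are re-examined. When ``cpg_threshold <= max_mean`` every
candidate run already satisfies the mean bound, and the output is exactly the
set of maximal qualifying runs.

Calls may optionally be filtered by the CpG observed/expected ratio of their
sequence (the CpG-island composition statistic), removing calls in
CpG-depleted sequence where segmentation from sparse data is unreliable.
"""

from __future__ import annotations

import warnings
from typing import List, Mapping, Optional, Sequence, Union

import numpy as np

from .core import Methylome, Region, UMR

GenomeLike = Union[Mapping[str, str], object]  # dict of sequences or pyfaidx.Fasta


def detect_umrs(
    methylome: Methylome,
    min_cpgs: int = 4,
    max_mean: float = 0.10,
    cpg_threshold: float = 0.10,
    max_gap: int = 1000,
) -> List[UMR]:
    """Segment one methylome into UMRs.

    Parameters
    ----------
    methylome
        Sorted per-sample CpG profile.
    min_cpgs
        Minimum CpGs per call (default 4).
    max_mean
        Upper bound (strict) on the run mean methylation ratio.
    cpg_threshold
        Per-CpG cap (strict); CpGs at or above it terminate runs.
    max_gap
        Maximum distance in bp between adjacent CpGs within one run.
    """
    if min_cpgs < 1 or max_mean <= 0 or cpg_threshold <= 0 or max_gap <= 0:
        raise ValueError("detection parameters must be positive")
    out: List[UMR] = []
    for chrom in methylome.chroms:
        pos, ratio, _, _ = methylome.chrom_arrays(chrom)
        ok = ratio < cpg_threshold
        if not ok.any():
            continue
        # candidate run boundaries: per-CpG failures and over-long gaps
        breaks = np.zeros(len(pos) + 1, dtype=bool)
        breaks[0] = breaks[-1] = True
        breaks[1:-1] = (~ok[:-1]) | (~ok[1:]) | (np.diff(pos) > max_gap)
        idx = np.flatnonzero(breaks)
        for a, b in zip(idx[:-1], idx[1:]):
            if not ok[a]:
                continue
            _emit_run(pos, ratio, int(a), int(b), min_cpgs, max_mean, chrom,
                      methylome.sample_id, out)
    out.sort(key=lambda u: (u.region.chrom, u.region.start))
    return out


def _emit_run(pos, ratio, i, j, min_cpgs, max_mean, chrom, sample_id, out):
    """Emit runs within [i, j) satisfying the mean bound, peak-trimming if not."""
    stack = [(i, j)]
    while stack:
        a, b = stack.pop()
        n = b - a
        if n < min_cpgs:
            continue
        m = float(np.mean(ratio[a:b]))
        if m < max_mean:
            out.append(
                UMR(
                    region=Region(chrom, int(pos[a]), int(pos[b - 1]) + 2),
                    n_cpg=n,
                    mean_meth=m,
                    sample_id=sample_id,
                )
            )
        else:
            peak = a + int(np.argmax(ratio[a:b]))
            stack.append((a, peak))
            stack.append((peak + 1, b))


def _fetch(genome: GenomeLike, region: Region) -> str:
    seq = genome[region.chrom]
    if not isinstance(seq, str):
        try:
            n = len(seq)
        except TypeError:
            n = None
        if n is not None and region.end > n:
            raise IndexError(
                f"region {region.chrom}:{region.start}-{region.end} outside sequence"
            )
        seq = str(seq[region.start : region.end])
    else:
        if region.end > len(seq):
            raise IndexError(
                f"region {region.chrom}:{region.start}-{region.end} outside sequence"
            )
        seq = seq[region.start : region.end]
    return seq.upper()


def cpg_obs_exp(region: Region, genome: GenomeLike) -> Optional[float]:
    """CpG observed/expected ratio ``(N_CpG * L) / (N_C * N_G)`` of the +
    strand sequence of ``region`` (the classic CpG-island composition form).

    Returns None when the sequence has no C or no G (ratio undefined).
    """
    seq = _fetch(genome, region)
    length = len(seq)
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cpg = seq.count("CG")
    if n_c * n_g == 0:
        return None
    return n_cpg * length / (n_c * n_g)


def filter_umrs_by_obs_exp(
    umrs: Sequence[UMR],
    genome: Optional[GenomeLike],
    min_oe: float = 0.1,
) -> List[UMR]:
    """Drop UMRs whose CpG observed/expected ratio is below ``min_oe``
    (strict <; boundary values are kept). With no genome available the input
    is returned unchanged with a warning. The computed ratio is recorded on
    each retained UMR."""
    if genome is None:
        warnings.warn(
            "no genome sequence given; obs/exp filter disabled", stacklevel=2
        )
        return list(umrs)
    kept: List[UMR] = []
    for u in umrs:
        oe = cpg_obs_exp(u.region, genome)
        u.obs_exp = oe
        if oe is None or oe >= min_oe:
            kept.append(u)
    return kept
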