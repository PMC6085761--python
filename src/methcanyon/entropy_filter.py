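"""Shannon-entropy heterogeneity filter over the normal cohort.

For each reference UMR the per-normal-sample mean methylation vector is
turned into a probability vector (with a pseudocount) and its Shannon entropy
in bits is computed. A constant vector (the region behaves identically in
every normal) attains the maximum log2(N) bits; tissue-specific regions --
unmethylated in a few normals, methylated in the rest, or vice versa --
score low. Regions below the threshold (default log2(N) - 1 bits) are
removed before differential testing, mirroring the removal of high-frequency
germline variants from a disease cohort.

This is a deliberately plain normalized-entropy specificity score standing
in for QDMR's entropy variant: low entropy means sample-specific behaviour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import Methylome, Region

log = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.01


@dataclass
class EntropyScore:
    region: Region
    values: np.ndarray  # per-normal-sample mean methylation (NaN = no data)
    entropy_bits: float
    threshold_bits: float

    @property
    def is_heterogeneous(self) -> bool:
        return self.entropy_bits < self.threshold_bits


def region_mean_methylation(methylome: Methylome, region: Region) -> float:
    """Unweighted mean meth_ratio over CpGs inside the region; NaN if none."""
    return methylome.region_mean(region)


def region_mean_matrix(
    methylomes: Sequence[Methylome], regions: Sequence
) -> pd.DataFrame:
    """Regions x samples matrix of region mean methylation levels."""
    regs = [r.region if hasattr(r, "region") else r for r in regions]
    data = np.empty((len(regs), len(methylomes)))
    for j, m in enumerate(methylomes):
        for i, r in enumerate(regs):
            data[i, j] = m.region_mean(r)
    return pd.DataFrame(
        data,
        index=[f"{r.chrom}:{r.start}-{r.end}" for r in regs],
        columns=[m.sample_id for m in methylomes],
    )


def shannon_entropy(
    values: Sequence[float], pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """Entropy in bits of the normalized (value + pseudocount) vector.

    p_j = (x_j + eps) / sum_k (x_k + eps); H = -sum p_j log2 p_j. Maximal
    (log2 n) for constant vectors, low for sample-specific ones. Missing
    values are dropped; at least two non-missing values are required.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("all values missing")
    if v.size < 2:
        raise ValueError("need at least two non-missing values")
    if (v < 0).any():
        raise ValueError("methylation values must be nonnegative")
    p = (v + pseudocount) / np.sum(v + pseudocount)
    return float(-np.sum(p * np.log2(p)))


def entropy_scores(
    ref_umrs: Sequence,
    normal_methylomes: Sequence[Methylome],
    threshold_bits: Optional[float] = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> List[EntropyScore]:
    """Score every reference UMR across the normal cohort."""
    if len(normal_methylomes) < 2:
        raise ValueError("need at least two normal samples")
    if threshold_bits is None:
        threshold_bits = float(np.log2(len(normal_methylomes)) - 1.0)
    mat = region_mean_matrix(normal_methylomes, ref_umrs)
    scores: List[EntropyScore] = []
    for i, item in enumerate(ref_umrs):
        region = item.region if hasattr(item, "region") else item
        row = mat.iloc[i].to_numpy()
        h = shannon_entropy(row, pseudocount)
        scores.append(
            EntropyScore(
                region=region,
                values=row,
                entropy_bits=h,
                threshold_bits=threshold_bits,
            )
        )
    return scores


def filter_heterogeneous(
    ref_umrs: Sequence,
    normal_methylomes: Sequence[Methylome],
    threshold_bits: Optional[float] = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> List:
    """Retain reference UMRs with entropy >= threshold across normals.

    Default threshold: log2(N) - 1 bits for N normal samples. A threshold of
    0 disables the filter.
    """
    scores = entropy_scores(
        ref_umrs, normal_methylomes, threshold_bits, pseudocount
    )
    kept = [u for u, s in zip(ref_umrs, scores) if not s.is_heterogeneous]
    log.info(
        "entropy filter: retained %d/%d regions (threshold %.3f bits)",
        len(kept),
        len(ref_umrs),
        scores[0].threshold_bits if scores else float("nan"),
    )
    return kept
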