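"""Core domain types shared across the pipeline.

All genomic intervals are 0-based half-open ``[start, end)``; a ``CpGRecord``
position is the coordinate of the C of a CpG dinucleotide on the + strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

PROMOTER_UPSTREAM = 1000  # bp upstream of TSS
PROMOTER_DOWNSTREAM = 500  # bp downstream of TSS; gene body starts here
CANYON_MIN_LENGTH = 3500  # strict >: a reference UMR longer than this is a canyon


@dataclass(frozen=True, order=True)
class Region:
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


class Methylome:
    """Per-sample CpG methylation profile.

    Wraps a DataFrame with columns ``chrom, pos, meth_ratio, coverage``,
    strictly sorted by (chrom, pos) with no duplicate positions.
    """

    def __init__(
        self,
        sample_id: str,
        records: pd.DataFrame,
        group: Optional[str] = None,
        tumor_type: Optional[str] = None,
    ):
        req = ["chrom", "pos", "meth_ratio", "coverage"]
        missing = [c for c in req if c not in records.columns]
        if missing:
            raise ValueError(f"methylome records missing columns {missing}")
        df = records[req].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["coverage"] = df["coverage"].astype(np.int64)
        df["meth_ratio"] = df["meth_ratio"].astype(float)
        if ((df["meth_ratio"] < 0) | (df["meth_ratio"] > 1)).any():
            raise ValueError("meth_ratio outside [0, 1]")
        if (df["coverage"] < 0).any():
            raise ValueError("negative coverage")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if df.duplicated(["chrom", "pos"]).any():
            df = df.drop_duplicates(["chrom", "pos"], keep="first").reset_index(
                drop=True
            )
        self.sample_id = sample_id
        self.group = group
        self.tumor_type = tumor_type
        self.records = df
        # per-chromosome views cached lazily for fast range queries
        self._by_chrom: Optional[dict] = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def chroms(self):
        return list(dict.fromkeys(self.records["chrom"]))

    def chrom_arrays(self, chrom: str):
        """(pos, meth_ratio, coverage, cumulative-ratio-sum) arrays for one chromosome."""
        if self._by_chrom is None:
            self._by_chrom = {}
            for name, sub in self.records.groupby("chrom", sort=False):
                pos = sub["pos"].to_numpy()
                ratio = sub["meth_ratio"].to_numpy()
                cov = sub["coverage"].to_numpy()
                csum = np.concatenate([[0.0], np.cumsum(ratio)])
                self._by_chrom[name] = (pos, ratio, cov, csum)
        return self._by_chrom.get(chrom)

    def region_mean(self, region: Region) -> float:
        """Unweighted mean meth_ratio over CpGs inside ``region``; NaN if none."""
        arrs = self.chrom_arrays(region.chrom)
        if arrs is None:
            return float("nan")
        pos, _, _, csum = arrs
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="left")
        if hi <= lo:
            return float("nan")
        return float((csum[hi] - csum[lo]) / (hi - lo))


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware gene with derived promoter and gene-body windows.

    The promoter spans 1 kb upstream through 500 bp downstream of the TSS;
    the gene body spans from 500 bp downstream of the TSS to the TTS.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    promoter: Region = field(compare=False)
    genebody: Region = field(compare=False)

    @staticmethod
    def from_interval(
        gene_id: str, chrom: str, start: int, end: int, strand: str
    ) -> "GeneModel":
        if strand not in ("+", "-"):
            raise ValueError(f"unknown strand {strand!r} for gene {gene_id}")
        if not start < end:
            raise ValueError(f"gene {gene_id}: start must be < end")
        if strand == "+":
            tss, tts = start, end
            promoter = Region(chrom, tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM)
            body_start, body_end = tss + PROMOTER_DOWNSTREAM, tts
        else:
            tss, tts = end, start
            promoter = Region(chrom, tss - PROMOTER_DOWNSTREAM, tss + PROMOTER_UPSTREAM)
            body_start, body_end = tts, tss - PROMOTER_DOWNSTREAM
        if body_end - body_start <= 0:
            raise ValueError(f"gene {gene_id}: empty gene body")
        return GeneModel(
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            tss=tss,
            tts=tts,
            promoter=promoter,
            genebody=Region(chrom, body_start, body_end),
        )


@dataclass
class UMR:
    """Under-methylated region called in a single sample."""

    region: Region
    n_cpg: int
    mean_meth: float
    sample_id: str
    obs_exp: Optional[float] = None


@dataclass
class UOFSegment:
    """Atomic segment of the merged UMR union with constant sample occupancy."""

    region: Region
    k: int
    n_samples: int

    @property
    def uof(self) -> float:
        return self.k / self.n_samples


@dataclass
class ReferenceUMR:
    """Population reference UMR called from the occupancy (UOF) profile."""

    region: Region
    k: int
    n_samples: int
    poisson_p: float
    fdr: float

    @property
    def uof(self) -> float:
        return self.k / self.n_samples

    @property
    def umr_class(self) -> str:
        return "canyon" if self.region.length > CANYON_MIN_LENGTH else "cUMR"
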