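"""Readers and writers for the plain-text formats the pipeline touches.

Internal coordinates are always 0-based half-open. BED output therefore needs
no shift; 1-based ratio-table input positions are shifted by -1 exactly once,
here.

Methylation tables are accepted in three dialects, auto-detected from the
column count and numeric ranges:

* 5 columns ``chrom, pos(1-based), meth_ratio, meth_reads, total_reads``
  (BSMAP-style ratio table; coverage = total_reads);
* 4 columns ``chrom, start(0-based), end, meth_ratio`` (bedGraph; coverage
  unknown, recorded as a large sentinel so no record is coverage-filtered);
* 4 columns ``chrom, pos(1-based), meth_ratio, coverage`` (compact ratio
  table; recognised when column 3 lies in [0, 1] and column 4 is
  integer-valued with a value > 1).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, List, Sequence, Union

import numpy as np
import pandas as pd

from .core import GeneModel, Methylome, ReferenceUMR, Region, UMR

log = logging.getLogger(__name__)

#: coverage recorded for bedGraph input, where read depth is not available
BEDGRAPH_COVERAGE = 2**30


def _detect_dialect(df: pd.DataFrame, path) -> str:
    ncol = df.shape[1]
    if ncol == 5:
        return "ratio5"
    if ncol != 4:
        raise ValueError(f"{path}: expected 4 or 5 columns, found {ncol}")
    c2 = pd.to_numeric(df.iloc[:, 2], errors="coerce")
    c3 = pd.to_numeric(df.iloc[:, 3], errors="coerce")
    c3_integer = np.allclose(c3.dropna() % 1, 0) if c3.notna().any() else False
    if c2.between(0, 1).all() and c3_integer and (c3 > 1).any():
        return "ratio4"
    return "bedgraph"


def read_methylome(
    path: Union[str, Path],
    sample_id: str,
    min_coverage: int = 4,
    group: str | None = None,
    tumor_type: str | None = None,
) -> Methylome:
    """Read a per-CpG methylation table and apply the read-coverage filter.

    CpGs covered by fewer than ``min_coverage`` reads are dropped (default 4,
    the depth needed for an accurate per-CpG methylation ratio). Input is
    sorted if needed (with a warning) and duplicate positions keep the first
    occurrence.
    """
    if min_coverage < 0:
        raise ValueError("min_coverage must be >= 0")
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "pos", "meth_ratio", "coverage"])
        return Methylome(sample_id, df, group=group, tumor_type=tumor_type)
    # optional header row: drop if the position column is not numeric
    if len(df) and pd.to_numeric(df.iloc[0, 1:], errors="coerce").isna().any():
        df = df.iloc[1:].reset_index(drop=True)
    if df.empty:
        empty = pd.DataFrame(columns=["chrom", "pos", "meth_ratio", "coverage"])
        return Methylome(sample_id, empty, group=group, tumor_type=tumor_type)
    for i in range(1, df.shape[1]):
        col = pd.to_numeric(df.iloc[:, i], errors="coerce")
        if col.isna().any():
            bad = int(np.where(col.isna())[0][0]) + 1
            raise ValueError(f"{path}: malformed value in line {bad}")
        df.isetitem(i, col)
    dialect = _detect_dialect(df, path)
    if dialect == "ratio5":
        out = pd.DataFrame(
            {
                "chrom": df.iloc[:, 0],
                "pos": df.iloc[:, 1].astype(np.int64) - 1,
                "meth_ratio": df.iloc[:, 2].astype(float),
                "coverage": df.iloc[:, 4].astype(np.int64),
            }
        )
    elif dialect == "ratio4":
        out = pd.DataFrame(
            {
                "chrom": df.iloc[:, 0],
                "pos": df.iloc[:, 1].astype(np.int64) - 1,
                "meth_ratio": df.iloc[:, 2].astype(float),
                "coverage": df.iloc[:, 3].astype(np.int64),
            }
        )
    else:  # bedgraph
        out = pd.DataFrame(
            {
                "chrom": df.iloc[:, 0],
                "pos": df.iloc[:, 1].astype(np.int64),
                "meth_ratio": df.iloc[:, 3].astype(float),
                "coverage": np.int64(BEDGRAPH_COVERAGE),
            }
        )
    bad_ratio = ~out["meth_ratio"].between(0, 1)
    if bad_ratio.any():
        line = int(np.where(bad_ratio)[0][0]) + 1
        raise ValueError(f"{path}: meth_ratio outside [0, 1] at data line {line}")
    n_before = len(out)
    out = out[out["coverage"] >= min_coverage]
    n_dropped = n_before - len(out)
    if n_dropped:
        log.info(
            "%s: dropped %d/%d CpGs below coverage %d",
            sample_id,
            n_dropped,
            n_before,
            min_coverage,
        )
    unsorted = not out[["chrom", "pos"]].equals(
        out[["chrom", "pos"]].sort_values(["chrom", "pos"], kind="mergesort")
    )
    if unsorted:
        warnings.warn(f"{path}: input not sorted; sorting", stacklevel=2)
    if out.duplicated(["chrom", "pos"]).any():
        warnings.warn(
            f"{path}: duplicate CpG positions; keeping first occurrence",
            stacklevel=2,
        )
    return Methylome(sample_id, out, group=group, tumor_type=tumor_type)


def read_gene_models(path: Union[str, Path]) -> List[GeneModel]:
    """Read gene intervals (gene_id, chrom, start, end, strand; 0-based
    half-open) and derive promoter/gene-body windows strand-aware.

    Genes whose body would be empty (total length <= 500 bp) are excluded with
    a warning.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if len(df) and not str(df.iloc[0, 2]).lstrip("-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)
    genes: List[GeneModel] = []
    for _, row in df.iterrows():
        gene_id, chrom = str(row.iloc[0]), str(row.iloc[1])
        start, end, strand = int(row.iloc[2]), int(row.iloc[3]), str(row.iloc[4])
        try:
            genes.append(GeneModel.from_interval(gene_id, chrom, start, end, strand))
        except ValueError as exc:
            if "empty gene body" in str(exc):
                warnings.warn(
                    f"gene {gene_id} excluded: body would be empty", stacklevel=2
                )
            else:
                raise
    return genes


def _region_of(item) -> Region:
    return item.region if hasattr(item, "region") else item


def write_regions_bed(regions: Sequence, path: Union[str, Path]) -> None:
    """Write Region-like items as BED; ReferenceUMR/UMR get BED6+ extra columns.

    ReferenceUMR rows carry ``class, k, n, uof, poisson_p, fdr``; UMR rows carry
    ``n_cpg, mean_meth, obs_exp``; bare Regions are BED3. All rows in one file
    share a flavour.
    """
    with open(path, "w") as fh:
        for item in regions:
            r = _region_of(item)
            if isinstance(item, ReferenceUMR):
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{item.umr_class}\t0\t.\t"
                    f"{item.k}\t{item.n_samples}\t{item.uof:.6g}\t"
                    f"{item.poisson_p:.6g}\t{item.fdr:.6g}\n"
                )
            elif isinstance(item, UMR):
                oe = "." if item.obs_exp is None else f"{item.obs_exp:.6g}"
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{item.sample_id}\t0\t.\t"
                    f"{item.n_cpg}\t{item.mean_meth:.6g}\t{oe}\n"
                )
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_regions_bed(path: Union[str, Path]) -> List:
    """Read BED written by :func:`write_regions_bed`, restoring the flavour."""
    out: List = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            region = Region(f[0], int(f[1]), int(f[2]))
            if len(f) == 3:
                out.append(region)
            elif len(f) == 11:
                out.append(
                    ReferenceUMR(
                        region=region,
                        k=int(f[6]),
                        n_samples=int(f[7]),
                        poisson_p=float(f[9]),
                        fdr=float(f[10]),
                    )
                )
            elif len(f) == 9:
                oe = None if f[8] == "." else float(f[8])
                out.append(
                    UMR(
                        region=region,
                        n_cpg=int(f[6]),
                        mean_meth=float(f[7]),
                        sample_id=f[3],
                        obs_exp=oe,
                    )
                )
            else:
                raise ValueError(f"{path}: unrecognised BED row with {len(f)} fields")
    return out


def write_methylome(methylome: Methylome, path: Union[str, Path]) -> None:
    """Write a methylome as a 5-column ratio table (1-based positions)."""
    df = methylome.records
    meth_reads = np.rint(df["meth_ratio"] * df["coverage"]).astype(np.int64)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"] + 1,
            "meth_ratio": df["meth_ratio"].map("{:.6g}".format),
            "meth_reads": meth_reads,
            "coverage": df["coverage"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_gene_models(genes: Iterable[GeneModel], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            start = min(g.tss, g.tts)
            end = max(g.tss, g.tts)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{start}\t{end}\t{g.strand}\n")


def read_expression(path: Union[str, Path]) -> pd.DataFrame:
    """Gene x sample expression matrix (TSV, header row, gene ids in column 1)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: expression values must be nonnegative")
    return df


def read_gene_set(path: Union[str, Path]) -> List[str]:
    """One gene id per line."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def validate_chrom_names(*name_sets: Iterable[str]) -> dict:
    """Report chromosome-name-set disagreement between inputs (used verbatim,
    never normalised)."""
    sets = [set(s) for s in name_sets]
    common = set.intersection(*sets) if sets else set()
    return {
        "common": sorted(common),
        "only_in": [sorted(s - common) for s in sets],
        "agree": all(s == common for s in sets),
    }
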