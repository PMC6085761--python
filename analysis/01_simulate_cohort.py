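#!/usr/bin/env python
"""Simulate the default pan-cancer cohort (30 normals, 35 tumors over 7 tumor
types on one synthetic chromosome) and summarize what was planted."""

import pandas as pd

from common import parse_args
from methcanyon.pipeline import PipelineConfig, simulate_stage


def main():
    args = parse_args(__doc__)
    state = simulate_stage(PipelineConfig(seed=args.seed))
    truth = state.cohort.truth
    table = truth.regions_table()
    table.to_csv(args.outdir / "planted_regions.tsv", sep="\t", index=False)
    truth.gene_labels.to_csv(args.outdir / "gene_labels.tsv", sep="\t", index=False)
    counts = table.groupby(["kind", "effect"]).size()
    print(f"chromosome: {truth.chrom_len:,} bp; "
          f"{len(state.cohort.methylomes[0]):,} CpGs per sample")
    print(f"samples: {len(state.cohort.normals)} normal / {len(state.cohort.tumors)} tumor")
    print("planted regions by kind x tumor effect:")
    print(counts.to_string())
    print(f"tables -> {args.outdir}")


if __name__ == "__main__":
    main()
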