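#!/usr/bin/env python
"""Associate hypermethylated canyons with genes, apply the expression filter
(rank-sum FDR < 0.01, fold change > 2) and test gene-set enrichment."""

from common import parse_args, state_upto


def main():
    args = parse_args(__doc__)
    state = state_upto(args.seed, "association_stage")
    state.de_table.to_csv(args.outdir / "de_genes.tsv", sep="\t", float_format="%.6g")
    state.enrichment.to_csv(args.outdir / "enrichment.tsv", sep="\t", index=False,
                            float_format="%.6g")
    print(f"DE genes: {len(state.de_up)} up, {len(state.de_down)} down")
    for _, row in state.enrichment.iterrows():
        print(f"  {row.gene_set:>15}: overlap {row.n_overlap:2d}, "
              f"OR {row.odds_ratio:8.2f}, p {row.p_value:.3g}")
    print(f"tables -> {args.outdir}")


if __name__ == "__main__":
    main()
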