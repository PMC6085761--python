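#!/usr/bin/env python
"""Beta-LRT pan-cancer differential methylation: chi-squared (df = 2) on the
likelihood ratio, BH FDR < 0.001 plus DM value > 0.1, four-way hyper/hypo x
canyon/cUMR categorization and per-tumor-type recurrence."""

import pandas as pd

from common import parse_args, state_upto
from methcanyon.diffmeth import conserved_controls, results_table


def main():
    args = parse_args(__doc__)
    state = state_upto(args.seed, "diffmeth_stage")
    table = results_table(state.dm_results)
    table.to_csv(args.outdir / "dm_results.tsv", sep="\t", index=False, float_format="%.6g")
    state.per_type.to_csv(args.outdir / "dm_per_type.tsv", sep="\t")
    print("category counts:", table["category"].value_counts().to_dict())
    canyons = table[table["class"] == "canyon"]
    print(f"canyons: {100 * (canyons.category == 'hyper-canyon').mean():.1f}% hyper, "
          f"{100 * (canyons.category == 'hypo-canyon').mean():.1f}% hypo")
    sig = table[table.category != "none"]
    if len(sig):
        rec3 = (sig.n_types_recurrent >= 3).mean()
        print(f"{100 * rec3:.0f}% of differential UMRs recur in >= 3 tumor types")
    cons_canyon, cons_cumr = conserved_controls(state.dm_results, state.per_type)
    print(f"conserved controls: {len(cons_canyon)} canyons, {len(cons_cumr)} cUMRs")
    print(f"tables -> {args.outdir}")


if __name__ == "__main__":
    main()
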