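#!/usr/bin/env python
"""Build the population reference-UMR atlas (UOF + Poisson test at
p < 1e-8, BH-adjusted) and classify canyons (> 3.5 kb) vs control cUMRs."""

from common import parse_args, state_upto
from methcanyon.io_formats import write_regions_bed


def main():
    args = parse_args(__doc__)
    state = state_upto(args.seed, "atlas_stage")
    for name, refs in (("normal", state.ref_normal), ("tumor", state.ref_tumor),
                       ("combined", state.ref_combined)):
        write_regions_bed(refs, args.outdir / f"reference_{name}.bed")
        n_canyon = sum(1 for r in refs if r.umr_class == "canyon")
        print(f"{name:>8}: {len(refs):4d} reference UMRs, {n_canyon} canyons")
    print(f"atlas BED files -> {args.outdir}")


if __name__ == "__main__":
    main()
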