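#!/usr/bin/env python
"""Remove reference UMRs that behave heterogeneously across the normal
cohort (Shannon-entropy specificity below log2(N) - 1 bits)."""

import numpy as np
import pandas as pd

from common import parse_args, state_upto
from methcanyon.entropy_filter import entropy_scores


def main():
    args = parse_args(__doc__)
    state = state_upto(args.seed, "entropy_stage")
    scores = entropy_scores(state.ref_combined, state.cohort.normals)
    df = pd.DataFrame({
        "region": [f"{s.region.chrom}:{s.region.start}-{s.region.end}" for s in scores],
        "entropy_bits": [s.entropy_bits for s in scores],
        "removed": [s.is_heterogeneous for s in scores],
    })
    df.to_csv(args.outdir / "entropy_scores.tsv", sep="\t", index=False, float_format="%.4f")
    removed = df["removed"].sum()
    print(f"threshold {scores[0].threshold_bits:.3f} bits; "
          f"removed {removed}/{len(df)} heterogeneous regions "
          f"(min H = {df.entropy_bits.min():.3f}, max = {df.entropy_bits.max():.3f})")
    print(f"scores -> {args.outdir / 'entropy_scores.tsv'}")


if __name__ == "__main__":
    main()
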