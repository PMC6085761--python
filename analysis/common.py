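"""Shared plumbing for the numbered analysis drivers.

Each driver re-runs the pipeline deterministically from the seed up to the
stage it reports on (the cohort simulates in a few seconds, so no
inter-script state needs to be pickled) and writes its tables under
``results/synthetic``.
"""

from __future__ import annotations

import argparse
from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def parse_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=RESULTS)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    return args


def state_upto(seed: int, stage_name: str):
    from methcanyon.pipeline import PipelineConfig, run_upto

    return run_upto(PipelineConfig(seed=seed), stage_name)
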